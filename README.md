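# riverdiv

Spatial-phylogenetic biodiversity prioritization along river corridors.

River valleys concentrate plant diversity — heterogeneous habitats, water and
nutrient gradients, dispersal corridors — yet they are routinely overlooked
when conservation areas are designed. `riverdiv` implements the full analysis
a conservation biogeographer runs to change that: it grids point occurrence
records over buffered river corridors, scores every grid cell with
complementary diversity indicators, selects hotspot cells, overlays the
existing protected-area network, and quantifies how much of the hotspot area
and flora that network actually covers — and where the gaps are.

The package is aimed at researchers with three inputs: occurrence records
(species, x, y), a rooted phylogeny with branch lengths (Newick), and river
centerlines plus reserve polygons (GeoJSON, planar/projected coordinates).
A first-class synthetic-data generator produces all of these with *planted*
hotspots, so every stage of the pipeline can be validated against a known
answer.

## Indicators

All indicators are computed per grid cell *c* from the boolean presence
matrix (cells × species) and, for the phylogenetic ones, a rooted tree with
branch lengths *L_b*:

- **Species richness** — number of species of a group (all / endemic /
  threatened / nationally protected) present in *c*.
- **Faith's phylogenetic diversity** — PD(c) = Σ L_b over the branches on
  the union of root-to-tip paths of the tips present in *c* (root-inclusive
  by default).
- **Phylogenetic endemism** (Rosauer) — PE(c) = Σ L_b / R_b over the same
  branch set, where R_b is the number of cells containing any descendant tip
  of branch *b*. Summed over all cells, PE returns exactly the PD of the
  pooled tip set.
- **Weighted endemism** — WE(c) = Σ_s 1 / r_s over species present in *c*,
  with r_s the species' range in cells. Σ_c WE(c) equals the species count.
- **Complementarity** — greedy set cover: iteratively select the cell adding
  the most not-yet-covered species until every species of the group is
  represented; selected cells carry their marginal gain, all others 0.

Each indicator table is standardized by its maximum, the top 10% of cells
(ties at the cutoff included) are hotspots per indicator, and the per-cell
sum of standardized indicators ranked the same way gives the combined
hotspot set. Reserve polygons (national / provincial tiers) are overlaid on
the cells; a hotspot cell intersected by no reserve of a tier is a
conservation gap of that tier. Species in any cell stratum are reported in
three exclusive classes — threatened (TH), endemic-not-threatened (EN),
remaining (REMA) — and congruence between indicators is measured with
Pearson correlations on the zero-filled, log1p + z-score transformed
cells × indicators matrix.

## Worked example

Simulate a corridor study (300 species, 6 rivers, 10 planted hotspot cells,
5× occurrence boost in planted cells) and run the whole pipeline:

```python
from riverdiv import SimulationConfig, run_pipeline

res = run_pipeline(SimulationConfig(n_species=300, seed=11))
print(len(res.corridor), len(res.hotspots.combined))
print(res.report.table)
```

Output:

```
corridor cells: 278
hotspot cells:  28
planted cells recovered: 9 of 10
                   th   en  rema  total  grid_cells
corridor           29  121   150    300         278
hotspots           26   84    88    198          28
nnr                16   83   106    205          82
effectiveness_nnr   4   21    19     44           6
gap_nnr            25   78    80    183          22
...
r(all, PD)  = 0.94
r(all, WE)  = 0.81
r(PD, PE)   = 0.8
```

Reading this: the corridor contains 278 cells and 300 species; the top-10%
combined selection flags 28 cells which hold 198 species (66%) including 26
of the 29 threatened ones — hotspots concentrate the flora. Only 6 hotspot
cells are covered by national reserves (effectiveness_nnr), leaving 22
national-tier gap cells that still hold 183 species. Richness, PD and WE are
strongly congruent (r ≥ 0.8), as expected when narrow-ranged species
aggregate in the same cells.

The same stages are available from the shell:

```sh
riverdiv simulate --config cfg.yaml --out data/ --seed 7
riverdiv grid --rivers data/rivers.geojson --occurrences data/occurrences.csv \
              --buffer 20 --cell 50 --out grid/
riverdiv metrics --matrix grid/presence_matrix.csv --grid grid/grid.json \
                 --tree data/tree.nwk --catalog data/catalog.csv --out ind/
riverdiv hotspots --indicators ind/ --grid grid/grid.json --out hot/
riverdiv gaps --hotspots hot/hotspots.geojson --reserves data/reserves.geojson \
              --matrix grid/presence_matrix.csv --grid grid/grid.json \
              --catalog data/catalog.csv --out gaps/
riverdiv correlate --indicators ind/ --grid grid/grid.json --out corr/
```

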