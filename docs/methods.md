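# Methods

## The analysis model

The pipeline treats a set of river valleys as the study region. Each river
is a planar polyline; the region of interest is the union of fixed-width
buffers (default half-width 20 length units, i.e. a 40-unit corridor) around
the centerlines. A regular square grid (default cell size 50 units) is laid
over the region; the analysis universe is every cell the buffered corridor
touches, wholly or partially — boundary or corner contact counts, so no
marginally occupied cell is dropped.

Occurrence records are cleaned in three ordered steps before rasterization:
records without precise locality are dropped; species names are rewritten
through a synonym map (resolved transitively; cyclic maps are rejected);
and, when a species carries an `allowed_regions` set and region polygons are
supplied, records geolocated outside every allowed region are dropped
(range rescreening). Each rule's removals are counted in a cleaning log.
The cleaned records become a boolean cells × species presence matrix —
presence, never abundance — and species left with no record inside the
corridor are removed from the matrix with a notice.

### Indicators

Eleven cell-value tables are computed by default:

| indicator | definition |
|---|---|
| `all`, `endemic`, `threatened`, `protected` | group species richness per cell |
| `all_C`, `endemic_C`, `threatened_C`, `protected_C` | greedy-complementarity marginal gains (0 at unselected cells) |
| `PD` | Faith's phylogenetic diversity, root-inclusive |
| `PE` | Rosauer's phylogenetic endemism, Σ L_b / R_b |
| `WE` | weighted endemism, Σ 1 / r_s |

PD, PE and WE are always computed from the all-species matrix and a single
tree; group flags never restrict them. Species present in the matrix but
absent from the tree are excluded from PD/PE with a logged warning (partial
overlap between a flora and a megatree is the normal situation). The branch
range R_b is the number of *corridor grid cells* containing at least one
descendant tip — the same spatial units every other indicator uses.

Root handling is configurable (`pd_include_root`, default `True`): the
default counts every branch from the root down to the present tips, so a
one-species cell scores that species' full root path. This matches the
convention of the Biodiverse software that popularized these metrics; the
alternative (`False`) counts only the minimal spanning subtree of the
present tips. PE follows the same convention so that Σ_c PE(c) equals the
pooled-tip PD exactly — an identity the tests assert at 1e-9.

### Greedy complementarity

Standard greedy set cover per plant group: select the cell with the most
uncovered group species, remove *all* species present in that cell from
consideration, repeat until coverage is complete. Ties are broken by lowest
cell id — deterministic and documented. Marginal gains are strictly
positive, non-increasing, and partition the covered species set; both
properties are asserted. On instances small enough for exhaustive search the
greedy solution is compared against the true minimum cover via the classical
harmonic bound (a reporting check, not an equality).

### Hotspot selection

Every indicator is standardized by dividing by its maximum cell value
(an all-zero indicator is a degenerate-indicator error). The top fraction
(default 10%) of the *cell universe* — all corridor cells, occupied or not —
is selected per indicator: k = fraction × universe size, rounded half-up
(configurable `floor|round|ceil`), and every cell tied with the k-th ranked
value is also included so equally valuable cells are never split
arbitrarily. Zero-valued cells are never selected. The combined hotspot set
applies the same rule to the per-cell sum of standardized indicators.
Connected components of the selection (rook adjacency) are reported as a
convenience for naming contiguous hotspot regions, with no claim about how
many such regions "should" exist.

Two indicator presets are provided: `full` (all eleven tables; the
procedure sums "the different standardized values" without restriction) and
`reduced` (all-species richness, all-species complementarity, PD). `full`
is the default.

### Conservation assessment

Reserves carry a two-level tier (`national` / `provincial`); invalid
polygons are repaired with `make_valid` at construction. A cell is covered
by a tier when any reserve polygon of that tier intersects the cell square
at all — binary coverage, no minimum-overlap threshold. For each tier and
for the union: effectiveness = hotspot cells covered, gaps = hotspot cells
not covered. Species in any cell stratum are classified with precedence
threatened > endemic > remaining into TH / EN / REMA, which are mutually
exclusive and sum to the stratum total. "Area" percentages are cell-count
ratios, not polygon-area ratios — the only interpretation under which
counts and percentages stay mutually consistent. Percentages are rounded
half-up (decimal arithmetic, not float), since published tables use
half-up conventions and banker's rounding would disagree at exact halves.

### Congruence analysis

The cells × indicators matrix keeps *every* corridor cell as a row and fills
missing cell-indicator combinations with 0 (complementarity columns are
mostly zeros by construction). Columns are transformed log1p-then-z-score:
the zero-filled entries make a plain log undefined, so log1p first is the
only order defined on the stated matrix; the alternative order
(`z_then_log`, z-score then signed log1p) is available behind a switch and
the order used is recorded in the output metadata. Constant columns cannot
be scaled; they are left at zero with a warning, and correlations involving
them are reported as r = 0, p = 1. Pearson r with two-sided t-test p-values
is computed over the full row set for every pair; no multiple-testing
correction is applied (raw p-values are reported). Strength labels follow
the conventional cutoffs |r| ≥ .8 very strong, .6–.8 strong, .4–.6 moderate,
.2–.4 weak, below .2 very weak or none, inclusive on the lower bound.

## The synthetic-data generator

The generator emulates the *structure* of a multi-river occurrence study at
configurable scale, with defaults chosen to resemble such a study in
miniature:

| parameter | default | meaning |
|---|---|---|
| `n_species` | 500 | species pool (tree tips) |
| `n_rivers` | 6 | parallel west-east rivers at staggered latitudes |
| `extent` | (0, 0, 1000, 1000) | planar bounding box, abstract length units |
| `cell_size` / `buffer_width` | 50 / 20 | grid resolution and corridor half-width |
| `corridor_sd` | 10 | Gaussian spread of points around the centerline |
| `mean_occurrences` | 50 | Poisson mean points per species (min 1) |
| `range_mu`, `range_sigma` | 1.0, 0.6 | lognormal of intended range size in cells |
| `n_hotspot_centers` / `hotspot_boost` | 10 / 5 | planted cells and their intensity multiplier |
| `frac_endemic` / `frac_threatened` / `frac_protected` | 0.49 / 0.08 / 0.005 | Bernoulli flag proportions |
| `reserve_cover_frac` | 0.64 | fraction of corridor cells receiving a reserve |
| `frac_national_reserves` | 0.37 | national share among reserves |

Rivers are polylines crossing the extent west to east in their own
latitudinal band with mild Gaussian meander, like adjacent parallel
drainages; their corridors are largely disjoint, so cell richness is not
inflated by artificial river crossings. The phylogeny is a random binary
tree (sequential pairwise joins, exponential branch lengths with mean 1,
floored at 1e-3); trees read from Newick may contain polytomies.

Each species is anchored at a position along one river and spreads its
occurrences uniformly along the river over a window proportional to its
intended range, displaced perpendicular by a 2-D Gaussian with s.d.
`corridor_sd`. Range sizes are lognormal so weighted endemism has
heavy-tailed, nontrivial variance. Flags are independent Bernoulli draws —
the threatened ⊂ endemic nesting is deliberately *not* imposed, since real
lists overlap without nesting.

Planted hotspots are one-cell river windows whose anchor density is
`hotspot_boost` times the background density. Species anchored in a window
additionally have all their spatial scales (anchor offset from the window
center, along-river span, perpendicular s.d.) shrunk by the boost factor,
so planted cells aggregate narrow-ranged species — the mechanism by which
real endemism hotspots arise. At `hotspot_boost = 1` both effects vanish
identically and planted windows are statistically indistinguishable from
background. Window centers are accepted only ≥ 20% of the cell size from
every cell edge so the signal lands in the intended cell. Reserves are
axis-aligned rectangles strictly inside `round(frac × n_cells)` randomly
chosen cells, so the covered-cell count is exact by construction.

Everything is deterministic for a fixed seed: each generator stage draws
from its own stream derived from `(seed, stage)`, and all writers emit
sorted rows with fixed float formatting, so repeated runs are byte-identical.

### What the generator does *not* emulate

Climate- or niche-driven species distributions, georeferencing noise,
taxonomic synonymy (the cleaning rules are exercised with crafted inputs
instead), spatial autocorrelation of flags (threatened species are not
spatially clustered), real reserve geometry (one rectangle per covered
cell), and geographic coordinate systems (all geometry is planar; users of
geographic data must project to an equal-area CRS before input, since no
projection machinery is included). Passing tests therefore demonstrate the
*algorithms* are correct and the pipeline recovers planted structure, not
that any particular real-world dataset would yield particular hotspots.

## Numerical and design choices

- **Cell assignment** uses half-open squares `[x0+i·s, x0+(i+1)·s)` so every
  point maps to exactly one cell; points exactly on the grid's outer
  top/right hull are assigned to the last row/column so no data are lost.
- **Grid origin** defaults to the buffered region's bounding box snapped
  down to the cell-size lattice, making grids from overlapping regions
  share one lattice. The synthetic pipeline pins the extent-based grid so
  planted cell ids stay valid.
- **Buffers** use round end-caps and joins (shapely defaults).
- **Corridor cell counts are reported, never asserted** — with tie-inclusive
  selection and data-dependent geometry there is no canonical "right"
  number of corridor or hotspot cells, only the arithmetic relating them.
- **Top-k arithmetic**: round-half-up of fraction × universe, minimum 1.
- **Recovery metric**: |combined hotspots ∩ planted cells| / |planted cells|.
- Groups with no species present (e.g. `protected` at 0.5% of a small pool)
  are skipped with a warning rather than failing the run; the indicator set
  shrinks accordingly.
- The per-module command-line verbs are subcommands of one `riverdiv`
  console script, a thin layer over the library functions.

## Known limitations

- No geographic CRS handling; planar coordinates only.
- Greedy cover is the only complementarity solver; no exact set cover at
  scale and no cost/area weighting.
- No randomization-based significance for the phylogenetic metrics
  (no RPD/RPE/CANAPE) and no abundance weighting.
- Correlation p-values ignore spatial autocorrelation; they are the plain
  t-approximation on cell rows treated as independent observations.
- The acceptance and test simulations run at a few hundred species for
  speed; the implementation is vectorized over cells and has been run at
  several thousand species, but very large trees (≫10⁴ tips) would warrant
  sparse presence storage.
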