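# Methods

## Model and assumptions

The package assesses the carrying capacity of a coral reef island as a
vector comparison between human pressure and system support. Every
indicator is a pair (p, s) in one unit system with s > 0 acting as the
threshold for p ≥ 0; its surplus ratio is d = 1 − p/s. The printed form
(p − s)/s found in parts of the literature contradicts its own stated sign
convention (positive = surplus); this package implements the convention,
d = (s − p)/s, so d > 0 always means surplus. Ratios below −1 are legal
and meaningful (pressure more than double the support) and are never
clamped.

Levels are pooled with the equal-weight vector rule
D = 1 − sqrt(mean((1 − d_j)²)): load factors (1 − d_j) are averaged in the
root-mean-square sense, so a single badly over-loaded child dominates a
dimension — an intentional precautionary property. The rule is permutation
invariant, reduces to the child for singletons, and is strictly monotone
in every child. Equal weights reflect the assumption that no prior
knowledge ranks the factors; a per-child weight hook exists in the config
but defaults to 1 everywhere.

**Aggregation modes.** The published Zhaoshu Island results are only
reproducible under mixed conventions: its ecosystem-services dimension
pools the four coral indicators into the coral-reef factor before
combining with the terrestrial (Sum LAI) factor, while the socio-economic
dimension pools its three indicators in one step even though they span two
factors. `aggregation_mode` is therefore a per-dimension config field
(`flat` | `nested`); the bundled ZSI fixture sets ecosystem services to
`nested` and the other three dimensions to `flat`. Mixed modes change the
numbers: flat pooling of the ecosystem dimension would give −0.51 rather
than −0.35.

**States.** d < 0 over-loaded; d = 0 full-loaded exactly (never warning);
0 < d < w warning; d ≥ w surplus. The warning width w defaults to 0.10 —
an uncertainty buffer acknowledging that most pressure/support estimates
are means of uncertain ranges, so a small nominal surplus should not be
read as safety. Display rounding is two decimals for ratios and whole
percents for degrees; stored and JSON-rendered values keep full precision
and the acceptance machinery reads those.

## Support-end estimators

**Land suitability.** Weighted overlay of aligned factor rasters with
weights summing to 1 (tolerance 1e−9). A zero grade in *any* layer vetoes
the cell (standard ecological-suitability veto logic; the alternative
"all-zero" reading would let a forbidden fracture zone be averaged away).
Grades default to the {0, 1, 3, 5} convention and classes use thresholds
(t1, t2) = (2, 4): score 0 forbidden, (0, t1) limited, [t1, t2)
less-suitable, ≥ t2 suitable; less-suitable + suitable counts as suitable
construction land. Grids are ESRI ASCII (row-major, origin upper-left,
square cells, NODATA −9999); floats are written in shortest
round-tripping representation so read/write is bit-exact.

**Water.** The available-water budget is an open named-component sum: the
four canonical components (ground, transferred-in, reclaimed, desalinated)
plus anything else the config supplies (e.g. surface water, which prose
descriptions include but the canonical formula omits). Units are a
consistency tag, never converted — whether 1 t ≈ 1 m³ is the user's call.

**Assimilative capacity.** Linear program: maximize Σ Q_j subject to
P·Q ≤ C_s − background per sea area and Q_l ≤ Q ≤ Q_u per source, solved
with `scipy.optimize.linprog` (HiGHS). The optional per-area background
concentration is a standard TMDL refinement; its default 0 reproduces the
plain formulation. Only the optimum AC is contract-bound: with degenerate
optima the load vector is whichever vertex the solver returns. Lower
bounds violating a standard raise an infeasibility error naming the
violated areas before the solver runs. With several pollutants (typically
inorganic N and P) the per-pollutant ratios 1 − discharge/AC combine into
the single water-assimilation indicator by the conservative minimum
(default) or the same RMS rule as the tree (`rms`).

**Ecosystem services.** Sum LAI = Σ L_i A_i / A_total with empirical mean
LAI per land-cover type (Farmland 3.0, Garden 3.0, Woodland 5.0, Grassland
2.0, Wetland 6.5, Construction 0.5, Other 1.0; overridable). Hard-coral
coverage is 100·n/M per point-intercept transect — the product form
sometimes printed for this estimator cannot yield a percentage and the
variable definitions force the ratio. Fish density is N/(2LW) per belt
transect, the 2 covering both sides of the line. Multi-transect surveys
pool by effort-weighted mean (equal weights by default); species counts
pass through as raw indicator values with no estimator.

## Synthetic data

The generator emulates a small inhabited reef island: a 48 × 48 grid of
10 m cells (≈ 0.23 km², the size class of the ZSI case), four suitability
factors graded iid on {1, 3, 5} with a 10% forbidden fraction per factor,
a land cover dominated by woodland (35%) and construction (25%), true
hard-coral cover 30%, true fish density 0.2 fish/m², and a 3-area ×
4-source response field with exponential index-distance decay. Transect
counts are exact binomial (point-intercept) and Poisson (belt) draws, so
estimator unbiasedness is testable against sampling theory. Standards in
generated LP instances are placed between the zero-load and max-load
responses, guaranteeing feasibility with some probability of binding
quality constraints.

What the generator does **not** emulate: spatial autocorrelation in
rasters, overdispersion or observer error in surveys, correlated
pollutant plumes, or any real hydrodynamics — passing tests demonstrate
correctness of the estimators and aggregation, not realism of field data.

Randomness: one root seed per call; each generator draws from
`default_rng([seed, stream_id])` with a fixed per-generator stream id, so
outputs are bit-reproducible and adding a generator never perturbs
existing streams.

The ZSI 2017 fixture materializes each published ratio d as the pair
(p, s) = (1 − d, 1), because the raw pressure/support values behind most
indicators were never published; this keeps the whole chain from Eq-level
ratios to the overall index executable. The fixture notes one published
inconsistency (environmental-protection investment listed with degree 5
beside ratio 0.08); the package reports the arithmetically consistent 8.

## Numerical choices

* Weight sums checked to 1e−9; LP feasibility/binding tolerance 1e−9
  relative; tree-oracle agreement asserted to 1e−12 relative.
* d = 0 classifies as full-loaded even with a warning buffer configured.
* Aggregating an empty node is a structural error, never a silent skip.
* Overall ratios are computed from unrounded dimension ratios; rounding
  happens only at display.

## Problem sizes

The test suite runs the case study (11 indicators), 200 random LP
instances of up to 4 sources × 3 areas against a brute-force
vertex-enumeration oracle, 1000 random trees for aggregation invariants,
1000 simulated transects for estimator recovery (3-standard-error bands),
and 8 × 8 random rasters against a per-cell loop oracle. These sizes give
the oracles exhaustive coverage while keeping the whole suite in seconds.

## Known limitations

* No stakeholder weight elicitation, multi-year trends, or spatial
  carrying-capacity mapping.
* The hydrodynamic model that produces the response matrix is out of
  scope: P is an input.
* Pressure-end targets (planning values, reef-health standards) are
  config inputs; the package never invents them.
* Units are tags, not dimensioned quantities; mismatches across a
  pressure/support pair are the user's responsibility beyond the tag
  check.
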