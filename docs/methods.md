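# Methods

## The atom-specific construction

For a centre C&alpha; atom and an element-specific pair P ∈ {CC, CN, CO}
the package builds two point clouds: the *full* cloud (all atoms of the
pair subset strictly within the cutoff radius of the centre, centre
included at distance 0) and the *reduced* cloud (the same set minus the
centre atom).  Under `pair_union` (the default) the pair subset contains
all atoms whose element is either member of the pair; the alternative
`center_plus_partner` keeps only the partner element plus the centre.
Both clouds are filtered identically and their persistence diagrams are
compared per homology dimension with Bottleneck or Wasserstein
distances.  Because the clouds differ by exactly one point, the
dimension-0 diagrams always differ by one interval; the diagram distance
is therefore never trivially zero unless the removed atom is topologically
invisible (e.g. coincident with another atom).

The cutoff defaults to 11 Å everywhere (features, packing density,
clouds); it is exposed for cutoff-sweep experiments but the 60-feature
layout assumes it.

## Filtrations

* **Euclidean**: pairwise distances, capped at the cutoff radius r_c.
  The cloud has radius < r_c around its centre, so every structural
  death occurs below the 2·r_c diameter bound and essential classes need
  a finite cap for downstream metrics.
* **Kernel**: M[n,m] = 1 − Φ(d; η, power) with exponential
  (Φ = e^{−(d/η)^κ}) or Lorentz (Φ = 1/(1+(d/η)^ν)) radial basis
  functions; entries lie in [0, 1) and the cap is 1.  η (Å) sets the
  resolution scale: large η (Lorentz η = 21, ν = 5; exponential η = 10,
  κ = 1 — the two production parameter sets) sees the neighbourhood
  coarsely, small η (exponential η = 2) resolves contact-scale detail.
  Since 1 − Φ is strictly increasing in distance, kernel filtrations
  reorder nothing: they reparametrise the same sequence of complexes,
  which is tested via the dimension-0 merge order.

Matrix symmetry is enforced by construction (entries computed once and
mirrored), the diagonal is exactly zero, and arithmetic is double
precision throughout.

## Persistence computation

The production path computes Vietoris–Rips persistent homology over Z2
up to dimension 2 by persistent cohomology with the clearing
optimisation: dimension-0 pairs from a union-find sweep over sorted
edges; dimension-1 (and 2) pairs by reducing the coboundary columns of
the cycle-creating simplices in reverse filtration order, with sparse
set-based columns whose pivot is the earliest cofacet.  Simplices are
ordered by (filtration value, dimension, lexicographic vertices), a
total order in which faces always precede cofaces.  A deliberately
naive, fully enumerated Z2 boundary-matrix column reduction
(`reduce_boundary_matrix`) defines the contract; the test suite checks
exact multiset equality of the two paths on random clouds (dimensions
0–2) and the boundary-of-boundary identity.

Conventions:

* Essential classes are reported with death = cap (1 for kernel, r_c for
  Euclidean filtrations), never dropped and never infinite, because the
  diagram metrics need finite coordinates and the conjugated pairs
  always differ by one essential dimension-0 class.
* Intervals with birth = death are dropped on output; they lie on the
  diagonal, so dropping them changes no matching-based distance.
* Production features use dimensions {0, 1}; dimension 2 is available
  and used by the manifold fixtures.

## Diagram metrics and transforms

Bottleneck and Wasserstein (order p ≥ 1, default p = 1; the order is a
documented package default, configurable) optimise over
diagonal-augmented matchings: unmatched points pay their L∞ distance to
the diagonal, |death − birth| / 2.  Wasserstein is solved exactly as a
linear assignment over the (n+m)×(n+m) augmented cost matrix; Bottleneck
by binary search over the candidate costs with a maximum-bipartite-
matching feasibility test — both exact, and both verified against
exhaustive enumeration of all augmented matchings on small diagrams.

Diagram modifications re-weight short-persistence classes before the
distance is taken: "y-axis rotated clockwise by θ" (θ = 30° or 60°) is
implemented as a counterclockwise rotation of the diagram points about
the origin, and "diagonal reflection" swaps (birth, death).  After any
transform, diagonal costs remain |death − birth| / 2 regardless of the
side of the diagonal on which a point lands.  The rotation centre and
sense are a convention; any fixed invertible plane map achieves the
stated purpose, and this one is frozen and documented so features are
reproducible.

## The feature set

60 topological features per C&alpha;: five configuration rows (Lorentz
η = 21 ν = 5 unchanged; exponential η = 10 κ = 1 unchanged; exponential
η = 2 κ = 1 under diagonal reflection, 30° rotation, 60° rotation), each
crossed with metric {Bottleneck, Wasserstein} × dimension {0, 1} × pair
{CC, CN, CO}.  The order is frozen (row-major, metric before dimension
before pair) and encoded in the column names so trained models stay
portable.  Conjugated diagrams are computed once per (kernel, pair) and
shared across transforms/metrics/dimensions.

The (8, 10, 3) image tensor sweeps exponential kernels over
η ∈ {1, 2, 3, 4, 5, 10, 15, 20} (rows) × κ ∈ {1..10} (columns) per
element-pair channel.  The scalar per cell is the conjugated-diagram
distance under that kernel; the metric/dimension of that scalar is not
pinned by the construction, so the package defaults to dimension-0
Wasserstein (p = 1) — cheap (dimension 0 only needs the union-find
sweep) and sensitive to the removed atom's contact shell — and exposes
the choice.

Auxiliary features: packing density — defined here as the count of heavy
atoms strictly within the cutoff (no formula is canonical in the
flexibility literature; a kernel-weighted variant would be the rigidity
index, and the count is the simplest reading); occupancy; amino-acid
type as a 21-way one-hot (20 standard residues + other); secondary
structure (helix/strand/turn/coil, consumed from STRIDE ASG files, with
3₁₀ and π helices counted as helix and bridges as strand); and the
protein-level R-value, resolution and heavy-atom count.

## Structure input

Model 1 only (single-conformer semantics; the method targets X-ray
structures), HETATM and hydrogens excluded, alternate locations resolved
to highest occupancy (first on tie), all chains pooled.  Elements come
from the element column when present, else from the atom name.
C&alpha; B-factors equal to zero are unphysical and are flagged;
dataset-level policy (drop the protein, as in the reference data
hygiene, or just the residue) is the caller's choice.

## Models

* **Per-protein least squares**: linear model with intercept of
  B-factors on the 60 features, minimum-norm solution.  With ≤ 61 rows
  (or a rank-deficient design — common, since several features vanish
  identically on sparse neighbourhoods) the fit can interpolate; it is
  flagged `underdetermined`, and a PCC of 1 in that regime should be
  read as capacity, not signal.
* **GBT**: scikit-learn gradient boosting with quantile loss α = 0.975,
  500 estimators, learning rate 0.25, depth 4, min samples leaf/split 9.
  The upper-quantile objective is kept as specified (a faithful
  reproduction choice); Pearson evaluation is shift-invariant, so the
  quantile offset does not distort the score.
* **CNN**: implemented directly in numpy (no deep-learning framework is
  a dependency): two 2×2 valid convolutions with ReLU, dropout 0.5, a
  channelwise dense layer, flatten, concatenation with the auxiliary
  features, then dense 218 → dropout 0.5 → dense 100 → dropout 0.25 →
  dense 10 → one linear output; MSE loss, Adam at 0.001, batch size
  1000, 1000 epochs by default (tests train far smaller configurations).
  The convolution filter counts and the width of the image dense layer
  are not pinned by the architecture description; the defaults (8, 16
  filters; width 8) keep the flattened image code comparable in size to
  the auxiliary block.  Backpropagation is verified against finite
  differences.  Dropout uses inverted scaling; all randomness flows from
  one seed.
* **Consensus**: elementwise mean of two aligned prediction series.
* **Leave-one-protein-out**: every row of the held-out protein is
  excluded from training; image standardisation (per-channel mean 0,
  variance 1 — per-channel rather than global, since the three element
  channels have different magnitudes) is fitted on training images only.
  Size-class averages (small/medium/large) are reported only when the
  caller supplies boundaries; none are hard-coded because no canonical
  thresholds exist.

The Pearson correlation is computed directly from centred sums; a
constant series raises an explicit error rather than returning 0.

## Synthetic data

The generators define the conditions under which the package's
statistical claims are tested.

* **Manifolds**: `sample_torus` is a deterministic n×n angular grid
  (default radii R = 3, r = 1, separating the two 1-cycle scales from
  grid noise); `sample_circle` draws seeded uniform angles;
  `sample_sphere` uses a Fibonacci lattice composed with a seed-derived
  random rotation.  The lattice is a coverage requirement, not a
  convenience: detecting the 2-cavity requires the covering radius to
  sit well below the feature scale, and i.i.d. draws leave gaps whose
  spurious loops decay too slowly with n (measured maximum spurious
  dimension-1 persistence 0.26 at n = 400 i.i.d. vs 0.14 at n = 150
  lattice).  Fixture assertions call a bar "long" when its persistence
  exceeds 25% of the filtration cap; the torus loop count uses the
  absolute threshold 1.0.
* **Fixture caps**: the torus computation caps the Euclidean filtration
  at 2.0 (the tube diameter).  Measured deaths of the non-essential
  classes are 1.78 (minor loop) and 1.90 (cavity); the major-circle loop
  is reported as essential at the cap.  Capping only shortens bars, so
  the count of loops with persistence > 1.0 is conservative and equal to
  its uncapped value, at a small fraction of the cost of a
  diameter-capped complex.  Circle: n = 40, cap 2.0 (the loop dies at
  √3 · radius).  Sphere: n = 150, cap 1.2.
* **Pseudo-proteins**: self-avoiding C&alpha; walks with exact 3.8 Å
  consecutive spacing and a 3.5 Å non-consecutive exclusion, one side
  atom per residue cycling C/N/O at 1.5–2.5 Å (so every element pair is
  populated while neighbourhood clouds stay small enough for fast
  dimension-1 persistence), residue names cycling the 20 standard amino
  acids, occupancy 1, and headers (resolution 2.0 Å, R-value 0.18) so
  global features round-trip.  B-factor laws: `linear_in_features`
  (B = 20 + w·f with weights drawn once from `law_seed`, shared across
  an ensemble, plus Gaussian noise with σ = 5% of the within-protein
  signal SD by default) and `inverse_packing`
  (B ∝ 1/(1 + packing density), the mass-and-spring intuition that
  flexibility anti-correlates with crowding).

What the pseudo-proteins deliberately lack: real side-chain geometry,
rotamers, element abundances, chain topology beyond self-avoidance, and
any physical force field.  Passing the recovery tests therefore shows
that the pipeline is self-consistent — features are informative about
B-factors generated from those same features or from local density, and
the blind-prediction machinery learns a law that generalises across
chains — not that the features predict experimental B-factors at any
particular accuracy; that claim requires real structures.

## Problem sizes used by the tests and acceptance script

Torus 400 points (cap 2.0, ~15 s); sphere 150, circle 40; oracle
equivalence on 100 random clouds of ≤ 7 points; metric enumeration on
200 diagram pairs of ≤ 5 points; least-squares recovery on one
80-residue pseudo-protein; leave-one-protein-out GBT on five 30-residue
pseudo-proteins sharing one linear law.  The full suite runs in under
two minutes on one CPU.

## Known limitations

* Kernel filtrations on a cloud of n points have every pair below the
  cap, so dimension-1 persistence enumerates all C(n,3) triangles;
  neighbourhoods of several hundred atoms (large real proteins at
  pair_union with C-rich environments) make the 60-feature vector
  noticeably slower than on the test fixtures.
* The Bottleneck feasibility search rebuilds its bipartite matching per
  threshold; fine for conjugated diagrams (tens of points), not tuned
  for diagrams with thousands of points.
* Multi-model (NMR) files use model 1 only; mmCIF is not supported.
* The quantile-loss GBT predicts an upper quantile by design; absolute
  predicted values are biased high even though correlations are
  unaffected.
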