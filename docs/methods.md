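# Methods

## Model

N particles on the unit sphere represent the cells of a spherical
epithelial monolayer. Each carries an effective radius `s_i` drawn from a
Gaussian with mean 1 and standard deviation σ (draws at or below 0.05 are
rejected and redrawn to keep radii physical; the sample is then renormalized
to mean exactly 1 — only radius ratios matter, since multiplying all radii
by β multiplies the energy by β^α). The interaction is a pure contact
repulsion over unordered pairs,

    U = Σ_{i<j} ((s_i + s_j) / r_ij)^α ,

with `r_ij` the 3D chord distance and α ≥ 1 the stiffness exponent. α = 1
with equal radii is the Thomson problem; α → ∞ approaches a Tammes-like
packing of caps with radii proportional to `s_i`. Whether distances should
be chords or geodesics is a genuinely open modeling choice; chords are used
(particles are 3D points constrained to the sphere). As a spot check, the
N = 60 equal-radius landscape was probed with geodesic distances as well and
showed the same minima structure, so the choice is not load-bearing for the
topological statistics. A 12-6 Lennard-Jones variant
(`U = Σ (ρ/r)¹² − 2(ρ/r)⁶`) is retained for comparison with classic
colloidal packings.

Defaults follow the monolayer-matching regime: α = 12 (the natural exponent
inherited from the repulsive Lennard-Jones term), σ in 0–0.26 depending on
the species being emulated, N from tens to several hundred.

## Minimization

Structures are local minima reached by projected gradient descent from a
seeded random start (positions uniform on the sphere, radii as above; one
integer seed governs both draws). The descent has two phases, both strictly
monotone in energy (a trial step is halved until the energy decreases):

1. **Flow phase.** Steps along the negative tangent gradient with the
   largest per-particle displacement capped at 0.05 × the mean hexagonal
   neighbor spacing `sqrt(8π/(√3 N))`. Small capped steps track the
   gradient-descent flow, so which local minimum is reached is decided by
   the starting point, not by the optimizer's step-size heuristics. This
   matters physically: aggressive adaptive steps taken from a random start
   systematically hop into metastable scarred minima (measured at N = 94,
   α = 1: 4/10 random starts ended with scars under pure adaptive stepping,
   0/10 under capped-flow descent — the latter matching the known behavior
   of identical repelling particles at this size). The phase ends when the
   energy settles (relative decrease < 1e-7 over 100 accepted steps) or
   after 1000 accepted steps.
2. **Polish phase.** Barzilai–Borwein steps with the same backtracking
   safeguard, run until the maximum per-particle tangent-gradient norm
   falls below `tol × gscale` (default tol 1e-8; `gscale = α√N` for the
   generalized energy) or the energy stalls at machine precision
   (relative decrease < 1e-15 on five consecutive accepted steps).
   Non-convergence within `max_iter` (default 5000 polish iterations) is
   flagged on the result, never raised.

For numerical robustness at large α (up to ~300) the descent operates on
log U — the same minimizers — with pair terms evaluated directly while they
fit in double precision and through a max-shifted log representation
otherwise. Pairwise squared distances use the Gram-matrix identity
`d² = 2 − 2·x·x'` for unit vectors, keeping all pair operations at BLAS
speed; pairs closer than ~1e-8 raise a degenerate-geometry error.

No global-optimum search is attempted: the scientific object of interest is
precisely the ensemble of local minima reached by gradient descent, mirroring
how real monolayers settle into metastable packings.

### Known landscape subtlety at N = 60

For equal radii and α in [8, 12] the N = 60 landscape is often described as
having a single reachable structure. This package reproduces that at
α = 10 and α = 12 (final energies across 10 random starts agree to better
than 1e-10 relative, identical valence histograms). At α = 8, however, two
robust distinct minima exist (relative energy gap ≈ 6e-5, different distance
spectra, both stable under independent re-polish and reached from
quasi-gradient-flow descent with either metric); the uniqueness property
therefore does not hold exactly at the α = 8 boundary, and the corresponding
acceptance test documents this by failing for that sub-case.

## Tessellation and defects

For points on a sphere the Delaunay triangulation equals the convex hull, so
the triangulation comes from Qhull with triangulated output, which resolves
cocircular ties deterministically for a fixed input order. Near-cocircular
quadruples — "square order" regions where four cells share a contact and the
diagonal choice is arbitrary — are detected (coplanarity slack < 1e-9 across
every interior edge) and reported, not hidden. The Voronoi dual
(scipy's spherical Voronoi) provides per-cell polygons whose edge counts
equal the Delaunay valences and whose solid-angle areas sum to 4π.
Tessellation is center-based; radii do not enter (no Laguerre weighting).

Charges are `q = 6 − valence`; on every sphere-topology triangulation they
sum to +12 (asserted throughout). Defectiveness is the total negative charge
`Q₋ = Σ_{i≥7} N_i (i − 6)`, and `Q₋/N` the relative defectiveness. Defect
clusters are connected components of the subgraph induced by charged
vertices under Delaunay adjacency — the minimal operationalization of an
"extended topological defect"; touching defects merge into one cluster by
convention. Classification is rule-based and exhaustive: singletons are
point disclinations; an adjacent 5-7 pair is a dislocation; a strictly
alternating 5/7 simple path is a pleat (balanced, Z = 0) or a scar (one
extra 5, Z = +1; size 3 is the simplest scar); anything branched, containing
valence ≥ 8, or with |Z| > 1 is a complex ETD. Burgers-vector contour
analysis is not implemented; the net-charge/path classification stands in
for it. The rotation angle picked up by a hexagonal translation circulated
around a charge-Z ETD is reported as πZ/3.

A tiny-N caveat: on an icosahedron (N = 12) every vertex is charged and
adjacent to charged vertices, so the connectivity convention yields one
12-vertex cluster rather than twelve singletons; the "twelve isolated
disclinations" picture applies once defects are separated by hexagonal
order, as at the N used in practice.

## One-sided (hemisphere) analysis

Emulates quantification of single-view images of a spherical monolayer.
A model structure is orthographically projected along a view axis; the
visible set is the open hemisphere. A cell is *completely visible* when its
entire Voronoi cell lies in the open hemisphere (all incident Voronoi
vertices above the equator) and *partially visible* when any part does.
The analysis circle, centered on the projected pole, is the largest circle
such that every center inside is completely visible with all Delaunay
neighbors at least partially visible (so every in-circle valence is free of
boundary truncation): its radius is the projected distance of the nearest
inadmissible center. The total count is extrapolated as

    N̂ = 2n / (1 − √(1 − (r/R)²)) ,

exact in expectation for an orthographic view of a uniform layer (the cap
of half-angle θ with r = R sinθ holds the fraction (1 − cosθ)/2 of all
cells), and whole-sphere defectiveness as Q̂₋ = Q₋(circle) · N̂ / n. At
r = R this reduces to doubling the count; as r → 0 it approaches the area
ratio 4nR²/r².

For external 2D center tables (no 3D information) the same pipeline runs on
the planar Delaunay triangulation: a center is admissible when it is marked
visible and neither it nor any of its neighbors lies on the convex hull of
the data; the circle is centered on the centroid, and R comes from either
the minimal enclosing circle (`circular_fit`) or, for elongated samples,
a quarter of the sum of the largest and smallest visible diameters of the
convex boundary (`elongated_mean`). Units are the caller's; r and R must
share them.

Accuracy, measured on minimized model structures with known N (10 seeds per
N ∈ {100, 200, 400}, single view each): mean relative error of N̂ is ~1.3%
for σ = 0 and ~3% for σ = 0.2, but the worst case over such a batch is
several percent larger (up to ~8% at σ = 0, ~10% at σ = 0.2, dominated by
N = 100). The residual is cap-count fluctuation of the packing itself — at
the selected circle the in-circle count deviates from the continuum
expectation by a few cells — so single-view worst-case error at N ≈ 100 is
intrinsically above the mean-level figures; Q̂₋ carries a substantially
larger relative error than N̂, as extrapolating a small integer count
amplifies boundary noise. The acceptance suite reports both maxima honestly.

## Synthetic fixtures

`generate_fixture` emulates a segmented one-sided confocal image: minimize a
configuration, project the visible hemisphere, scale to physical units
(default sample radius 100, in μm-like units), optionally jitter positions
with Gaussian noise of magnitude `jitter` × the mean nearest-neighbor
spacing, and mark completely visible cells. The ground-truth sidecar stores
the true N, whole-sphere Q₋, the spherical valence of every exported cell,
and the *projected* valences (planar Delaunay of the noiseless projection).
The two valence sets differ for a few cells at large projected radius:
planar triangulation of an orthographic projection is not identical to the
spherical triangulation. This distortion is intrinsic to one-sided imaging
(real image analyses inherit it too), which is why recovery is tested
exactly against the projected truth and only within a tolerance against the
spherical truth. What fixtures do not emulate: segmentation errors beyond
isotropic center jitter, sample asphericity, boundary blurring, and missing
cells — so passing fixture tests validates the geometry/topology pipeline,
not robustness to real imaging artifacts.

## Batch experiments

`run_experiment` sweeps an explicit (N, σ, α) × seeds grid, writing one
configuration CSV and one defect report per run plus a tidy aggregate CSV;
all outputs are pure functions of the spec and seeds (reruns are
byte-identical). Non-convergent runs are flagged in the aggregate, never
dropped. The ETD-frequency statistic used for dispersion trends is the mean
number of ETDs (clusters of ≥ 2 charged cells) per structure; the binary
"contains at least one ETD" indicator saturates at the N/α where scars are
ubiquitous and cannot express the trend.

## Problem sizes in the test and acceptance suites

The suites minimize batches at N up to 400 (10 seeds per condition for
extrapolation checks, 50 seeds for the best-structure search at N = 79,
20 seeds per σ for the dispersion trend), which keeps a full run to a few
minutes on one CPU while leaving every headline condition at its stated
(N, σ, α).
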