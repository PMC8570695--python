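# Methods

`epi3d` analyses the three-dimensional neighbour organisation of
pseudostratified epithelia from labelled cross-sections, and ships a
synthetic-tissue generator so the whole pipeline can be exercised and
tested without microscopy data. This note describes the models, the
generator, the numerical choices, and what the synthetic results do and do
not say about real tissue.

## Polygonal lattice statistics

A tissue cross-section is a polygonal lattice. On a contiguous lattice
with three-way vertices, Euler's polyhedron formula forces the mean
neighbour number to six (`n̄ = 6` exactly on a torus; slightly below six
on bounded patches because border cells are excluded from statistics but
still truncate their neighbours' rings). Around that topological
constraint, energy-minimising packings follow two phenomenological laws:

* **Aboav-Weaire**: the neighbours of an n-sided cell have on average
  `m(n) = 5 + 8/n` neighbours;
* **Lewis**: the mean area of the n-sided class satisfies
  `A_n/Ā = (n − 2)/4`, or, at high area variability, the quadratic
  relation `A_n/Ā = (n/6)·tan(π/6)/tan(π/n)` under which all side lengths
  become equal.

`layer_morphometrics` computes neighbour frequencies, `n̄`, the area CV
(sample standard deviation over mean, n−1 denominator), the observed
`m(n)` and `A_n/Ā` tables with SEMs, the hexagon fraction, and — where
polygon vertices are available — per-class internal angles and
normalised side lengths. Conventions: two cells are neighbours when they
share at least `min_contact = 2` four-connected boundary pixel pairs
(single-pixel corner contacts would fabricate four-way junctions); cells
with fewer than three neighbours are treated as segmentation artefacts
and excluded; border cells are excluded from statistics but their
neighbour numbers still enter the Aboav-Weaire sums of interior cells.

## Predicted class distribution versus area CV

`organisation_theory` converts an area CV into a predicted polygon-class
distribution: normalised areas follow a positive distribution with unit
mean and standard deviation CV (truncated normal renormalised to unit
mean by default; gamma as an alternative), and each cell adopts the class
whose law-predicted area is nearest (bin edges at arithmetic midpoints of
consecutive class areas, classes capped to n ∈ [3, 16], with the boundary
classes absorbing the tails). Because every cell is assigned a class and
the distribution has unit mean, the mean cell area across classes equals
the population mean identically — the self-consistency condition holds at
unit scale, and no iterative rescaling is applied. An explicit rescale of
the class areas was evaluated and rejected: with the convex quadratic law
it drags the bin centres away from the distribution mean and makes the
predicted hexagon fraction non-monotone in CV, contrary to the behaviour
of the published prediction curves. The prediction refuses to answer when
more than 20% of the area mass falls outside the supported classes
(reachable with the heavily skewed gamma family).

## Lateral T1 transitions

A lateral T1 transition (T1L) is **any** change of the neighbour-ID set
between adjacent sections of a cell column — including partner swaps that
conserve the neighbour count, which scutoid-type exchanges produce. The
exchange point is unresolved between the two sections, so events sit at
the midpoint of the bounding z values. Opaque neighbour IDs (contacts
with unsegmented surroundings) are retained so exchanges with them are
still detected.

Per-cell counts are summarised by the dispersion index σ²/µ (unity under
a Poisson law) and a Pearson chi-squared goodness-of-fit test against
Poisson(µ̂), with tail bins merged until every expected count is ≥ 5 and
dof = bins − 2. Inter-transition distances use interior segments only
when requested (the first and last segment of each cell are dropped to
reduce boundary effects). The mean relative position carries a normal
95% CI. The mean transition count is reported as total/N throughout.

The area-change profile bins all adjacent-section interfaces by Δarea and
reports the fraction of events gaining/keeping/losing neighbours per bin,
both among events and as per-interface rates, for cellular or nuclear
cross-sections.

## Curvature model

Collapsed epithelial tubes have nearly elliptic apical and basal
boundaries. For cells at the cusp (minor vertex), the local radius of
curvature of an ellipse with semi-axes a ≥ b is a²/b. Averaged apical
and basal semi-axes interpolate linearly, giving

    R(x) = (a_ap + x·(a_ba − a_ap))² / (b_ap + x·(b_ba − b_ap)),

with x ∈ [0, 1] the relative apical-basal position. Every pair of
consecutive transitions of a cell then has a curvature fold change
R2/R1, with R2 the more basal radius (fold > 1 when the basal side is
flatter).

Ellipses are fitted by the direct least-squares conic method in its
numerically stable block formulation (centre-and-scale preconditioning,
constraint 4AC − B² = 1), with the RMS radial distance reported as the
residual. Degenerate or hyperbolic inputs are rejected.

The neighbour-number-dependent prediction of a curvature-driven
(scutoid) mechanism is pluggable; the shipped default assumes the
neighbour number is proportional to the local circumference, so one
neighbour gain requires a fold change of (n + 1)/n — strictly decreasing
in n. This default is a modelling assumption of this package, stated as
such, not a derived result.

## Nuclear morphometrics

Nuclear volume, centre and principal semi-axes come from voxel counts
and the second-moment (inertia) tensor of the label mask (for a solid
ellipsoid the covariance eigenvalue along a semi-axis a is a²/5).
Ellipticity is defined as 1 − (shortest/longest principal semi-axis):
spheres score 0, elongated nuclei approach 1. The definition is isolated
in one function because imaging suites do not agree on a convention;
absolute values are therefore not comparable across tools — only
directions of effects are. The apical-versus-middle ellipticity
comparison is a one-sided Welch t-test (Satterthwaite dof) of nuclei
with centre_z ∈ [0, 0.25] (closed interval) against (0.25, 0.75].
Idealised diameters treat the cell as a cylinder of its measured height
and the nucleus as a sphere; when the spherical nuclear diameter exceeds
the cylindrical cell diameter, nuclei must deform to fit.

## Synthetic tissue generator

The generator emulates a segmented pseudostratified epithelium
statistically rather than mechanically — there is no force balance, cell
division or growth.

**Geometry.** Default: 140 columnar cells on a periodic 60×60 µm domain
(mean cross-section ≈ 26 µm², cell volume ≈ 640 µm³), tissue height
25 µm, 15 sections (≈ 1.7 µm spacing, matching light-sheet section
spacing typical for such datasets). Seed points are Lloyd-relaxed random
points (or an exact triangular lattice for degenerate regular tests) and
are shared across sections with small AR(1)-correlated jitter
(σ = 0.25 µm, ρ = 0.7) so columns stay contiguous.

**Areas.** Each cell has a baseline drawn once from a gamma distribution
with CV `base_area_cv` (default 0.3, clipped to [0.25, 4]× the mean), and
a nucleus: an ellipsoid elongated along the apical-basal axis
(aspect 1.5) whose volume is `nuclear_volume_fraction` (default 0.55) of
the cell volume. Nuclear centres follow an IKNM-flavoured distribution:
80% uniform on [0.15, 0.85], 20% apical excess on [0, 0.25] (mitoses are
apical), clamped so the ellipsoid fits inside the tissue. The per-layer
target area of a cell is its baseline share plus its nucleus's elliptic
cross-section at that depth, rescaled so each layer sums to the domain
area. Where the summed rigid-ellipsoid cross-sections would overfill a
layer, they are compressed laterally to leave at least 8% cytoplasm —
real nuclei deform; a layer needing more than 2-fold compression is an
infeasible packing and raises an error naming the layer. Every section
keeps a floor of 1.5 µm² (thin cytoplasmic stalks).

**Tessellation.** Each section is a power diagram: pixel p belongs to the
cell minimising ‖p − s_i‖² − w_i, evaluated on a raster (0.4 µm pixels by
default) so label images fall out directly and total area is conserved
exactly. Weights are tuned by the damped fixed-point iteration
w ← w + η(target − realised) with η = 0.4, annealed after a constant
phase to settle raster quantisation and warm-started from the previous
layer; each cell's step is additionally scaled by its squared relative
nearest-seed spacing, because a boundary between seeds a distance d apart
shifts by Δw/(2d) and tightly spaced pairs otherwise oscillate. Layers
that fail the first schedule are retried from zero weights with longer
constant phases and slower annealing. Convergence means a mean absolute
area error below 1% with no empty cells; a layer that exhausts all
schedules raises an error reporting the residual. Pixel
assignment prunes candidates to the 24 nearest seeds (toroidal KD-tree on
periodic domains) with an exactness guard that re-evaluates ambiguous
pixels against all cells. Adjacency is **not** read off the raster:
it comes from the exact regular (weighted Delaunay) triangulation of the
tuned diagram via the convex-hull lifting, tiled 3×3 for periodic
domains — this is what makes the toroidal mean neighbour number exactly
six at every layer. All randomness derives from a single seed;
regeneration is bit-identical.

**What the generator reproduces and what it does not.** It reproduces:
exact Euler topology; Aboav-Weaire behaviour within ~0.3 of 5 + 8/n for
the dominant classes on ≥400-cell layers; strong cell-nucleus coupling
(per-layer area correlations ≥ 0.8); the direction of the
area-change → T1 relation (gain fraction rises monotonically with
Δarea); mean nuclear/cell volume ratio within a few percent of the
configured fraction. It does **not** reproduce: the Poisson dispersion
of per-cell T1L counts (the generator's counts are underdispersed,
σ²/µ ≈ 0.5, because nuclear passage deterministically schedules several
transitions per cell — Poisson behaviour is exercised separately with
`generate_poisson_columns`); realistic per-layer CV bounds (nucleus-dense
mid-layers reach CV ≈ 0.9); rounder apical nuclei (all nuclei share one
aspect ratio, so the ellipticity-position test on synthetic tissue
retains the null — the test's sensitivity is validated on dedicated
effect fixtures); real mitotic dynamics or temporal evolution. The mean
T1L count per cell (~7.5 at default settings) sits above typical measured
means because the exact triangulation registers every sliver-face
exchange, however small the shared face.

**Poisson columns.** `generate_poisson_columns` builds abstract columns
whose number of neighbour-set changes is exactly Poisson: k ~ Poisson(rate)
distinct interfaces chosen uniformly, each swapping, adding or dropping
one neighbour ID. It isolates the T1 statistics from the tessellation.

## Numerical and interface choices

* Coordinates: z is relative apical→basal in [0, 1]; layer 0 is apical.
* CSVs are comma-separated UTF-8 with header rows; ID sets are
  semicolon-joined. Label stacks are multi-page int32 TIFFs, page 0
  apical.
* Degenerate inputs: periodic domains require ≥ 7 cells; layers need at
  least 3 sections; ellipse fits need ≥ 6 non-collinear points; the
  Poisson GoF needs ≥ 20 cells and ≥ 3 bins after merging.
* Co-circular seed configurations (regular lattices) degenerate the
  lifted hull; qhull's deterministic joggle is applied as a fallback.
* Problem sizes in tests and analyses (140-cell tissues, a 600-cell
  bounded layer, 500 Poisson columns, 200 GoF replicates) were chosen so
  each statistic's sampling error is small relative to the tolerance it
  is checked against.

## Known limitations

* The raster power diagram approximates cell boundaries at pixel
  resolution; areas converge to targets within 1%, not exactly.
* `predict_class_distribution` is a nearest-class binning model; it does
  not re-derive the surface-energy minimisation the laws descend from.
* The curvature prediction's closed form is an explicit default, not a
  derived quantity; alternative forms can be registered.
* Bounded (non-periodic) tissues exclude border cells from statistics,
  which biases `n̄` slightly below six; this matches what segmentation
  pipelines do but makes small bounded layers noisy.
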