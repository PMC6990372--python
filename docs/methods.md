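# Methods

`qrscale` isolates one mechanism — left-ventricular (LV) size — and asks what
QRS-duration (QRSd) threshold in a female LV corresponds, under identical
tissue properties, to a given threshold in a male LV. This note documents the
model, the numerical choices, and what the synthetic geometry does and does
not represent.

## Activation model

Electrical activation is modeled with the anisotropic eikonal equation
|∇t|_M = 1: the activation time t(x) is the first arrival under a per-element
squared-speed tensor

    M = v_f² f fᵀ + v_t² (t₁t₁ᵀ + t₂t₂ᵀ),   v_t = ρ · v_f,

with fiber direction f and transversely isotropic cross-fiber speed
(anisotropy ratio ρ = 0.4 by default). Because the two transverse speeds are
equal, sheet orientation is irrelevant and no sheet-angle rule is
implemented. Units are fixed package-wide — mm, ms, m/s — exploiting
1 m/s = 1 mm/ms so no conversion constants appear in the numerics.

Two tissue regions exist: bulk myocardium, and a fast endocardial layer
(elements whose centroid lies within 1 mm of the endocardial surface) whose
tensor is scaled by the square of a sixfold speedup. The speedup multiplies
the full tensor by default, preserving ρ; a `speedup_mode="longitudinal"`
switch restricts it to the fiber direction, since the original description
("sixfold increased CV") does not distinguish the two. The layer is a
surrogate for Purkinje-mediated rapid endocardial spread; no His–Purkinje
network topology is modeled.

QRSd is defined as total LV activation time: latest activation minus the
(zero) stimulus onset. No repolarization, ECG lead fields, scar, or
reaction–diffusion electrophysiology.

### Eikonal solver

The solver is a heap-ordered label-correcting scheme with closed-form local
updates. For an unknown vertex opposite a tet face, the minimization of
(linear interpolation on the face) + (metric distance) has the closed-form
solution q² (1 − sᵀG⁻¹s) = c − hᵀG⁻¹h in the face's metric Gram matrix;
rejected (out-of-simplex) face solutions fall back to the analytic edge and
vertex minimizers. Every accepted update is the travel time of a realizable
path, so iterates upper-bound the true first arrival; this also covers obtuse
tets without virtual splitting. Nodes pop in (time, node-index) order —
deterministic and bit-reproducible — and re-insert on improvement, since
anisotropy can break strict Dijkstra causality. A full verification pass
recomputes every node and re-seeds any improvement above the convergence
tolerance (10⁻⁶ ms max node update); convergence typically takes one or two
rounds.

Near an isolated point stimulus the planar-front assumption of the local
solver carries an O(h) curvature error. Nodes within four edge rings of a
point source — restricted to the region where the metric equals the source
element's — are initialized with the exact straight-line metric distance and
frozen. With this, arrival times on a 1 mm isotropic slab match Euclidean
distance within 1.4%, and principal-axis anisotropic arrivals are exact to
discretization.

An independent cross-check is a Dijkstra shortest path on the graph of mesh
edges plus per-tet edge-midpoint augmentations (complete graph on 4 vertices
+ 6 midpoints per tet, shared edges taking the minimum weight over adjacent
tets). Every graph path is realizable, so the oracle upper-bounds the true
solution; empirically it stays within 8% of the eikonal solve away from the
source singularity (beyond three mean edge lengths).

## Geometry and coordinates

Meshes are tetrahedral with boundary triangles labeled ENDO/EPI/BASE. Two
text formats are supported: legacy ASCII VTK (tets followed by boundary
triangles carrying a `surface_label` cell array) and CARP-style
`.pts/.elem/.lon/.surf`. Unlabeled meshes can be labeled geometrically: faces
near the top of the long-axis extent become BASE, the remaining connected
components split into ENDO (smaller enclosed volume) and EPI.

Size metrics: wall volume is the tet-volume sum; LV mass multiplies it by
1.05 g/mL (overridable); LVEDV is the volume enclosed by the endocardial
surface closed with a planar fan cap across its single basal boundary loop
(divergence theorem). Papillary muscles are not modeled, consistent with
counting them into the cavity volume.

**Transmural coordinate.** The normalized wall depth d_endo/(d_endo+d_epi)
from exact point-to-triangle distances to the two labeled surfaces. A
harmonic (Laplace) interpolant was rejected as the default because between
curved surfaces it concentrates its gradient at the higher-curvature
endocardium — on a spherical shell it reaches 0.6 at mid-wall, and ~0.8 near
a prolate apex — so "depth" thresholds would not mean physical depth. The
distance ratio is smooth inside a shell (the wall contains no medial axis of
either surface), exact on both surfaces, and extremum-free in the interior.
The harmonic variant remains available (`transmural_method="harmonic"`).

**Apicobasal coordinate.** Harmonic with BASE = 1 and the apex node = 0,
where the apex is the boundary node graph-geodesically farthest from BASE
(ties to the lowest index). A point Dirichlet sink has zero capacity in 3-D,
so the raw field hugs 1 almost everywhere; it is therefore composed with a
strictly monotone piecewise-linear map (quantile matching against normalized
geodesic height above the apex). This preserves level sets, gradient
directions, exact boundary values and the maximum principle, while making
values approximately linear in apex-to-base arc length — so "the apical
third of the endocardium" selects a geometric third.

**Fibers.** Per element, the frame is built from the transmural gradient
(wall normal), the apicobasal gradient orthogonalized against it
(longitudinal), and their cross product (circumferential). The fiber is the
circumferential direction rotated about the wall normal by the helix angle
α(d) = +40°·(1−d) − 50°·d at the element-mean depth d — the rule-based
+40°→−50° rotation, reduced to a single-ventricle linear rule.

## Synthetic cohorts

The generator emulates only what the analysis consumes: the joint
distribution of LV mass and LVEDV. Anatomy is a truncated prolate-ellipsoid
shell — cavity semi-axes (a, a, c) with c/a = 3, uniform outward wall offset
t, truncation keeping 90% of the apex-to-equator extent below the base plane
(both configurable). With the aspect ratio fixed, LVEDV determines a and
mass then determines t, each by a 1-D root find on closed-form truncated-
ellipsoid volumes, followed by a short fixed-point correction for mesh
faceting so measured metrics land within 3% (typically 0.3%) of targets.

Cohorts draw (mass, LVEDV) pairs from per-sex normal marginals — CRT
defaults: males 273 ± 78 g and 261 ± 109 mL, females 173 ± 58 g and
165 ± 67 mL — coupled by a Gaussian copula (corr 0.7, the marginals being
all that is published), truncated at ±2.5 sd and at feasibility; infeasible
draws are resampled (≤100 per case). Everything is reproducible from the
seed.

What the generator does **not** represent: real shape variation (sphericity,
regional wall thinning, papillary muscles, trabeculation), the right
ventricle and septum, scar. Consequences worth knowing:

* male and female synthetic LVs differ (almost) only by size, so
  perturbations common to both — e.g. the anisotropy ratio — cancel almost
  exactly under recalibration, more completely than in real anatomies;
* the female-to-male QRSd ratio tracks the cuberoot-LVEDV ratio of the
  size distributions (~0.86 for the CRT defaults), giving ~21–23 ms
  threshold reductions at 150 ms — larger than reductions obtained from
  patient geometries whose measured size gap is milder (≈0.89, ~11–13 ms,
  reproduced by the patient-metric pair in the acceptance script).

Mesh resolution: structured (θ, φ, depth) grid split into conforming tets
(six per hex, three per apex wedge); the first transmural layer is 1 mm to
resolve the fast endocardial band, tangential target edge 3.5 mm for cohort
runs (3.0 mm for the test fixture). Halving the edge length changes QRSd by
≤1.4% (intrinsic) and ≤0.2% (paced) on the fixture, so cohort conclusions
are resolution-converged at the percent level; these sizes keep a full
39/11-cohort analysis to a few minutes on one CPU.

## Protocols and calibration

* **Intrinsic** (non-LBBB surrogate): simultaneous onset 0 on all
  endocardial nodes with apicobasal ≤ 1/3. No Purkinje delay model.
* **RV-paced** (LBBB surrogate): a single stimulus at the epicardial node
  with the smallest apicobasal coordinate (optionally restricted to an
  azimuthal septal sector, or overridden by an explicit coordinate). The
  geometries are LV-only, so a true right-ventricular apex does not exist;
  the apical epicardial site is the closest realizable analogue, and its
  placement is a documented choice rather than a published one.

Activation time is exactly inversely proportional to the global speed scale,
so calibration is closed-form: one unit-CV solve gives T₁ and the CV for a
target QRSd is T₁/target (verified to 10⁻⁶ relative; a bisection fallback
exists for any future non-homogeneous model and agrees to 10⁻⁴ m/s). The
cohort runner caches the unit-CV solve per (mesh, protocol), which is exact,
not an approximation.

The sex calibration averages male CVs arithmetically per
(protocol, threshold) cell (harmonic mean behind a flag, CV and time being
reciprocal), predicts every female QRSd at that mean CV, and reports
mean ± sample sd (and sem, the "±" convention in the source tables being
unstated). Guideline rows map LBBB morphologies to the paced protocol and
non-LBBB (or unspecified) to intrinsic; female bounds round to the nearest
integer ms (half-to-even — the convention that reproduces all published
cells), and the upper end of a 120–149 ms range maps to the female
equivalent of the exclusive 150 ms bound minus 1 ms.

**Sensitivity protocol.** With recalibration (default), a perturbation
(helix angles ±10%, anisotropy ratio ±10%) is applied to both models, the
male CV is re-fitted to the stated baseline (100 ms), and the change in the
predicted female QRSd is reported; re-fitting absorbs any common speed
change, so the anisotropy effect is ≲0.05 ms here. At fixed CV
(`recalibrate=False`) the perturbation applies to the female model alone,
measuring the raw leverage of the rule: ±10% on the helix angles then moves
QRSd by ~2.6 ms. A fixed-CV anisotropy perturbation changes QRSd by several
ms — the transverse speed directly sets transmural propagation — which is
why the near-null anisotropy result is only reproducible under the
recalibrated protocol.

## Numerical details and edge cases

* Laplace solves: P1 FEM, sparse direct solve, relative residual < 10⁻⁸;
  Dirichlet sets built per surface label with ENDO/EPI taking precedence on
  shared rim nodes.
* Negative-volume tets are reordered on construction (logged); boundary
  faces are extracted outward-oriented and must partition into the three
  labels, which doubles as a conformity check on the structured mesher.
* Endocardial openings that are not a single simple loop raise a cavity-
  volume error rather than guessing a cap.
* Point-to-surface distances use exact point-triangle distance with a
  KD-tree prefilter (k = 12 candidate triangles).
* Degenerate inputs: zero layer thickness → all bulk (warning); thickness
  beyond the wall → all layer (warning); empty stimulus sets, out-of-range
  pacing sites, non-SPD tensors, disconnected (unreachable) nodes all raise
  with context.
* Homogeneity and scaling laws hold to ~10⁻¹² through the cached-solve path;
  between two independent eikonal runs agreement is bounded by the 10⁻⁶ ms
  convergence tolerance (~2·10⁻⁶ ms in practice).

## Known limitations

LV-only anatomy with an idealized pacing surrogate; no scar or ischemia; no
clinical-outcome modeling; the synthetic shape family cannot exhibit
shape-specific (as opposed to size-specific) sex differences, so
shape-mediated sensitivities are lower bounds; QRSd equals total activation
time, which ignores lead projection effects on measured QRS width.
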