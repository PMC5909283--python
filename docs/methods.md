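# Methods

This note documents the models implemented in `tma_dearray`, the parameters
that matter, the numerical choices, and what the synthetic benchmarks do and
do not establish.

## Detection model

The detector assumes cores are bright, roughly circular blobs of known
approximate radius `r_core` on an arbitrary (possibly inhomogeneous,
possibly noisy) background. Everything else about the background is left
unspecified on purpose: the threshold is distribution-free.

**Wavelet frame.** Scaling functions are isotropic Gaussians with variances
`v_j² = σ₁² (4^j − 1)/3` (equivalently `v_j² = σ_j² + v_{j−1}²` with
`σ_j = 2^{j−1} σ₁`, `v₀ = 0`). The atom at scale `j` is the difference
`ψ_j = G_{v_{j−1}} − G_{v_j}`; only the single matched scale
`ĵ = argmin_j |r_core − 2^{j−1} σ₁|` is ever computed, directly as two
Gaussian smoothings (ties go to the smaller, cheaper scale). Only the
decomposition is needed; no reconstruction is implemented.

- `sigma1` (default 2.0 px): base scale, tied to pixel size. With 2 px the
  matched index stays small (ĵ = 3–5) for core radii of 8–60 px.
- Gaussian kernels are truncated at 6 standard deviations and convolutions
  use reflect padding (zero padding would create spurious edge responses).
  6σ, rather than the more common 4σ, keeps the direct decomposition equal
  to the iterative per-scale cascade to ~1e−9 relative error; at 4σ the
  truncation already breaks the semi-group identity at the 1e−4 level,
  which matters because the cascade is the test oracle for the direct path.

**Adaptive threshold.** Local background statistics are estimated as
`μ̂ = ĝ ⋆ Ψ_ĵu`, `ν̂² = ĝ ⋆ (Ψ_ĵu)² − μ̂²` (clamped at zero before the
square root; floating point can drive the difference slightly negative).
The weighting window `ĝ ∝ sup ψ_ĵ − ψ_ĵ` is non-negative, sums to one and
is hollow at the center, so the object under test contributes least to its
own background estimate. Tchebychev's inequality then bounds the
false-alarm probability of the rule `Ψ_ĵu ≥ μ̂ + ν̂/√p_FA` by `p_FA` under
any background distribution; `p_FA = 0.05` by default. Because the bound is
distribution-free it is very conservative: measured exceedance rates on
background-only synthetic fields are ~1e−5, three orders of magnitude below
the bound.

Two support choices matter and are deliberate:

- *Weighting-window support*: the atom is sampled on a radius of `2 v_ĵ`
  (≈ 2.5 `r_core` at the matched scale). The window must behave as a
  *local background* estimator: it has to cover the atom's negative lobe,
  but a support as large as the kernel truncation radius would reach the
  neighbouring cores on realistic grids and inflate `ν̂` until no core
  passes the test (verified: on a 10×10 grid at spacing 4.7 `r_core`,
  support 4`v_ĵ` detects nothing, support 2`v_ĵ` detects 100/100).
- *Degenerate-variance floor*: exactly constant regions (the zero
  background of binary pseudo-slides) have `ν̂ = 0`, making the threshold
  rule fire on equality everywhere in the flat region. The Tchebychev
  derivation itself only yields a *family* of valid thresholds
  `τ ≥ μ̂ + ν̂/√p_FA`, not attained at `ν̂ = 0`; the implementation uses
  `τ̂ = μ̂ + max(ν̂/√p_FA, η)` with `η = 1e−9 · max|Ψ_ĵu|`. Consequence: a
  perfectly featureless map produces *no* detections (rather than all
  pixels). Set `contrast_floor_rel=0` to recover the bare rule.

Candidates are gravity centers of 8-connected components with area at least
`⌈π r_core²/16⌉` (a mild floor that removes speckle cheaply; real outlier
rejection is the segmentation screen's job).

## Segmentation model

Each candidate seeds a pair of concentric coaxial ellipses, outer `Γ`
(`{x₀, a, b, θ}`) and inner `Γ′` with axes divided by √2, so ring and core
have equal areas and the contrast energy vanishes on constant images. The
energy is evaluated on raw intensities (no local normalization) over a
square patch around the detected centroid, with the logistic smoothing
`w_ε(t) = S_ε(t) − 2S_ε(2t)`, `S_ε(t) = 1/(1+e^{(t−1)/ε})`, of the
indicator pattern; `w′_ε` vanishes away from the two boundaries, so
gradients are boundary-driven as an active contour should be.

- `eps` (default 0.05, in units of the squared normalized metric): gives a
  soft boundary about one pixel wide for `r_core ≥ 10` px. Smaller values
  converge to the hard indicator energy but make the gradient stiffer.
- Optimizer: L-BFGS-B on the five parameters with analytic gradients and
  box constraints — center within `ρ_max = 0.5 r_core` of the seed, axes in
  `[0.5 r_core, 2.2 r_core]`, `θ ∈ [−π/2, π/2]`. `a ≥ b` is re-imposed
  after convergence by an axis swap plus a quarter-turn. The multi-ellipse
  problem is separable apart from the pairwise minimum center distance,
  which is enforced post hoc: of two accepted ellipses closer than the
  patch radius, the lower-energy one survives.
- *Patch radius*: `ρ = ρ_max + r_max = 2.7 r_core`. The patch must contain
  every admissible ellipse: if the outer ring is clipped by the patch (or
  the image border), the ring/core area cancellation breaks, and on bright
  backgrounds the energy then *rewards* ballooning to the box bound. This
  is why `ρ` exceeds the conventional `2 r_core`.
- *Acceptance screen*: the outer axes of a perfectly round core are
  `√2 r_core`, so accepted fits must satisfy
  `0.75·√2·r_core ≤ b ≤ a ≤ 1.5·√2·r_core` and `a/b ≤ 2`. The band is
  symmetric around the ideal outer axis and cleanly separates nominal cores
  from half-size, double-size and 3:1-elongated ones; fits that saturate
  the optimizer's `r_max` bound fall outside it by construction.

## Grid registration

The deformation of the design grid is modeled as affine plus a smooth
non-linear residual.

**Affine part (oblique grid).** Statistics run over ordered pairs (point,
one of its 4 nearest neighbours). The spacing `d̄` and the two principal
angles `ᾱ ≤ π/4 ≤ β̄` (pair angles taken modulo π into `[−π/4, 3π/4)`) are
30%-trimmed means, where "trimmed" means *discarding the 30% of values
farthest from the median*: the 4-NN pair set of a square lattice
unavoidably contains diagonal pairs (length `d√2`, angle π/4) for boundary
points — up to ~17% of pairs, all in one tail — which symmetric per-tail
trimming cannot fully reject. The translation `t̂` alternates
nearest-lattice-node assignment with re-centering and is folded into the
fundamental cell (it is only identified modulo the lattice; consequently
recovered array coordinates are compared to ground truth up to one global
integer offset, with no transpose or reflection allowed).

Under isotropic positional jitter of standard deviation σ the pair-length
statistic carries an irreducible Jensen bias of about `2σ²/d` (+2% of `d`
at σ = 0.1 d); the TPS stage absorbs it, but `d̄` itself should only be
read as a spacing estimate to ~1% at realistic jitter.

**Non-linear part.** Interpolating thin-plate spline with kernel
`U(r²) = r² log r²` (`U(0) = 0`), sources the paired *ideal* nodes
`y*_p = d·p`, targets the observed centers — the classical landmark
formulation, solved from the bordered system `L W = [targets; 0]`
(pseudo-inverse on singular configurations; fewer than three pairs fall
back to an affine/translation map). Association is greedy one-to-one by
increasing distance within radius `δ = 0.4 d̄` (below half a cell, so
associations cannot jump cells; ties break lexicographically on the node
coordinate). Association and fitting alternate, re-warping the full node
set (the integer bounding box of the observations' lattice coordinates)
each iteration, until the maximum node displacement is below 1e−2 px or 50
iterations. When no design spacing is supplied the ideal spacing is taken
equal to `d̄` (scale ratio 1).

Coordinates are assigned to the nearest warped node, one observation per
node; the loser of a collision takes its next-nearest unclaimed node within
δ or stays unassigned. Refinement runs one ellipse fit at every empty node
(screened as above), then refits the spline once with the augmented pairs.
The reported per-axis bending energies are the standard TPS quadratic form
`wᵀ K w` per output coordinate — one reasonable reading of a "deformation
quality" summary; other conventions (e.g. the 8π-normalized form) differ
only by a constant factor.

## Synthetic data

The generator renders a rows×cols design grid deformed by rotation,
per-axis stretch, a sum of smooth Gaussian bumps (deliberately *not* a
thin-plate spline, so registration tests are not self-fulfilling), and
i.i.d. Gaussian jitter, with a fraction of nodes left empty. Cores are
anti-aliased filled ellipses with mild area-preserving axis-ratio
variation; an optional malformed fraction renders cores at half size,
double size, or 3:1 elongation (outside the screen by construction), and an
optional annulus ("hole") variant exists because real cores with inner
holes are a known detection failure mode. Three shadings: binary {0,1};
brightfield (bright background 220, cores 160 darker, Gaussian noise σ=4,
8-bit range); fluorescence (baseline 500 plus a smoothed random field of
amplitude 300 and scale 80 px, core amplitude 3000, Poisson noise at gain
2 plus Gaussian read noise σ=20, 16-bit range). Everything is a pure
function of the seed.

Benchmark regimes (and the problem sizes used, chosen to keep a full run in
minutes on one CPU):

- *pseudo-TMA*: 10×10 binary grids, `r_core` 15 px, spacing 70 px, rotation
  uniform in ±10°, stretch uniform in [0.95, 1.05] per axis, jitter
  σ = 0.05 d; 10 seeds.
- *malformed*: same with 5% of cores malformed. The 5% rate makes the
  screened-out fraction match the recall the screen is expected to produce
  (localization R ≈ 0.95 with precision 1, coordinate F ≈ 0.97–0.98).
- *DNA-microarray fluorescence*: perfectly regular 10×10 grids of round
  spots, radius 8 px, pitch 40 px; 10 seeds, all four workflow options.
- *background-only*: ~485² fluorescence fields with zero spot amplitude;
  10 seeds, ~2.4M pixels total for the false-alarm estimate.

**What these tests do not show.** The generator has no tissue texture, no
fragmented cores, no dust/glue/washing artifacts, no multiple sub-arrays,
and its backgrounds are smooth; perfect scores on the synthetic regimes
therefore bound the *geometric* correctness of the pipeline (detection at
the matched scale, screen selectivity, registration and coordinate
assignment) but say little about segmentation robustness on real stained
tissue, where recall in the high-0.8s to mid-0.9s is the realistic regime.

## Degenerate inputs and edge cases

- Patches are clipped (never padded) at image borders; sums run over valid
  pixels only.
- Fewer than two detected points: registration raises a structured error
  (the CLI exits non-zero with a diagnostic).
- One empty angle class (e.g. a single row of cores) falls back to an
  axis-aligned grid with a warning.
- Association collapse (< 3 pairs) returns the last valid deformation with
  a warning rather than diverging.
- All-zero metric denominators yield zero-valued metrics with a
  `degenerate` flag, never NaN.

## Known limitations

- The modality must be declared; polarity is not auto-detected (an
  ambiguous rule for binary images with dark spots is avoided by requiring
  `brightfield` to mean "invert me").
- No whole-slide pyramid formats; inputs are single-resolution TIFF/PNG of
  roughly 10³×10³ px.
- One design grid per image; multiple sub-arrays are out of scope.
- The screen bounds assume a single known `r_core`; arrays mixing core
  sizes would need per-class runs.
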