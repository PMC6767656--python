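# Methods

`csinet` implements a two-stage pipeline for quantitative microwave breast
imaging on synthetic data: (1) complex-permittivity reconstruction by
FEM-based Contrast Source Inversion (CSI) with a three-tissue-region prior
imposed as an inhomogeneous numerical background, and (2) a U-Net that maps
the rough CSI reconstructions to clean permittivity images.  This note
records the model, the numerical choices, and what the bundled synthetic
studies do and do not demonstrate.

## Wave model and forward solver

The imaging configuration is 2D transverse-magnetic: a line source reduces
Maxwell's equations to the scalar Helmholtz equation for the out-of-plane
electric field.  With the e^{+jωt} convention the complex relative
permittivity is ε = ε′ − jε″ (ε″ ≥ 0) and the scattered field for
transmitter *t* satisfies

    ∇²E_t^sct + k_n² E_t^sct = −k_n² w_t ,   k_n = ω √(μ₀ε₀ε_n),

where ε_n is the known numerical background and w_t = χ·E_t is the
contrast source, χ = (ε_r − ε_n)/ε_n.

The solver discretizes a disk-shaped problem domain with linear (P1)
triangles laid out on concentric rings and triangulated with Delaunay.
Numerical choices that matter:

- **Absorbing boundary.** First-order absorbing condition on the outer
  circle *with the curvature correction*, ∂u/∂n = −(jk_b + 1/(2R))u.
  Omitting the 1/(2R) term costs several percent of field accuracy at
  these domain sizes.  The outer radius defaults to 1.5× the measurement
  radius; validation runs against the analytic cylinder series use 2×,
  where boundary reflection is negligible.
- **Dispersion-minimized mass matrix.** The k² mass matrix is the
  half-and-half blend of the consistent and row-sum-lumped P1 mass
  matrices.  Pure consistent mass leaves a phase drift (numerical
  dispersion) that accumulates to ~2–4% field error across the
  electrically large domain; the blend cancels most of the leading-order
  term.  With it, the scattered field of a lossy dielectric cylinder
  matches the cylindrical-harmonic (Mie-type) series to ≤2% relative RMS
  at the receivers for edge lengths of λ_min/15 and finer.
- **Material sampling.** Permittivity is sampled at element centroids,
  which represents the sharp skin/fat/fibroglandular interfaces of the
  phantoms better than nodal averaging.
- **Mesh density.** Inversion meshes use edges ≤ λ_min/10 where λ_min is
  the wavelength in the highest-permittivity tissue; forward-data meshes
  are 1.5× finer.  Generating data on a different (finer) mesh than the
  inversion uses, plus measurement noise, is the inverse-crime
  mitigation.
- **Noise.** Complex circular Gaussian noise, independent per datum,
  scaled so its expected RMS equals the requested fraction (default 5%)
  of the RMS of the noise-free dataset.

Default physics (not prescribed by the study conditions and therefore
package choices): 1.0 GHz operating frequency, 24 transmitters and 24
receivers equally spaced on a circle just outside the imaging square,
receivers rotated half a step so none coincides with a source, and a
lossy matching medium ε_b = 23 − 1j.

## Contrast Source Inversion

CSI minimizes the sum of the normalized data error and domain error

    F_CSI(χ, w_t) = Σ_t‖f_t − M_S L[w_t]‖² / Σ_t‖f_t‖²
                  + Σ_t‖χ⊙E_t^inc − w_t + χ⊙M_D L[w_t]‖² / Σ_t‖χ⊙E_t^inc‖²,

where L is the factorized inverse of the FEM operator assembled with the
prior background (so the prior's tissue structure is baked into the
forward map), M_S samples receivers and M_D restricts to imaging-domain
nodes.  The implementation:

- **w-update**: one Polak–Ribière conjugate-gradient step per transmitter
  with an exact line search (the subproblem is quadratic because the F_D
  normalizer is held at the previous contrast).  Inner products are
  conjugate-linear in the first argument; the adjoint solve reuses the
  same LU factorization (A is complex-symmetric, solved with trans="H").
- **χ-update**: closed-form nodewise least squares
  χ = Σ_t w_t·conj(E_t) / Σ_t|E_t|² with the current total fields
  E_t = E_t^inc + M_D L[w_t].  Nodes where Σ_t|E_t|² = 0 are set to zero
  and counted in a diagnostic.
- **Guarded acceptance**: the candidate χ is kept only if the recorded
  F_CSI (with its normalizer moved to the new χ) does not increase;
  otherwise the previous χ is retained for another round of w-updates.
  Together with the exact line search this makes the recorded cost
  history non-increasing by construction (per-step tolerance 1e−10
  relative); the guard fires rarely in practice.
- **Initialization**: back-propagation, w_t = s_t (M_S L)^H f_t with the
  per-transmitter scalar s_t minimizing the data error; deterministic.
- No positivity or bound constraints are imposed on χ during iteration.
- F_D is undefined at χ ≡ 0 (its normalizer vanishes); this is signalled
  with a dedicated exception rather than silently regularized.

Reconstructed permittivity is ε_r = ε_n(1 + χ) on mesh nodes,
rasterized to the pixel grid by barycentric (P1) interpolation.

## Synthetic phantoms and the surrogate prior

Three procedural base outlines emulate breast density classes: Model I
(heterogeneously dense, 10 × 9.5 cm), Model II (fatty, 11.2 × 9.6 cm),
Model III (very dense, 10 × 5 cm).  Each is an ellipse with a 1–3-pixel
closed skin ring (0.2 cm target thickness) and a single contiguous
fibroglandular region obtained by thresholding a smoothed Gaussian random
field at a per-class area fraction (nominally 35% / 15% / 65% of the
interior for I / II / III; the largest-component selection makes realized
fractions somewhat smaller, but the ordering II < I < III is stable).
Tumors are grown from a uniformly chosen fibroglandular seed pixel by
random 4-connected accretion until no pixel can be added without the
mask's maximum pairwise centre distance reaching the sampled maximum
diameter (uniform in 1.1–1.5 cm).  Two-tumor phantoms reject and regrow a
second tumor that touches the first (8-connectivity, up to 100 attempts).

Tissue dielectric values are a configurable table of mid-range
single-frequency literature values at 1 GHz — matching medium 23 − 1j,
skin 36 − 4j, fat 5 − 0.5j, fibroglandular 35 − 6j, tumor 50 − 10j —
chosen for the strong fibroglandular/fat contrast characteristic of
breast tissue; they are assumptions, not measured data.  Per-pixel
heterogeneity is multiplicative uniform texture (default ±5%) on tissue
pixels; the exterior medium is exact.

The ultrasound-derived tissue segmentation of the original multimodal
procedure is replaced by a surrogate: the phantom's own label map with
tumors relabelled as fibroglandular, region boundaries displaced by a
smooth random field bounded by ±2 px, and per-region permittivities
scaled by a uniform error of ±5%.  With zero jitter and zero value error
the prior is the exact tumor-free background, so the true contrast is
nonzero only on tumor pixels — a property the tests verify against the
contrast definition.

## U-Net enhancement

The enhancement stage is a classic U-Net implemented in numpy (forward,
backward and Adam optimizer; im2col convolutions): 3×3 conv + ReLU pairs,
2×2 max-pool encoder, 2×2 transposed-conv decoder with skip
concatenation, linear 1×1 head.  Inputs are three channels — real part,
imaginary part, and magnitude √(ε′² + ε″²) — of the CSI reconstruction,
min-max normalized per channel on the training split only.  Architecture
1 trains two independent single-output networks (true ε′ and true ε″
targets); architecture 2 trains one three-output network (magnitude,
real, imaginary).  The loss is the plain pixelwise squared error; for
architecture 2 the channels are deliberately unweighted, so the
larger-scale real part dominates the cost (an optional per-channel
weighting exists but defaults to uniform).  Weights use Glorot normal
initialization; shuffling and init are seeded, so training is bitwise
deterministic.  Max-pool backward distributes gradient equally among tied
maxima so the backward pass remains a true adjoint.

Full-scale defaults follow the published training protocol where stated
(batch 10, 75 epochs) and classic U-Net proportions where not (depth 4,
32 base filters, Adam at 1e−3).

## Evaluation

- **RMS error** is computed over breast-interior pixels (the exterior
  medium is known from the prior and would dilute the comparison),
  separately for ε′ and ε″.
- **Pixel-wise ROC-AUC** pools pixels across all phantoms of a test
  subset and thresholds the reconstructed ε′ (real half) or ε″
  (imaginary half) directly; higher values are more tumor-like since
  tumor permittivity exceeds the other tissues in the default table.
  The AUC is the Mann–Whitney statistic with tie correction.
- **Cross-validation** uses four folds balanced per (model, tumor count);
  training settings A–D include models {I,II,III}, {I,II}, {I,III},
  {II,III} respectively, and every setting is evaluated on all seven
  model subsets of the hold-out fold, with raw CSI as the baseline.
- **Robustness** evaluates a trained network on early-terminated CSI
  inputs and on rotated/flipped inputs (truth transformed identically),
  with the CSI baseline computed on the same transformed inputs.

## Problem scales

The `full` preset mirrors the study conditions (128×128 grid at 0.1 cm,
200 single- + 200 two-tumor phantoms per model, 250 CSI iterations,
75 epochs, four folds) and takes hours of CPU time.  The package's own
validation runs use the `desk` preset: 64×64 grid at 0.2 cm, 10 + 10
phantoms per model (60 total), 30 CSI iterations with snapshots at
{10, 20, 30}, architecture 1, depth 3 with 8 base filters, batch 10,
40 epochs at learning rate 3e−3 with step decay, one fold.  Training
uses a short multi-start (two inits probed for five epochs, the better
one retrained in full): the joint three-output network occasionally
converges to a basin whose small-scale imaginary channel is poorly
fitted, whereas the separate real/imaginary networks of architecture 1
are stable across initializations — an echo, at desk scale, of the
scale-disparity argument for training the two parts separately.  The desk training length and
learning rate compensate for the much smaller number of gradient steps
relative to full scale (60 phantoms × tens of epochs versus 900 × 75);
with the full-scale learning rate the desk-scale network is visibly
undertrained.  These sizes are the package's choices for a
laptop-class validation; the directional claims they support (U-Net
improves RMS and AUC over CSI; the improvement survives input
degradation) are scale-reduced reproductions, not the study-scale
numbers.

## What the synthetic studies do and do not show

The generator emulates the geometry and statistics of the study's
MRI-derived phantoms, not their pixel data: real fibroglandular texture,
skin thickness variation, 3D propagation, tissue dispersion
(frequency-dependent permittivity), antenna characteristics and
experimental calibration errors are all absent.  Passing tests therefore
demonstrate the correctness of the solver, the optimizer, the generator
contracts and the direction of the CSI→U-Net improvement under these
idealized conditions; they do not certify performance on measured data.
A further caveat: with a three-region prior of this quality the CSI
baseline is itself strong (pooled AUC ≈ 0.98 at desk scale), so the
U-Net's margin over CSI is smaller than in the published full-scale
setting, where the baseline AUC is ≈ 0.9.

## Known limitations

- Standard CSI only; no multiplicative regularization, no frequency
  hopping, no 3D.
- The sharp-edge contrast of an object is recovered only to the
  diffraction limit; nodewise contrast error against a discontinuous
  truth is dominated by the ~λ/4 interface band regardless of iteration
  count.
- The numpy U-Net is CPU-bound and sized for desk-scale grids; the
  full-scale preset is functional but slow.
- Single frequency, scalar 2D fields, isotropic nonmagnetic media.
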