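# Methods

## Worm-like-chain model and estimator

A semiflexible filament confined to two dimensions in thermal equilibrium
is modelled as a worm-like chain: tangent angles θ(s) along the arc length
s decorrelate as ⟨cos(θ(s+Δ) − θ(s))⟩ = exp(−Δ/2Lₚ), where Lₚ is the
persistence length. Integrating this correlation twice over the contour
gives the closed form

⟨R²⟩(L, Lₚ) = 4Lₚ² [2 exp(−L/2Lₚ) − 2 + L/Lₚ],

relating the mean-square end-to-end distance to the contour length. The
estimator consumes one point per filament: L is the mean of the per-frame
contour lengths and ⟨R²⟩ the mean of the squared per-frame end-to-end
distances, averaged over 100–200 frames (fewer or more frames trigger a
warning, not an error). Lₚ is then the single free parameter of an
unweighted nonlinear least-squares fit pooled over all filaments
(`scipy.optimize.curve_fit`, positivity bound, initial guess from the
floppy-limit moment median(⟨R²⟩/4L)). A weighted variant
(σᵢ = sd(R²)ᵢ/√nᵢ) is available behind a flag but is not the default: the
per-filament frame counts are similar by design and the unweighted pooled
fit is the plainest reading of the procedure.

Assumptions worth keeping in mind:

- **Equilibrium, independent frames.** Frames are treated as independent
  equilibrium samples. Real movies at 40 ms intervals are temporally
  correlated; this inflates neither L nor ⟨R²⟩ but reduces the effective
  number of frames, so real uncertainties are larger than synthetic ones.
- **Strict 2D confinement.** Out-of-plane excursions are not modelled.
- **Whole-filament endpoints.** R uses only the first and last node; no
  internal-segment subsampling.

Per-filament validity is enforced: ⟨R²⟩ > L² is physically impossible and
such points are rejected with a message. Fits with Lₚ above 10× the longest
filament are flagged `beyond_support`: in that regime the data barely bend
and constrain only a lower bound (accurate estimation needs filaments at
least as long as a sizeable fraction of Lₚ — which is why estimates from
short, stiff filaments carry large systematic uncertainty).

Numerical care: for L/Lₚ < 10⁻⁶ the closed form suffers catastrophic
cancellation and the series L² − L³/(6Lₚ) is used; mid-range values go
through `expm1`. The closed form is verified in the tests against an
independent numeric integral of the tangent correlation (reduced by
symmetry of |s−s′| to 2∫₀ᴸ(L−u)e^(−u/2Lₚ)du) at 10⁻⁸ relative.

### Tangent-correlation cross-check

`tangent_correlation_lp` pools ⟨cos Δθ⟩ over all node pairs at each arc
separation across frames and filaments and fits a single-exponential decay
by a through-origin log-linear fit restricted to the initial decay
(correlation > 1/e); large-separation points are few, noisy, and biased
downward by the log transform. The decay length equals 2Lₚ in 2D. When the
correlation barely decays over the available arc range (decay length >
10× the largest separation) the result is flagged as a lower bound.
Synthetic-grid tests require the two estimators to agree within 15%.

## Synthetic worm-like-chain ensembles

`sample_wlc_chain` draws a chain of ⌊L/ds⌋ segments with a uniformly random
initial direction and i.i.d. Gaussian tangent-angle increments of variance
ds/Lₚ. For Gaussian increments ⟨cos Δθ⟩ = exp(−var/2) holds exactly, so the
discrete chain's tangent autocorrelation is exactly exp(−s/2Lₚ) at every
node separation — the generator is faithful at any ds, and discretisation
enters only through the polyline representation (contour within one ds of
the request; default ds = min(0.05 µm, L/200) keeps this far below fit
tolerances). Ensembles are reproducible bit-for-bit from a single seed;
filament placement in the field is uniform (re-drawn when >10% of nodes
fall outside, shape preserved) or on a regular grid (`placement="grid"`,
useful for rendering tests where overlaps must be avoided).

Default study-scale conditions mirror the experimental design the package
targets: 55 (tube) or 37 (actin) filaments, 150 frames, contour lengths
uniform in 2–15 µm, ground-truth Lₚ of 19.7 µm and 12.5 µm respectively.
Parameter-recovery tests at these conditions require median relative error
≤ 10% over 20 seeded replicates, and single-seed recovery within 15%.

## Fluorescence rendering

`render_frames` deposits unit line density along each trace at 0.25 px arc
sampling (bilinear weights), convolves with a Gaussian PSF, and scales so a
straight filament's ridge peaks at `peak_intensity` photons. Background,
Poisson shot noise, Gaussian read noise and quantisation to 8/16 bit follow;
stacks are written as multi-page TIFF. Defaults emulate a TIRFM setup:
0.267 µm/px (16 µm camera pixel through a 60× objective), PSF σ = 1 px,
40 ms frame interval. Pixel size and PSF width are conventions of the
renderer, not measured properties, and are fully configurable. The
`shot_noise` toggle exists because noiseless rendering is the reference
condition for tracking-fidelity tests. What the renderer does *not*
emulate: photobleaching, uneven illumination, out-of-focus light,
camera-specific fixed-pattern noise, and filament crossings' excluded
volume. Passing tests on rendered data therefore validate geometry and
statistics of the estimation chain, not robustness to every imaging
artefact of real movies.

## Tracking

Per frame: Gaussian smoothing (σ configurable, default 1 px), global Otsu
or fixed threshold, morphological skeletonisation, and per connected
component the longest endpoint-to-endpoint geodesic through the skeleton
graph (edge weights 1/√2; near-ties broken by summed intensity along the
path, then lexicographically). The pixel path is smoothed
(Gaussian, σ = 1.5 samples) and splined to kill the staircase, then two
sub-pixel refinements are applied:

1. **Ridge registration.** Each node is shifted along its local normal to
   the intensity centroid of the perpendicular profile (±2.5 px window).
2. **Tip extension.** Each end is extended along its end tangent to the
   half-maximum crossing of the ridge intensity (0.1 px steps with
   interpolation of the crossing). Skeletonisation retreats from the
   rounded caps of a thresholded ridge by roughly its half-width; for a
   PSF-convolved line end the half-max crossing coincides with the true
   tip, so this removes an otherwise systematic ~1–2 px shortening.

Nodes are resampled at 1 px spacing (configurable); traces shorter than
`min_length_px` or touching the border margin (default 5 px, because
truncated filaments bias L and R jointly) are dropped; node order runs
from the lexicographically smaller endpoint so output is stable under
image rotation. Linking is greedy nearest-centroid with a displacement
gate (default 15 px; note that with independent equilibrium frames the
centroid genuinely jumps between frames, so the gate should comfortably
exceed the typical shape fluctuation), deterministic tie-breaks, and gap
counting per track.

Measured fidelity on noiseless rendered data (see tests): contour length
within 0.5% and end-to-end within ~0.3 px for smooth shapes with curvature
radius above a few px. For worm-like chains the tracked contour is
systematically short by roughly ℓ/(πLₚ_px) — bending below the PSF scale ℓ
is physically absent from the image and unrecoverable. This deficit
amplifies in the Lₚ fit by a factor that grows toward 12Lₚ/L in the stiff
regime, which is the quantitative face of the "longer filaments needed for
stiff samples" caveat: the full render→track→fit chain is tested at
realistic stiffness (Lₚ ≈ 74 px) with long filaments (90–150 px), where
the tracking-induced bias measures ≈ +4% (≤ 10% required).

## Tube morphometry

Tube length = half the perimeter of a traced closed outline. The rule
assumes a thin loop hugging both tube edges, so perimeter ≈ 2×length; the
width contribution (half the outline width per end) is deliberately not
corrected. Outlines are implicitly closed; self-intersection warns but
still yields a value. Longest-N selection (default N = 150) is a stable
top-N — it reproduces a published plotting procedure and is a selection
*bias* by construction; comparisons are only meaningful between samples
selected the same way. Welch's two-sided t test (Satterthwaite df) is
computed via `scipy.stats.ttest_ind(equal_var=False)` and reported raw —
no multiple-testing correction, mirroring how pairwise comparisons are
conventionally reported for this assay. Degenerate zero-variance input:
both samples constant and equal → p = 1 with a warning; any other
zero-variance configuration is an error (real length data never hits it).

## Melt-curve fitting

The default model is a four-parameter logistic
S(T) = b_f + (b_u − b_f)/(1 + exp(−(T − Tm)/k)) with constant baselines;
Tm is the inflection. Sloped baselines (six parameters) are available
behind a flag but default off — at typical melt lengths (~50 points) the
extra slopes trade against k and widen the Tm confidence interval without
improving the midpoint. Initial guesses come from the data (tercile means
for baselines, half-transition temperature for Tm, a tenth of the span for
k); the fit is direction-agnostic, and Tm is invariant under affine
rescaling of the signal. A fitted amplitude below 3× the residual RMS is
declared "no resolvable transition" (`converged=False`); a midpoint
outside the scanned range is flagged as extrapolated. At 2% amplitude
noise and 1 °C sampling the estimator's bias measures < 0.1 °C over 500
replicates and single-curve recovery is well within 0.3 °C.

## Problem sizes and design choices

Test and acceptance runs use the study-scale ensembles directly
(55×150 and 37×150 chains at ds = 0.05 µm), 5000-chain grids for generator
fidelity, 100–500 melt replicates, and a 4-filament × 50-frame rendered
movie for the full tracking chain; these sizes make every statistical
tolerance comfortably resolvable while keeping a full run in minutes on one
CPU. Frames are independent equilibrium draws rather than Brownian
dynamics: the estimator only assumes equilibrium shapes, and simulating
relaxation would add diffusion parameters the analysis never uses.
Self-avoidance, 3D projection, filament turnover and depletion physics are
out of scope. Interactive active-contour ("snake") tracing is replaced by
the deterministic skeleton tracker above and validated against simulator
ground truth; real snake exports can bypass the tracker entirely through
`read_snakes`.
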