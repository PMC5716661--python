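# Methods

`optogate` analyzes the fluorescence of single genetically encoded emitters
reporting on ion-channel gating, and post-processes structure ensembles for
pore hydration. Because the interesting statistics live in the *fluctuations*
of weak signals, every analysis routine is paired with a generative model in
`optogate.synth` that produces recordings with the same statistical
structure, so each estimator can be validated against known ground truth.

## Generative model for a single-emitter trace

A fluorescent spot is modelled as `n_fluors` fluorophores attached to one
channel. The continuous-time intensity is

    I(t) = B * sum_j gate(t) * blink_j(t) * [t < T_bleach,j]

where

* `gate(t)` is a two-state telegraph (continuous-time Markov chain) shared
  by the spot. The opening rate depends on agonist concentration `c`
  through a Hill relation `k_open(c) = k_open_max * c^n / (c^n + EC50^n)`;
  the closing rate `k_close` is concentration independent. This choice —
  agonist acts on the opening rate only — reproduces the observed phenomen-
  ology (more frequent and longer bright bursts, higher bright-state
  probability at higher dose) and is configurable; the alternative
  (concentration-dependent closing) is obtained by varying `k_close`
  externally.
* `blink_j(t)` is an independent, faster telegraph per fluorophore
  (reversible dark states intrinsic to the dye), and `T_bleach,j` an
  exponential one-step photobleaching time. Setting both blink rates (or
  both gating rates) to zero disables that factor.
* Each camera sample is the **time-average of I(t) over its exposure
  window** (`dt` = 2 ms for a 500 Hz recording), computed exactly from the
  piecewise-constant path, plus Gaussian camera noise `N(bg_mean, bg_sd²)`.
  Integration rather than point sampling matters: it creates the partial-
  amplitude edge samples that a threshold idealizer actually sees.

The telegraph generator draws the initial state from the stationary
distribution `P(1) = k01/(k01+k10)`, so simulated records are stationary
from the first sample; a chain with one zero rate starts in (and never
leaves) its absorbing state, and a chain with both rates zero is rejected.

Defaults (`EmitterModel`): `k_close = 6.41 s⁻¹` (mean bright dwell 156 ms at
saturation), `k_open_max = 4 s⁻¹` (mean dark dwell 250 ms at saturation),
`EC50 = 0.33 µM`, Hill `n = 2` (the coefficient is not pinned down by the
phenomenology; 2 is typical for a multimeric ligand-gated channel and is a
free parameter everywhere), blink rates 0.5/5 s⁻¹ (≈9% dark fraction),
`k_bleach = 0.05 s⁻¹` (single emitters bleach within a minute of continuous
illumination), spot SNR `brightness/bg_sd = 10`.

**Apparent EC50.** The bright-state probability of the gate is
`P₁(c) = k_open(c)/(k_open(c)+k_close)`, which is again a Hill curve in `c`
with the same coefficient but a *smaller* midpoint,
`EC50_app = EC50 · (k_close/(k_open_max+k_close))^(1/n)`.
Tests that push simulated traces through the full pipeline therefore compare
against `EC50_app`, while dose-response recovery at the response level uses
`simulate_dose_series`, which generates the Hill curve directly (plus a
constant blink baseline and Gaussian noise).

## Trace analysis

**Filtering.** `gaussian_filter` is a zero-phase Gaussian smoother whose
−3 dB point sits at `cutoff_fraction × fs` (default one quarter of the
sampling rate). The kernel width follows from
`|H(f)| = exp(−2π²σ²f²) = 1/√2` at the cutoff, i.e.
`σ = √(ln 2)/(2π f_c)` samples (≈0.53 samples at fs/4).

**Autocovariance.** `autocovariance` returns the biased (1/N) estimator
normalized to `C(0) = 1` (the biased form keeps the implied spectrum
positive semidefinite); the FFT implementation is cross-checked in the test
suite against a direct double-loop oracle at 1e−10 absolute tolerance.

**Exponential fits.** `fit_exp_decay` fits `Σ aᵢ exp(−Δt/τᵢ) + offset`
(1 or 2 components, amplitudes constrained non-negative, offset on by
default to absorb slow baseline drift). Initialization scans a log-spaced τ
grid (1 ms–1 s) with linear amplitude solves and refines the best candidate
by bounded least squares. The zero-lag point is excluded by default: in real
data it contains the uncorrelated camera-noise variance, and even in
noise-free simulated data the exposure integration distorts `C(0)` relative
to the exponential continuation; excluding it removes both nuisances
without touching the decay constants.

**Component selection.** `select_components` prefers two components only if
they at least halve the squared residual *and* each component carries ≥10%
of the total amplitude. The autocovariance estimator's errors are strongly
correlated across lags — the empirical curve "wanders" at long lags — so an
unconstrained second exponential can absorb that wander with a near-zero
amplitude, and a parametric F-test badly overstates significance. With both
guards, single-relaxation records are classified as one-component in ≥95%
of simulated realizations while well-separated genuine pairs (13/148 ms)
are always detected.

**Idealization and dwell times.** `idealize` labels a sample L1 iff
`value > µ + k·σ` of the background (one-sided, default `k = 2.5`; L1 is by
definition the elevated level). The companion constant — the *two-sided*
Gaussian mass 0.9876 at 2.5σ — is exposed via `background_tail_mass`. The
per-sample false-positive rate is `1 − Φ(2.5) ≈ 0.62%`. Both the
time-fraction `p_l1` and the upward-transition count are reported, since
"probability of the elevated level" can reasonably mean either.

`dwell_statistics` drops the first and last runs (boundary-censored) and
optionally applies a dead time: at 0.62% per sample, a multi-minute record
contains hundreds of single-sample false L1 events, which would otherwise
dominate the bright-dwell mean and fragment the dark dwells. Events shorter
than `min_duration` are treated as unresolved and absorbed into their
flanking dwells (which are concatenated) — the standard dead-time treatment
in single-channel analysis. A dead time of two samples (4 ms at 500 Hz)
removes essentially all threshold noise while excluding only the ~2.5% of
genuine 156 ms-scale dwells shorter than 4 ms; by memorylessness this
raises the conditional mean by roughly the dead time (+4 ms), a ≤3% bias.
The default is 0 (no dead time) so the raw operation stays available;
the analysis recipes pass `min_duration = 2·dt` explicitly.

**Bleach steps.** `count_bleach_steps` segments the trace by iterative
binary change-point splitting (minimizing within-segment sum of squares,
O(n) per scan via prefix sums) with a BIC-like acceptance penalty
`2σ̂² ln n`, σ̂ estimated robustly from first differences. A boundary counts
as a bleaching step when the drop is at least `min_step` and at least 3×
the local noise SD; spots with exactly one step are flagged single
emitters.

**Photon counting.** ROIs are 4-connected components of the
frame-averaged image above a quantile threshold (default 99.5th
percentile — the threshold is a free parameter and, with a quantile rule,
the foreground area is set by the quantile, so analyses that need an exact
spot-area match should set it from the expected spot size). Histograms are
pooled per pixel class; the mode uses a smallest-count tie-break; modal
counts across replicate spots are compared with a two-sided Mann-Whitney
test (exact when sample sizes permit).

## Dose-response and activation curves

`correct_blinking` subtracts a constant blink baseline (default 0.12, the
fraction of positive transitions shown by surface-deposited free dye) with
a floor at zero and a flag when the floor engages; `normalize` implements
F/F_max. `fit_hill` fits `R = R_max c^n/(c^n + EC50^n)` (Hill coefficient
free by default, optionally fixed; 1/SEM weighting when replicate SEMs are
supplied) and reports standard errors from the scaled covariance;
saturating-only designs are flagged unidentifiable rather than silently
fitted. `fit_boltzmann` fits `I = I_max/(1 + exp(−zF(V−V_0.5)/RT))` at
T = 293.15 K (20 °C) — the sign is chosen so that current *increases* with
depolarization for positive valence, which is the physically meaningful
orientation for an outwardly activating channel; V_0.5 and z are invariant
under current-unit rescaling. `compare_optical_electrical` reports the
EC50 ratio, absolute difference, a normal overlap z-score from the fitted
SEs, a disjoint-CI mismatch flag, and an overlay table of both normalized
curves.

## Pore post-processing

All routines operate on a `PoreEnsemble` (frames × atoms × 3 Å, shared
labels/radii, a straight pore axis given as origin + unit vector;
multi-model PDB I/O round-trips through biotite, with vdW radii assigned by
element on read).

**Pore radius.** `pore_radius_profile` computes, for each axial position z,
`min over atoms (|axis point − atom center| − r_vdW)`, floored at 0. This
is a fixed-axis simplification of the usual Monte-Carlo center-optimizing
pore-profiling algorithm; it is exact for straight, axis-aligned pores
(the fixtures here) and conservative (never larger) otherwise.

**Occupancy.** `occupancy_grid` reports, per bin, the fraction of frames
occupied, with two conventions: `center` (≥1 atom center in the bin —
binary per frame, the default) and `vdw` (bin center inside any atom's vdW
sphere). Bin edges snap to multiples of the spacing.

**Water linear density.** Per frame and 1 Å axial slab (default), water
oxygens with radial distance ≤ the pore radius at the slab center are
counted and divided by the slab width → units Å⁻¹. The profile is applied
per frame; integrating the density over z reproduces the in-boundary water
count exactly by construction. `pore_continuity` calls a frame continuous
when every slab in the requested z-range has strictly positive density, and
summarizes the fraction of continuous frames.

**Grid SASA.** Per sub-trajectory window (default 10 frames):
(1) occupancy of all non-water atoms on a 0.5 Å lattice using the **vdW
volume** convention; (2) binarize at an occupancy threshold (default 0.5);
(3) surface bins = occupied bins with an empty bin center within 1.5 Å
(ties at exactly 1.5 Å included; outside the grid counts as empty);
(4) raw SASA = surface bins also covered by the target residue;
(5) normalize by the identical computation on the residue alone (its
"maximal surface area") on the same snapped lattice. The volumetric
occupancy in step (1) is deliberate: with atom-center occupancy at 0.5 Å
spacing a molecule is a scatter of isolated occupied bins and everything is
"surface", so burial would be undetectable. The 1.5 Å shell makes this a
contact-style surface (any bin just outside the vdW envelope counts as
solvent, with no probe-size exclusion); the test suite cross-checks it
against an independent rolling-probe calculation at probe radius 0.
Discretization: halving the spacing moves the normalized SASA of the
smallest (3-atom) fixture groups by <0.05, and rigid rotations move it by
<0.05 at 0.4 Å spacing; the 0.5 Å default is adequate for residue-sized or
larger selections, but sub-0.5 Å spacing is recommended for very small
groups.

**Ring orientation.** Each group's plane is the least-squares plane (SVD);
the reported angle between the plane normal and the pore axis is folded
into [0°, 90°], so a ring lying in the membrane plane scores 0° and a
vertical group 90°. Collinear groups are rejected.

## Toy pore fixtures

`make_pore_fixture` builds a z-axis cylinder of wall pseudo-atoms (bore
radius 4 Å, span z ∈ [−10, 10] Å), four planar 3-atom side-chain groups
(residue TYC, chains A–D) centred at z = 2.5 Å — horizontal ring in the
open state, vertical planes (containing the axis) in the closed state — and,
in the closed state, a solid plug of atoms at z = 4 Å occluding the bore.
Water oxygens are placed by uniform candidate generation at the requested
number density (default 0.0334 Å⁻³, bulk water) thinned by rejection
against atom vdW spheres, which yields a uniform point process at that
density in accessible space; water–water overlap is not excluded (ideal-gas
placement). The open fixture additionally guarantees one water within 1 Å
of the axis per 1 Å slab, so its hydration column is continuous *by
construction*; the closed plug makes the z ≈ 3–5 Å slabs dry by
construction. Frames beyond the first jitter side-chain and water positions
(σ = 0.05 Å).

What the fixtures do **not** emulate: real side-chain chemistry and
flexibility, membrane/lipid atoms, curved or tilted pore axes, correlated
water dynamics, and trajectory-scale conformational drift. Passing the
fixture tests demonstrates the correctness of the geometry operations, not
that a real trajectory would show any particular SASA or hydration time
course; reproducing the study-scale trajectory numbers is explicitly out of
scope.

## Problem sizes and numerical choices

The validation recipes use desk-scale record lengths chosen so that
statistical error is comfortably below the acceptance tolerances: 200 s at
500 Hz for single-τ recovery (≈23,500 relaxations of the 8.5 ms process),
400 s for the two-component fit (≈2,700 relaxations of the slow 148 ms
component, the binding constraint), 500 s (≥300, typically ≈1,200 completed
bright dwells) for dwell recovery, and 10-seed medians wherever a single
realization would be noticeably scattered. Exponential-fit bounds are
τ ∈ [10 µs, 100 s]; Hill fits bound n ∈ [0.1, 10] and EC50 > 0; Boltzmann
fits bound z ∈ [10⁻³, 50]. Ties in the histogram mode go to the smallest
count; ties at exactly the SASA shell distance are included; dwell
durations are integer multiples of dt by construction.

## Known limitations

* The dead-time treatment assumes false crossings are isolated; at SNR ≲ 3
  the threshold idealizer degrades faster than the dead time can repair.
* `p_l1` is a time fraction; transition-based activity is reported but no
  missed-event correction is attempted (bursts shorter than the exposure
  are invisible by design).
* The exponential-decay standard errors come from the least-squares
  covariance and ignore the lag-to-lag correlation of autocovariance
  estimates; treat them as optimistic.
* The on-axis pore radius underestimates the true radius for bent pores.
* Grid SASA is a contact-style surface; it is not numerically comparable to
  probe-radius-1.4 SASA values, only to its own normalization.
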