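"""Fluctuation analysis of single-emitter fluorescence recordings.

The analysis chain for a 500 Hz trace is: optional zero-phase Gaussian
filtering at a quarter of the sampling rate, stationary noise analysis via
the normalized autocovariance C(dt) and exponential-decay fitting (the decay
constants reflect the kinetic rates of the underlying two-state process),
and threshold idealization at mu + k*sigma of the background into a basal
level L0 and an elevated level L1 with dwell-time statistics.  Photon-count
frame stacks are summarized by ROI detection on the averaged image, pooled
count histograms, and modal counts compared across conditions with a
Mann-Whitney test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.tsa.stattools import acovf

import lmfit

from .trace import FluorescenceTrace

__all__ = [
    "AutocorrDecay",
    "IdealizedTrace",
    "DwellStats",
    "BleachSteps",
    "PhotonCountSummary",
    "gaussian_filter",
    "autocovariance",
    "fit_exp_decay",
    "select_components",
    "idealize",
    "dwell_statistics",
    "count_bleach_steps",
    "define_rois",
    "photon_count_analysis",
    "compare_modes",
    "ensemble_average",
    "background_tail_mass",
]


def background_tail_mass(k_sd: float = 2.5, two_sided: bool = True) -> float:
    """Gaussian probability mass within (two_sided) or below (one-sided) k_sd.

    The two-sided mass at k_sd = 2.5 is 0.9876: the fraction of pure
    background samples a +/-2.5 sigma band retains.  Thresholding for L1 is
    one-sided (values above mu + k*sigma), so the false-positive rate per
    background sample is 1 - background_tail_mass(k_sd, two_sided=False).
    """
    if two_sided:
        return float(stats.norm.cdf(k_sd) - stats.norm.cdf(-k_sd))
    return float(stats.norm.cdf(k_sd))


def gaussian_filter(trace: FluorescenceTrace,
                    cutoff_fraction: float = 0.25) -> FluorescenceTrace:
    """Zero-phase Gaussian smoothing with -3 dB cutoff at a fraction of fs.

    ``cutoff_fraction=0.25`` reproduces the standard post-acquisition digital
    filter at one fourth of the acquisition frequency.  The Gaussian kernel
    sigma (in samples) follows from |H(f)| = exp(-2 pi^2 sigma^2 f^2) =
    1/sqrt(2) at f = cutoff_fraction cycles/sample.
    """
    if not 0 < cutoff_fraction <= 0.5:
        raise ValueError("cutoff_fraction must be in (0, 0.5]")
    sigma = math.sqrt(math.log(2)) / (2 * math.pi * cutoff_fraction)
    out = ndimage.gaussian_filter1d(trace.values, sigma, mode="nearest")
    return FluorescenceTrace(values=out, dt=trace.dt, t0=trace.t0)


def autocovariance(trace: FluorescenceTrace, max_lag: float,
                   adjusted: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Normalized autocovariance C(dt) up to ``max_lag`` seconds.

    C(dt) = <(x_t - xbar)(x_{t+dt} - xbar)> normalized so C(0) = 1.  The
    default biased (1/N) estimator keeps the implied spectrum positive
    semidefinite.  Returns (lags in seconds, C).
    """
    if max_lag >= trace.duration:
        raise ValueError("max_lag must be shorter than the trace")
    var = trace.values.var()
    if var == 0:
        raise ValueError("no fluctuations: trace variance is zero")
    nlags = int(round(max_lag / trace.dt))
    c = acovf(trace.values, adjusted=adjusted, fft=True, nlag=nlags)
    lags = np.arange(nlags + 1) * trace.dt
    return lags, c / c[0]


@dataclass
class AutocorrDecay:
    """Fitted exponential decay of a normalized autocovariance."""

    lags: np.ndarray
    c: np.ndarray
    n_components: int
    taus: np.ndarray
    amplitudes: np.ndarray
    offset: float
    fit_residual: float

    def predict(self, lags=None) -> np.ndarray:
        lags = self.lags if lags is None else np.asarray(lags, dtype=float)
        out = np.full(lags.shape, self.offset)
        for a, tau in zip(self.amplitudes, self.taus):
            out = out + a * np.exp(-lags / tau)
        return out


def _exp_design(x: np.ndarray, taus, offset: bool) -> np.ndarray:
    cols = [np.exp(-x / tau) for tau in taus]
    if offset:
        cols.append(np.ones_like(x))
    return np.stack(cols, axis=1)


def fit_exp_decay(lags, c, n_components: int = 1, offset: bool = True,
                  include_zero_lag: bool = False) -> AutocorrDecay:
    """Least-squares fit of sum_i a_i exp(-dt/tau_i) (+ constant offset).

    Initialization scans a log-spaced tau grid (1 ms - 1 s) with linear
    amplitude solves, then refines with bounded least squares (amplitudes
    >= 0).  The zero-lag point is excluded by default: it carries the
    uncorrelated camera-noise variance and the exposure-integration
    distortion, neither of which the exponential model describes.  Returned
    time constants are sorted ascending.
    """
    lags = np.asarray(lags, dtype=float)
    c = np.asarray(c, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if lags.size < 10:
        raise ValueError("need at least 10 lag points")
    if not np.all(np.isfinite(c)):
        raise ValueError("autocovariance values must be finite")
    mask = np.ones(lags.size, dtype=bool) if include_zero_lag else lags > 0
    x, y = lags[mask], c[mask]

    grid = np.geomspace(1e-3, 1.0, 25)
    best = None
    if n_components == 1:
        combos = [(tau,) for tau in grid]
    else:
        combos = [(grid[i], grid[j]) for i in range(len(grid))
                  for j in range(i + 2, len(grid))]
    for taus in combos:
        design = _exp_design(x, taus, offset)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        ssr = float(((design @ coef - y) ** 2).sum())
        if best is None or ssr < best[0]:
            best = (ssr, taus, coef)
    _, taus0, coef0 = best

    params = lmfit.Parameters()
    for i, tau in enumerate(taus0):
        params.add(f"tau{i}", value=tau, min=1e-5, max=100.0)
        amp0 = coef0[i] if coef0[i] > 0 else 0.1
        params.add(f"amp{i}", value=amp0, min=0.0)
    params.add("offset", value=coef0[-1] if offset else 0.0, vary=offset)

    def residual(p):
        model = np.full_like(x, p["offset"].value)
        for i in range(n_components):
            model = model + p[f"amp{i}"].value * np.exp(-x / p[f"tau{i}"].value)
        return model - y

    result = lmfit.minimize(residual, params, method="leastsq")
    ssr = float((result.residual ** 2).sum())
    if not result.success:
        raise RuntimeError(f"exponential fit did not converge (residual {ssr:.3g})")
    taus = np.array([result.params[f"tau{i}"].value for i in range(n_components)])
    amps = np.array([result.params[f"amp{i}"].value for i in range(n_components)])
    order = np.argsort(taus)
    return AutocorrDecay(lags=lags, c=c, n_components=n_components,
                         taus=taus[order], amplitudes=amps[order],
                         offset=float(result.params["offset"].value),
                         fit_residual=ssr)


def select_components(lags, c, ratio_threshold: float = 0.5,
                      min_amplitude_fraction: float = 0.1) -> tuple[int, float]:
    """Pick 1 vs 2 exponential components.

    Prefers two components only when (a) they at least halve the sum of
    squared residuals (SSR2/SSR1 < ratio_threshold) and (b) each component
    carries at least ``min_amplitude_fraction`` of the total amplitude.
    Both guards are deliberately conservative: autocovariance residuals are
    strongly correlated across lags (the estimator "wanders" at long lags),
    so an F-test overstates significance and an unconstrained second
    exponential happily absorbs that wander with a near-zero weight.
    Returns (n_components, ratio).
    """
    fit1 = fit_exp_decay(lags, c, n_components=1)
    fit2 = fit_exp_decay(lags, c, n_components=2)
    ratio = fit2.fit_residual / fit1.fit_residual if fit1.fit_residual > 0 else 1.0
    total = fit2.amplitudes.sum()
    balanced = total > 0 and fit2.amplitudes.min() / total >= min_amplitude_fraction
    return (2 if (ratio < ratio_threshold and balanced) else 1), ratio


@dataclass
class IdealizedTrace:
    """Two-level (L0/L1) idealization of a trace.

    ``levels`` holds the per-sample label (0 or 1); dwells are the maximal
    runs of equal labels, in seconds, in temporal order per class.  ``p_l1``
    is the fraction of samples above threshold; ``n_up_transitions`` counts
    L0->L1 crossings (the transition-based activity measure).
    """

    levels: np.ndarray
    dt: float
    threshold: float
    bg_mean: float
    bg_sd: float
    k_sd: float
    dwells_L0: np.ndarray = field(default_factory=lambda: np.empty(0))
    dwells_L1: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_l1: float = 0.0
    n_up_transitions: int = 0

    def runs(self) -> tuple[np.ndarray, np.ndarray]:
        """(level, length-in-samples) of each maximal run, in order."""
        change = np.flatnonzero(np.diff(self.levels)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [self.levels.size]])
        return self.levels[starts], ends - starts


def idealize(trace: FluorescenceTrace, bg_mean: float, bg_sd: float,
             k_sd: float = 2.5) -> IdealizedTrace:
    """Threshold idealization: L1 iff value > bg_mean + k_sd * bg_sd.

    One-sided by construction (L1 is the elevated level).  At k_sd = 2.5 a
    pure-background sample is mislabelled L1 with probability
    1 - Phi(2.5) ~ 0.62%.
    """
    if bg_sd <= 0:
        raise ValueError("bg_sd must be positive")
    threshold = bg_mean + k_sd * bg_sd
    levels = (trace.values > threshold).astype(np.int8)
    ideal = IdealizedTrace(levels=levels, dt=trace.dt, threshold=threshold,
                           bg_mean=bg_mean, bg_sd=bg_sd, k_sd=k_sd)
    run_levels, run_lengths = ideal.runs()
    dwells = run_lengths * trace.dt
    ideal.dwells_L0 = dwells[run_levels == 0]
    ideal.dwells_L1 = dwells[run_levels == 1]
    ideal.p_l1 = float(levels.mean())
    ideal.n_up_transitions = int(np.sum(np.diff(levels) == 1))
    return ideal


@dataclass
class DwellStats:
    """Mean/SEM/count of completed dwell durations per level."""

    mean_L0: float
    sem_L0: float
    n_L0: int
    mean_L1: float
    sem_L1: float
    n_L1: int


def dwell_statistics(ideal: IdealizedTrace,
                     min_duration: float = 0.0) -> DwellStats:
    """Dwell-time statistics excluding the boundary-censored dwells.

    The first and last runs of the trace are truncated by the recording
    window and are dropped.  ``min_duration`` optionally imposes a dead
    time: events shorter than it are unresolved (single-sample L1 events at
    a 2.5 sigma threshold are dominated by background tail noise) and are
    absorbed into their flanking dwells, which are then concatenated - the
    standard dead-time treatment, which also keeps dark dwells from being
    fragmented by brief false crossings.
    """
    run_levels, run_lengths = ideal.runs()
    if min_duration > 0:
        min_samples = int(round(min_duration / ideal.dt))
        levels = list(run_levels)
        lengths = list(run_lengths)
        while True:
            interior = [i for i in range(1, len(lengths) - 1)
                        if lengths[i] < min_samples]
            if not interior:
                break
            i = min(interior, key=lambda j: lengths[j])
            # runs alternate, so both neighbours share a level: merge all three
            lengths[i - 1] = lengths[i - 1] + lengths[i] + lengths[i + 1]
            del levels[i:i + 2]
            del lengths[i:i + 2]
        run_levels = np.array(levels)
        run_lengths = np.array(lengths)
    if run_levels.size <= 2:
        raise ValueError("no completed dwells: trace has too few transitions")
    run_levels = run_levels[1:-1]
    durations = run_lengths[1:-1] * ideal.dt
    out = {}
    for lvl, tag in ((0, "L0"), (1, "L1")):
        d = durations[run_levels == lvl]
        if d.size == 0:
            raise ValueError(f"no completed {tag} dwells")
        out[f"mean_{tag}"] = float(d.mean())
        out[f"sem_{tag}"] = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else 0.0
        out[f"n_{tag}"] = int(d.size)
    return DwellStats(**out)


@dataclass
class BleachSteps:
    """Downward intensity steps found by change-point segmentation."""

    n_steps: int
    step_times: np.ndarray
    step_sizes: np.ndarray
    segment_means: np.ndarray
    is_single_emitter: bool


def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Best single change point by within-segment sum of squares.

    Returns (index k splitting y[:k] | y[k:], SSE gain).  O(n) via prefix
    sums.
    """
    n = y.size
    csum = np.cumsum(y)
    csum2 = np.cumsum(y * y)
    total_sse = csum2[-1] - csum[-1] ** 2 / n
    k = np.arange(1, n)
    left_sse = csum2[k - 1] - csum[k - 1] ** 2 / k
    right_sum = csum[-1] - csum[k - 1]
    right_sse = (csum2[-1] - csum2[k - 1]) - right_sum ** 2 / (n - k)
    gain = total_sse - (left_sse + right_sse)
    best = int(np.argmax(gain))
    return k[best], float(gain[best])


def count_bleach_steps(trace: FluorescenceTrace, min_step: float,
                       min_segment: int = 3) -> BleachSteps:
    """Count statistically supported downward intensity steps.

    Iterative binary change-point segmentation minimizing within-segment
    variance; a candidate split is kept while its SSE gain exceeds a
    BIC-like penalty (2 sigma^2 log n, sigma robustly estimated from first
    differences).  Steps between adjacent segments count when the drop is at
    least ``min_step`` and at least 3x the local noise SD.  Spots with
    exactly one such step are flagged single emitters.
    """
    if min_step <= 0:
        raise ValueError("min_step must be positive")
    y = trace.values
    diffs = np.diff(y)
    sigma = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2)
    penalty = max(2 * sigma ** 2 * np.log(y.size), 1e-12)

    boundaries = [0, y.size]
    queue = [(0, y.size)]
    while queue:
        lo, hi = queue.pop()
        if hi - lo < 2 * min_segment:
            continue
        seg = y[lo:hi]
        k, gain = _best_split(seg)
        if gain <= penalty or k < min_segment or (seg.size - k) < min_segment:
            continue
        boundaries.append(lo + k)
        queue.append((lo, lo + k))
        queue.append((lo + k, hi))
    boundaries = sorted(set(boundaries))

    means = np.array([y[a:b].mean() for a, b in zip(boundaries[:-1], boundaries[1:])])
    sds = np.array([y[a:b].std(ddof=1) if b - a > 1 else 0.0
                    for a, b in zip(boundaries[:-1], boundaries[1:])])
    step_times, step_sizes = [], []
    for i in range(len(means) - 1):
        drop = means[i] - means[i + 1]
        local_sd = max(np.sqrt((sds[i] ** 2 + sds[i + 1] ** 2) / 2), sigma)
        if drop >= min_step and drop >= 3 * local_sd:
            step_times.append(trace.t0 + boundaries[i + 1] * trace.dt)
            step_sizes.append(drop)
    n = len(step_times)
    return BleachSteps(n_steps=n, step_times=np.array(step_times),
                       step_sizes=np.array(step_sizes), segment_means=means,
                       is_single_emitter=(n == 1))


def define_rois(frame_stack: np.ndarray,
                threshold_quantile: float = 0.995) -> list[np.ndarray]:
    """Detect ROIs as 4-connected components of the thresholded average image.

    The stack (n_frames, rows, cols) is averaged over frames; pixels above
    the ``threshold_quantile`` of the averaged image form the foreground.
    Returns one (n_pixels, 2) array of (row, col) indices per ROI; empty list
    when nothing crosses the threshold.
    """
    stack = np.asarray(frame_stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("frame stack must be (n_frames, rows, cols) with >= 1 frame")
    avg = stack.mean(axis=0)
    thr = np.quantile(avg, threshold_quantile)
    mask = avg > thr
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask, structure=structure)
    return [np.argwhere(labels == i) for i in range(1, n + 1)]


@dataclass
class PhotonCountSummary:
    """Pooled photon-count histograms and modal counts per pixel class."""

    histogram: dict[str, np.ndarray]
    modes: dict[str, object]
    n_replicates: int


def _histogram_mode(counts_hist: np.ndarray) -> int:
    """Smallest count value achieving the maximal frequency."""
    return int(np.argmax(counts_hist))


def photon_count_analysis(frame_stack: np.ndarray,
                          rois: list[np.ndarray]) -> PhotonCountSummary:
    """Photon statistics of spot vs background pixels.

    Pools counts over frames: spot pixels are the union of the ROIs (each
    ROI is one replicate and gets its own modal count); all other pixels are
    background.  Histograms are frequency per photon count; the mode uses
    the smallest-count tie-break.
    """
    stack = np.asarray(frame_stack)
    if stack.ndim != 3 or stack.size == 0:
        raise ValueError("frame stack must be a non-empty (n_frames, rows, cols) array")
    spot_mask = np.zeros(stack.shape[1:], dtype=bool)
    for roi in rois:
        roi = np.asarray(roi)
        spot_mask[roi[:, 0], roi[:, 1]] = True
    nbins = int(stack.max()) + 1
    spot_counts = stack[:, spot_mask].ravel()
    bg_counts = stack[:, ~spot_mask].ravel()
    hist = {
        "spot": np.bincount(spot_counts, minlength=nbins),
        "background": np.bincount(bg_counts, minlength=nbins),
    }
    roi_modes = [
        _histogram_mode(np.bincount(stack[:, roi[:, 0], roi[:, 1]].ravel(),
                                    minlength=nbins))
        for roi in rois
    ]
    modes = {
        "spot": roi_modes,
        "background": _histogram_mode(hist["background"]) if bg_counts.size else None,
    }
    return PhotonCountSummary(histogram=hist, modes=modes,
                              n_replicates=len(rois))


def compare_modes(modes_a, modes_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on replicate-level modal counts."""
    a = np.asarray(modes_a, dtype=float)
    b = np.asarray(modes_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 replicates per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def ensemble_average(traces: list[FluorescenceTrace]) -> tuple[FluorescenceTrace, np.ndarray]:
    """Pointwise mean trace and per-sample population SD across spots."""
    if not traces:
        raise ValueError("no traces")
    n = traces[0].n
    dt = traces[0].dt
    for tr in traces:
        if tr.n != n or tr.dt != dt:
            raise ValueError("traces must share length and dt")
    block = np.stack([tr.values for tr in traces])
    mean = FluorescenceTrace(values=block.mean(axis=0), dt=dt, t0=traces[0].t0)
    return mean, block.std(axis=0, ddof=0)
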