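"""Quantitative response analysis.

Everything measured on the input/output voltage pairs lives here: the
descriptive table statistics (mean, sd, median, extrema, dominant
frequency), peaks-per-second frequency estimation, FFT dB spectra,
normalized cross-correlation, two-channel PCA variance partitioning,
Savitzky-Golay smoothing, and the largest-Lyapunov-exponent estimator in
the style of Wolf et al.

Conventions
-----------
* "Peaks per second" is the rate of prominence-filtered local maxima
  (prominence >= 0.5 sd of the detrended signal by default); for a clean
  periodic signal it reduces to cycle counting.
* Spectra are reported as 20*log10(|rfft|/n), floored at -200 dB; summary
  levels are taken over the positive-frequency bins, the dominant mode over
  all bins including DC.
* Cross-correlation is Pearson-normalized so a self-pair attains exactly
  1 at zero lag; a positive lag means the second trace trails the first.
* The Lyapunov estimator tracks one nearby pair of trajectory points at a
  time (nearest neighbor in value, temporally decorrelated by a minimum
  index offset), accumulating one-step log-divergence and renormalizing
  when the separation exceeds a fraction of the data range.  The literal
  fixed-offset pairing rule is available as ``mode="fixed_offset"``; on
  bounded chaotic series it is a null statistic (separation statistics are
  stationary), which is worth knowing when comparing against near-zero
  published exponents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend, find_peaks, savgol_filter
from sklearn.decomposition import PCA

from .trace import VoltageTrace

__all__ = [
    "SignalSummary", "SpectrumSummary", "XCorrResult", "PCADecomposition",
    "LyapunovConfig", "LyapunovEstimate",
    "summarize", "peaks_per_second", "spectrum", "cross_correlate",
    "pca_input_output", "smooth_savgol", "lyapunov_wolf",
    "MetricsError", "LyapunovEstimationError",
]

DB_FLOOR = -200.0


class MetricsError(ValueError):
    pass


class LyapunovEstimationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# summary statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalSummary:
    """Table-style descriptive row: voltage statistics plus frequency."""
    mean: float
    sd: float
    median: float
    max: float
    min: float
    dominant_freq: float
    n: int

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "median": self.median,
                "max": self.max, "min": self.min,
                "dominant_freq": self.dominant_freq, "n": self.n}


def summarize(trace: VoltageTrace,
              prominence_factor: float = 0.5) -> SignalSummary:
    """Descriptive statistics of a trace, with peaks-per-second frequency."""
    v = trace.v
    if len(v) < 2:
        raise MetricsError("need at least 2 samples")
    return SignalSummary(
        mean=float(np.mean(v)), sd=float(np.std(v)),
        median=float(np.median(v)), max=float(np.max(v)),
        min=float(np.min(v)),
        dominant_freq=peaks_per_second(trace, prominence_factor),
        n=len(v))


def peaks_per_second(trace: VoltageTrace,
                     prominence_factor: float = 0.5) -> float:
    """Rate of prominent local maxima, in Hz.

    Counts interior maxima whose prominence exceeds
    ``prominence_factor * sd(detrended signal)`` and divides by the trace
    duration.  A zero-variance trace has no peaks and returns 0.
    """
    if len(trace) < 3:
        raise MetricsError("need at least 3 samples to count peaks")
    flat = detrend(trace.v, type="linear")
    sd = float(np.std(flat))
    if sd == 0.0:
        return 0.0
    peaks, _ = find_peaks(trace.v, prominence=prominence_factor * sd)
    # duration from dt*(n-1): exactly invariant under time translation
    return float(len(peaks) / (trace.dt * (len(trace) - 1)))


# --------------------------------------------------------------------------
# spectrum
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrumSummary:
    """One-sided magnitude spectrum in dB with its summary levels."""
    freqs: np.ndarray
    power_db: np.ndarray
    mean_db: float
    sd_db: float
    dominant_mode: float


def spectrum(trace: VoltageTrace, floor_db: float = DB_FLOOR) -> SpectrumSummary:
    """One-sided FFT magnitude spectrum of the mean-retained signal.

    dB convention: ``20*log10(|rfft(v)| / n)`` floored at ``floor_db``.
    ``mean_db``/``sd_db`` summarize the positive-frequency bins; the
    dominant mode is the argmax over all bins including DC.
    """
    v = trace.v
    n = len(v)
    mag = np.abs(np.fft.rfft(v)) / n
    with np.errstate(divide="ignore"):
        power_db = 20.0 * np.log10(mag)
    power_db = np.maximum(power_db, floor_db)
    freqs = np.fft.rfftfreq(n, trace.dt)
    pos = power_db[1:]
    return SpectrumSummary(
        freqs=freqs, power_db=power_db,
        mean_db=float(np.mean(pos)), sd_db=float(np.std(pos)),
        dominant_mode=float(freqs[int(np.argmax(power_db))]))


# --------------------------------------------------------------------------
# cross-correlation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class XCorrResult:
    """Normalized cross-correlation over symmetric lags.

    ``coeffs[i]`` is the Pearson-style coefficient at ``lags[i]`` samples;
    a positive lag means the second trace trails (is delayed relative to)
    the first.  Ties on the maximum magnitude break toward the smallest
    absolute lag.
    """
    lags: np.ndarray
    coeffs: np.ndarray
    max_coeff: float
    argmax_lag: int


def cross_correlate(a: VoltageTrace, b: VoltageTrace,
                    max_lag: int | None = None) -> XCorrResult:
    """Normalized (mean-removed, unit at zero-lag self-pair) cross-correlation."""
    if len(a) != len(b):
        raise MetricsError("traces must have equal length")
    if abs(a.dt - b.dt) > 1e-12 * max(a.dt, b.dt):
        raise MetricsError("traces must share dt")
    n = len(a)
    if max_lag is None:
        max_lag = n - 1
    max_lag = int(min(max_lag, n - 1))
    x = a.v - a.v.mean()
    y = b.v - b.v.mean()
    denom = np.sqrt(np.dot(x, x) * np.dot(y, y))
    if denom == 0.0:
        raise MetricsError("zero variance in one of the traces")
    # full cross-correlation; index n-1 corresponds to lag 0
    full = np.correlate(y, x, mode="full") / denom
    lags = np.arange(-max_lag, max_lag + 1)
    coeffs = full[n - 1 - max_lag: n + max_lag]
    # tie-break toward the smallest |lag|
    order = np.lexsort((np.abs(lags), -np.abs(coeffs)))
    best = order[0]
    return XCorrResult(lags=lags, coeffs=coeffs,
                       max_coeff=float(coeffs[best]),
                       argmax_lag=int(lags[best]))


# --------------------------------------------------------------------------
# PCA over the paired samples
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PCADecomposition:
    """Variance partitioning of the 2-D (input, output) sample cloud."""
    var_fraction: np.ndarray    # descending, sums to 1
    scores: np.ndarray          # (n, 2) projected coordinates
    standardized: bool
    degenerate: bool = False


def pca_input_output(a: VoltageTrace, b: VoltageTrace,
                     standardize: bool = False) -> PCADecomposition:
    """PCA of the paired (a_t, b_t) samples.

    ``standardize=True`` analyzes the correlation rather than covariance
    matrix.  A degenerate (zero-variance) channel yields fractions {1, 0}
    with a warning and the ``degenerate`` flag set.
    """
    if len(a) != len(b):
        raise MetricsError("traces must have equal length")
    X = np.column_stack([a.v, b.v]).astype(float)
    sds = X.std(axis=0)
    # a numerically constant channel (std at rounding level) is degenerate
    if np.any(sds <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))):
        warnings.warn("degenerate covariance: a channel has zero variance",
                      RuntimeWarning, stacklevel=2)
        centered = X - X.mean(axis=0)
        return PCADecomposition(var_fraction=np.array([1.0, 0.0]),
                                scores=centered, standardized=standardize,
                                degenerate=True)
    if standardize:
        X = (X - X.mean(axis=0)) / sds
    pca = PCA(n_components=2)
    scores = pca.fit_transform(X)
    return PCADecomposition(var_fraction=pca.explained_variance_ratio_.copy(),
                            scores=scores, standardized=standardize)


# --------------------------------------------------------------------------
# Savitzky-Golay smoothing
# --------------------------------------------------------------------------

def smooth_savgol(trace: VoltageTrace, order: int = 2,
                  frame: int = 15) -> VoltageTrace:
    """Least-squares local-polynomial smoothing (order 2, frame 15 default).

    Reproduces any polynomial of degree <= order exactly on interior
    samples.
    """
    if frame % 2 == 0 or frame <= order:
        raise MetricsError(
            f"frame must be odd and exceed order, got frame={frame}, order={order}")
    if len(trace) < frame:
        raise MetricsError(f"trace shorter than the {frame}-sample frame")
    return trace.with_values(savgol_filter(trace.v, frame, order))


# --------------------------------------------------------------------------
# Lyapunov exponent, Wolf-style
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LyapunovConfig:
    """Wolf-style estimator settings.

    min_separation
        Noise floor (V): candidate neighbors closer than this are skipped.
    step_offset
        Minimum temporal index distance between fiducial and neighbor —
        Wolf's decorrelation constraint (50 samples by default).
    epsilon
        Numerical guard added to separations inside the log ratio (1e-5).
    smooth_order / smooth_frame
        Savitzky-Golay pre-smoothing (order 2, frame 15); applied when
        ``presmooth`` is set.
    max_separation_frac
        Renormalization cap as a fraction of the data range (tracking
        stops and a fresh neighbor is selected once the pair separates by
        more than this).
    mode
        ``"wolf"`` (tracked nearby pairs, the reference interpretation) or
        ``"fixed_offset"`` (literal (i, i+step_offset) pairing with the
        one-step log ratio — a null statistic on bounded stationary
        series, retained for comparison with published near-zero values).
    """
    min_separation: float = 0.001
    step_offset: int = 50
    epsilon: float = 1e-5
    smooth_order: int = 2
    smooth_frame: int = 15
    max_separation_frac: float = 0.1
    mode: str = "wolf"
    presmooth: bool = False

    def __post_init__(self) -> None:
        if self.min_separation <= 0:
            raise MetricsError("min_separation must be positive")
        if self.step_offset < 1:
            raise MetricsError("step_offset must be >= 1")
        if self.smooth_frame % 2 == 0 or self.smooth_frame <= self.smooth_order:
            raise MetricsError("smooth_frame must be odd and exceed smooth_order")
        if self.mode not in ("wolf", "fixed_offset"):
            raise MetricsError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class LyapunovEstimate:
    """Largest Lyapunov exponent per sample step, with diagnostics."""
    lambda_per_step: float
    n_pairs: int
    config: LyapunovConfig

    def per_second(self, dt: float) -> float:
        return self.lambda_per_step / dt


def lyapunov_wolf(trace: VoltageTrace,
                  config: LyapunovConfig = LyapunovConfig()) -> LyapunovEstimate:
    """Estimate the largest Lyapunov exponent of a scalar voltage series.

    Negative values indicate convergence of nearby trajectories, positive
    values exponential divergence (chaos), zero neutral stability.
    """
    if len(trace) <= config.step_offset + 2:
        raise LyapunovEstimationError(
            f"trace length {len(trace)} too short for step_offset "
            f"{config.step_offset}")
    v = trace.v
    if config.presmooth:
        v = savgol_filter(v, config.smooth_frame, config.smooth_order)
    if config.mode == "fixed_offset":
        return _fixed_offset_estimate(v, config)
    return _wolf_estimate(v, config)


def _fixed_offset_estimate(v: np.ndarray, cfg: LyapunovConfig) -> LyapunovEstimate:
    k = cfg.step_offset
    d = v[:-k - 1] - v[k:-1]
    d_next = v[1:-k] - v[k + 1:]
    mask = np.abs(d) >= cfg.min_separation
    if not mask.any():
        raise LyapunovEstimationError(
            "no point pairs exceed the minimum separation "
            f"({cfg.min_separation} V); the series may be constant")
    lam = float(np.mean(np.log((np.abs(d_next[mask]) + cfg.epsilon)
                               / (np.abs(d[mask]) + cfg.epsilon))))
    return LyapunovEstimate(lambda_per_step=lam, n_pairs=int(mask.sum()),
                            config=cfg)


def _wolf_estimate(v: np.ndarray, cfg: LyapunovConfig) -> LyapunovEstimate:
    n = len(v)
    vrange = float(v.max() - v.min())
    if vrange == 0.0:
        raise LyapunovEstimationError(
            "constant series: no pairs exceed the minimum separation")
    cap = cfg.max_separation_frac * vrange
    idx = np.arange(n)
    i = 0
    total_log = 0.0
    total_steps = 0
    n_pairs = 0
    while i < n - 2:
        d0_all = np.abs(v - v[i])
        ok = ((np.abs(idx - i) >= cfg.step_offset)
              & (d0_all >= cfg.min_separation) & (idx < n - 1))
        if not ok.any():
            break
        j = int(idx[ok][np.argmin(d0_all[ok])])
        # evolve the pair until the separation exceeds the cap
        t = 1
        while i + t < n and j + t < n:
            if abs(v[i + t] - v[j + t]) > cap:
                break
            t += 1
        t_end = min(t, n - 1 - i, n - 1 - j)
        if t_end < 1:
            break
        d_start = abs(v[i] - v[j])
        d_end = abs(v[i + t_end] - v[j + t_end])
        total_log += float(np.log((d_end + cfg.epsilon)
                                  / (d_start + cfg.epsilon)))
        total_steps += t_end
        n_pairs += 1
        i += t_end
    if n_pairs == 0 or total_steps == 0:
        raise LyapunovEstimationError(
            "no qualifying point pairs above the minimum separation "
            f"({cfg.min_separation} V)")
    return LyapunovEstimate(lambda_per_step=total_log / total_steps,
                            n_pairs=n_pairs, config=cfg)
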