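"""Phenomenological surrogate of the proteinoid-actin transfer function.

The bio-composite transforms its drive in a few robust, measurable ways:
strong amplitude suppression (5-30x), a bounded output range, approximate
preservation of the dominant spectral mode (with a small shift in some
regimes), small additive noise, and — when coupled through a synaptic-like
sigmoid — all-or-none spiking above a midpoint threshold.  This module
encodes exactly those transfer signatures and nothing mechanistic:

    output = clamp(gain * lowpass(input) + offset, v_min, v_max) + noise

The smoothing kernel is a zero-phase moving average, so the noise-free map
is deterministic and commutes with time reversal.  Per-system presets ship
under ``protact/presets`` approximating the published per-drive output
statistics; they are presets, not ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources

import numpy as np
from scipy.ndimage import uniform_filter1d

from .trace import VoltageTrace

__all__ = ["SurrogateParams", "SigmoidCoupling", "apply_surrogate",
           "apply_sigmoid_coupling", "recover_surrogate_params",
           "load_preset", "SurrogateConfigError", "EstimationError"]


class SurrogateConfigError(ValueError):
    pass


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SurrogateParams:
    """Transfer-signature parameters of the composite.

    gain
        Attenuation factor (dimensionless, > 0); the composite's observed
        clamping regimes correspond to gains of roughly 1/30 to 1/5.
    offset
        Additive resting offset, volts.
    v_min, v_max
        Hard output clamp, volts (the composite's bounded response range).
    lp_cutoff
        Low-pass cutoff in Hz for the zero-phase smoothing kernel;
        ``None`` disables smoothing.
    freq_shift
        Optional shift of the dominant mode in Hz, implemented by uniform
        resampling of the time axis; 0 disables it (default — the observed
        ~0.05 Hz shift is a phenomenon, not a mechanism).
    noise_sd
        Additive Gaussian noise, volts; seeded, 0 for a deterministic map.
    """
    gain: float = 0.05
    offset: float = 0.0
    v_min: float = -np.inf
    v_max: float = np.inf
    lp_cutoff: float | None = None
    freq_shift: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise SurrogateConfigError("gain must be positive")
        if not self.v_min < self.v_max:
            raise SurrogateConfigError("v_min must be below v_max")
        if self.noise_sd < 0:
            raise SurrogateConfigError("noise_sd must be nonnegative")


def _lowpass(v: np.ndarray, dt: float, cutoff: float) -> np.ndarray:
    """Zero-phase moving average with window ~ 1/(2 * cutoff)."""
    nyquist = 0.5 / dt
    if cutoff >= nyquist:
        raise SurrogateConfigError(
            f"lp_cutoff {cutoff} Hz is at or above Nyquist ({nyquist} Hz)")
    window = max(1, int(round(1.0 / (2.0 * cutoff * dt))))
    if window % 2 == 0:
        window += 1
    if window <= 1:
        return v.copy()
    return uniform_filter1d(v, size=window, mode="nearest")


def apply_surrogate(trace: VoltageTrace, params: SurrogateParams) -> VoltageTrace:
    """Map a drive through the composite's phenomenological transfer."""
    v = trace.v
    if params.lp_cutoff is not None:
        v = _lowpass(v, trace.dt, params.lp_cutoff)
    v = params.gain * v + params.offset
    v = np.clip(v, params.v_min, params.v_max)
    if params.freq_shift:
        v = _shift_dominant_mode(v, trace.dt, params.freq_shift)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        v = v + rng.normal(0.0, params.noise_sd, size=v.shape)
    return trace.with_values(v, label=f"{trace.label} -> composite",
                             meta={**trace.meta, "surrogate": asdict_clean(params)})


def _shift_dominant_mode(v: np.ndarray, dt: float, shift: float) -> np.ndarray:
    """Shift the dominant frequency by ``shift`` Hz via uniform resampling."""
    from scipy.signal import resample
    spec = np.abs(np.fft.rfft(v - v.mean()))
    freqs = np.fft.rfftfreq(len(v), dt)
    f0 = freqs[int(np.argmax(spec))]
    if f0 <= 0:
        return v
    factor = (f0 + shift) / f0
    if factor <= 0:
        raise SurrogateConfigError(
            f"freq_shift {shift} Hz would invert the dominant mode at {f0} Hz")
    stretched = resample(v, max(2, int(round(len(v) / factor))))
    idx = np.minimum(np.arange(len(v)), len(stretched) - 1)
    return np.asarray(stretched)[idx]


@dataclass(frozen=True)
class SigmoidCoupling:
    """Synaptic-like logistic coupling: midpoint c (V) and slope m."""
    midpoint_c: float = 0.5
    slope_m: float = 10.0

    def __post_init__(self) -> None:
        if not self.slope_m > 0:
            raise SurrogateConfigError("slope_m must be positive")


def apply_sigmoid_coupling(trace: VoltageTrace,
                           coupling: SigmoidCoupling) -> VoltageTrace:
    """Pointwise logistic transform 1 / (1 + exp(-m (v - c))).

    Monotone nondecreasing in the input; at the midpoint the output is the
    half-maximum 0.5, and for large slope m it approaches the all-or-none
    step that mimics action-potential firing.
    """
    z = coupling.slope_m * (trace.v - coupling.midpoint_c)
    out = 0.5 * (1.0 + np.tanh(z / 2.0))  # numerically stable logistic
    return trace.with_values(out, label=f"{trace.label} -> sigmoid")


def recover_surrogate_params(inp: VoltageTrace, out: VoltageTrace,
                             clamp_tol: float = 1e-12) -> SurrogateParams:
    """Moment-based estimator of the surrogate transfer parameters.

    gain   = cov(input, output) / var(input) over samples away from the
             clamp rails — the closed-form slope; unlike the raw std ratio
             it stays consistent under additive output noise;
    offset = mean(output - gain * input) over the same samples;
    v_min/v_max = output extrema (exact when the clamp is active and the
             noise is off).

    This is a documented closed-form estimator, not an iterative fit; it is
    unbiased only when smoothing is mild and clamping spares most samples.
    """
    if len(inp) != len(out):
        raise EstimationError("paired traces must have equal length")
    x, y = inp.v, out.v
    v_min, v_max = float(y.min()), float(y.max())
    interior = (y > v_min + clamp_tol) & (y < v_max - clamp_tol)
    if interior.sum() < max(10, 0.1 * len(y)):
        interior = np.ones(len(y), bool)  # heavily clamped: use everything
    var_x = float(np.var(x[interior]))
    if var_x == 0.0:
        raise EstimationError("input has zero variance; gain unidentifiable")
    cov = float(np.cov(x[interior], y[interior], bias=True)[0, 1])
    gain = abs(cov) / var_x
    if gain == 0.0:
        raise EstimationError("zero covariance; gain unidentifiable")
    offset = float(np.mean(y[interior] - gain * x[interior]))
    return SurrogateParams(gain=gain, offset=offset, v_min=v_min, v_max=v_max)


def asdict_clean(params: SurrogateParams) -> dict:
    d = asdict(params)
    for k, v in list(d.items()):
        if isinstance(v, float) and not np.isfinite(v):
            d[k] = None
    return d


def load_preset(name: str) -> SurrogateParams:
    """Load a per-system preset (logistic, baker, lorenz, rossler, fhn)."""
    ref = resources.files("protact").joinpath(f"presets/{name}.json")
    try:
        data = json.loads(ref.read_text())
    except FileNotFoundError:
        raise KeyError(f"no preset named {name!r}") from None
    for key in ("v_min", "v_max"):
        if data.get(key) is None:
            data[key] = -np.inf if key == "v_min" else np.inf
    return SurrogateParams(**data)
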