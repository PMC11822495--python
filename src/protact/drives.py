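"""Chaotic stimulus generators.

Five waveform families drive the bio-composite: the discrete logistic map,
the baker transformation on the unit square, the Lorenz and Rossler
attractors, the FitzHugh-Nagumo excitable oscillator, plus seeded binary
pulse trains.  Map iterates are emitted one-per-sample on a configurable
playback interval; the flows are integrated with a fixed-step classical
fourth-order Runge-Kutta scheme (step 0.01 s by default) and a single state
component is scaled to volts.

All generators are pure functions of (params, seed): repeated calls are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .trace import VoltageTrace

__all__ = [
    "LogisticParams", "BakerParams", "LorenzParams", "RosslerParams",
    "FHNParams", "PulseTrainParams",
    "generate_logistic", "generate_baker", "generate_lorenz",
    "generate_rossler", "generate_fhn", "generate_pulse_train",
    "rk4_integrate", "DriveDomainError", "IntegrationError",
]


class DriveDomainError(ValueError):
    """Parameter or initial condition outside the generator's domain."""


class IntegrationError(RuntimeError):
    """Non-finite state encountered during fixed-step integration."""


# --------------------------------------------------------------------------
# discrete maps
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticParams:
    """Logistic difference equation x(n+1) = mu * x(n) * (1 - x(n)).

    The chaotic regime used for stimulation is mu = 3.8 with 10,000
    iterates, linearly rescaled from the unit interval to [v_lo, v_hi]
    (-500 to +500 mV).  ``x0=None`` draws the start uniformly on
    (0.01, 0.99), avoiding the absorbing endpoints; the seed is then
    mandatory for reproducibility.
    """
    mu: float = 3.8
    x0: float | None = None
    n_iter: int = 10_000
    v_lo: float = -0.5
    v_hi: float = 0.5
    dt: float = 0.01       # playback interval per iterate, seconds
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.mu <= 4.0):
            raise DriveDomainError(
                f"mu must lie in (0, 4], got {self.mu}; iterates of the "
                "logistic map leave [0, 1] for mu > 4")
        if self.x0 is not None and not (0.0 < self.x0 < 1.0):
            raise DriveDomainError(f"x0 must lie in (0, 1), got {self.x0}")
        if not self.v_lo < self.v_hi:
            raise DriveDomainError("v_lo must be below v_hi")
        if self.n_iter < 2:
            raise DriveDomainError("n_iter must be at least 2")
        if self.x0 is None and self.seed is None:
            raise DriveDomainError("seed is required when x0 is drawn randomly")


def generate_logistic(params: LogisticParams) -> VoltageTrace:
    """Iterate the logistic map and rescale the orbit to volts."""
    if params.x0 is None:
        rng = np.random.default_rng(params.seed)
        x = float(rng.uniform(0.01, 0.99))
    else:
        x = params.x0
    orbit = np.empty(params.n_iter)
    orbit[0] = x
    for i in range(1, params.n_iter):
        x = params.mu * x * (1.0 - x)
        orbit[i] = x
    v = params.v_lo + (params.v_hi - params.v_lo) * orbit
    return VoltageTrace.from_samples(
        v, dt=params.dt, label=f"logistic mu={params.mu:g}",
        meta={"system": "logistic", "mu": params.mu, "n_iter": params.n_iter,
              "seed": params.seed})


@dataclass(frozen=True)
class BakerParams:
    """Generalized area-preserving baker transformation on the unit square.

    For fold parameter alpha the square is cut at x = alpha, each strip is
    stretched to full width and compressed in height, and the right strip
    is stacked on top:

        x < alpha:  (x/alpha,         alpha*y)
        x >= alpha: ((x-alpha)/(1-alpha), alpha + (1-alpha)*y)

    The chosen coordinate is linearly scaled to [v_lo, v_hi].
    """
    alpha: float = 0.5
    x0: float = 0.3
    y0: float = 0.4
    n_iter: int = 10_000
    v_lo: float = -0.5
    v_hi: float = 0.5
    component: str = "x"
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise DriveDomainError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0.0 <= self.x0 <= 1.0 and 0.0 <= self.y0 <= 1.0):
            raise DriveDomainError(
                f"initial point ({self.x0}, {self.y0}) outside the unit square")
        if self.component not in ("x", "y"):
            raise DriveDomainError(f"component must be x or y, got {self.component}")
        if not self.v_lo < self.v_hi:
            raise DriveDomainError("v_lo must be below v_hi")


def baker_step(x: float, y: float, alpha: float) -> tuple[float, float]:
    """One stretch-and-fold iterate of the generalized baker map."""
    if x < alpha:
        return x / alpha, alpha * y
    return (x - alpha) / (1.0 - alpha), alpha + (1.0 - alpha) * y


def generate_baker(params: BakerParams) -> VoltageTrace:
    """Iterate the baker transformation; emit one coordinate in volts."""
    x, y = params.x0, params.y0
    xs = np.empty(params.n_iter)
    ys = np.empty(params.n_iter)
    xs[0], ys[0] = x, y
    for i in range(1, params.n_iter):
        x, y = baker_step(x, y, params.alpha)
        xs[i], ys[i] = x, y
    coord = xs if params.component == "x" else ys
    v = params.v_lo + (params.v_hi - params.v_lo) * coord
    return VoltageTrace.from_samples(
        v, dt=params.dt, label=f"baker alpha={params.alpha:g}",
        meta={"system": "baker", "alpha": params.alpha,
              "component": params.component, "n_iter": params.n_iter})


# --------------------------------------------------------------------------
# continuous flows: fixed-step RK4
# --------------------------------------------------------------------------

def rk4_integrate(rhs: Callable[[float, np.ndarray], np.ndarray],
                  y0: Sequence[float], dt: float, n_steps: int) -> np.ndarray:
    """Classical fixed-step fourth-order Runge-Kutta.

    Returns an array of shape ``(n_steps + 1, len(y0))`` including the
    initial state.  Raises :class:`IntegrationError` naming the step at
    which the state first became non-finite.
    """
    y = np.asarray(y0, dtype=float)
    out = np.empty((n_steps + 1, y.size))
    out[0] = y
    h = float(dt)
    for i in range(n_steps):
        t = i * h
        k1 = rhs(t, y)
        k2 = rhs(t + h / 2.0, y + h / 2.0 * k1)
        k3 = rhs(t + h / 2.0, y + h / 2.0 * k2)
        k4 = rhs(t + h, y + h * k3)
        y = y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state at step {i + 1}")
        out[i + 1] = y
    return out


_COMPONENT_INDEX = {"x": 0, "y": 1, "z": 2}


def _check_flow(dt: float, duration: float, scale: float) -> None:
    if not dt > 0:
        raise DriveDomainError(f"dt must be positive, got {dt}")
    if not duration > dt:
        raise DriveDomainError("duration must exceed dt")
    if not scale > 0:
        raise DriveDomainError("scale must be positive")


@dataclass(frozen=True)
class LorenzParams:
    """Lorenz convection system, chaotic at sigma=10, rho=28, beta=8/3.

    Integrated from y0 = [0, 1, 1.05] with RK4 at step 0.01 s over 100 s;
    the x-component (times ``scale`` volts per state-unit) is the stimulus.
    """
    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    y0: tuple[float, float, float] = (0.0, 1.0, 1.05)
    dt: float = 0.01
    duration: float = 100.0
    scale: float = 1.0
    component: str = "x"

    def __post_init__(self) -> None:
        _check_flow(self.dt, self.duration, self.scale)
        if self.component not in _COMPONENT_INDEX:
            raise DriveDomainError(f"component must be one of x/y/z")


def lorenz_rhs(params: LorenzParams) -> Callable[[float, np.ndarray], np.ndarray]:
    s, r, b = params.sigma, params.rho, params.beta

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return np.array([s * (y[1] - y[0]),
                         y[0] * (r - y[2]) - y[1],
                         y[0] * y[1] - b * y[2]])
    return rhs


def generate_lorenz(params: LorenzParams) -> VoltageTrace:
    n = int(np.floor(params.duration / params.dt))
    traj = rk4_integrate(lorenz_rhs(params), params.y0, params.dt, n)
    v = params.scale * traj[:, _COMPONENT_INDEX[params.component]]
    return VoltageTrace.from_samples(
        v, dt=params.dt, label="lorenz",
        meta={"system": "lorenz", "sigma": params.sigma, "rho": params.rho,
              "beta": params.beta, "component": params.component,
              "scale": params.scale})


@dataclass(frozen=True)
class RosslerParams:
    """Rossler system, chaotic at a = b = 0.2, c = 5.7."""
    a: float = 0.2
    b: float = 0.2
    c: float = 5.7
    y0: tuple[float, float, float] = (0.0, 1.0, 1.05)
    dt: float = 0.01
    duration: float = 100.0
    scale: float = 1.0
    component: str = "x"

    def __post_init__(self) -> None:
        _check_flow(self.dt, self.duration, self.scale)
        if self.component not in _COMPONENT_INDEX:
            raise DriveDomainError("component must be one of x/y/z")


def rossler_rhs(params: RosslerParams) -> Callable[[float, np.ndarray], np.ndarray]:
    a, b, c = params.a, params.b, params.c

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return np.array([-y[1] - y[2],
                         y[0] + a * y[1],
                         b + y[2] * (y[0] - c)])
    return rhs


def generate_rossler(params: RosslerParams) -> VoltageTrace:
    n = int(np.floor(params.duration / params.dt))
    traj = rk4_integrate(rossler_rhs(params), params.y0, params.dt, n)
    v = params.scale * traj[:, _COMPONENT_INDEX[params.component]]
    return VoltageTrace.from_samples(
        v, dt=params.dt, label="rossler",
        meta={"system": "rossler", "a": params.a, "b": params.b, "c": params.c,
              "component": params.component, "scale": params.scale})


@dataclass(frozen=True)
class FHNParams:
    """FitzHugh-Nagumo excitable oscillator.

        dv/dt = v - v^3/3 - w + c
        dw/dt = eps*(v + a) - gamma*w + bias

    ``v`` is the fast activation variable, ``w`` the slow recovery variable;
    ``c`` is the constant drive current.  The recovery bias sets the tonic
    recovery current and thereby the spiking rheobase; at the defaults
    (a = eps = gamma = 0.1, bias = 0.2) the rheobase sits at c ~ 1.7, so the
    system is quiescent at c = 1 and fires a sustained limit cycle at c = 2.
    """
    a: float = 0.1
    c: float = 1.0
    epsilon: float = 0.1
    gamma: float = 0.1
    bias: float = 0.2
    v0: float = 0.0
    w0: float = 0.0
    dt: float = 0.01
    duration: float = 100.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        _check_flow(self.dt, self.duration, self.scale)


def fhn_rhs(params: FHNParams) -> Callable[[float, np.ndarray], np.ndarray]:
    a, c = params.a, params.c
    eps, gam, b = params.epsilon, params.gamma, params.bias

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        v, w = y[0], y[1]
        return np.array([v - v ** 3 / 3.0 - w + c,
                         eps * (v + a) - gam * w + b])
    return rhs


def generate_fhn(params: FHNParams) -> tuple[VoltageTrace, VoltageTrace]:
    """Integrate the FitzHugh-Nagumo pair; returns (v, w) traces in volts."""
    n = int(np.floor(params.duration / params.dt))
    traj = rk4_integrate(fhn_rhs(params), (params.v0, params.w0),
                         params.dt, n)
    meta = {"system": "fhn", "a": params.a, "c": params.c,
            "epsilon": params.epsilon, "gamma": params.gamma,
            "bias": params.bias, "scale": params.scale}
    v_tr = VoltageTrace.from_samples(params.scale * traj[:, 0], dt=params.dt,
                                     label=f"fhn v (c={params.c:g})", meta=meta)
    w_tr = VoltageTrace.from_samples(params.scale * traj[:, 1], dt=params.dt,
                                     label=f"fhn w (c={params.c:g})", meta=meta)
    return v_tr, w_tr


# --------------------------------------------------------------------------
# binary pulse trains
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseTrainParams:
    """Seeded random bit stream rendered as a bipolar pulse train.

    Bits are drawn uniformly at ``bit_dt`` resolution (1 ms); each 1-bit
    holds the channel at ``v_high`` (+500 mV) for ``pulse_width`` (100 ms)
    from its onset, each 0-bit holds ``v_low`` (-500 mV).
    """
    n_bits: int = 1000
    bit_dt: float = 1e-3
    pulse_width: float = 0.1
    v_high: float = 0.5
    v_low: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pulse_width < self.bit_dt:
            raise DriveDomainError("pulse_width must be at least bit_dt")
        if not self.v_low < self.v_high:
            raise DriveDomainError("v_low must be below v_high")
        if self.n_bits < 2:
            raise DriveDomainError("n_bits must be at least 2")


def generate_pulse_train(params: PulseTrainParams):
    """Return ``(bits, trace)``: the seeded bit stream and its pulse train.

    Later pulse onsets overwrite earlier ones where widths overlap, so each
    sample reflects the most recent bit whose pulse window covers it.
    """
    from .otl import BitStream  # local import to avoid a cycle

    rng = np.random.default_rng(params.seed)
    bits = rng.integers(0, 2, size=params.n_bits).astype(np.uint8)
    width = int(round(params.pulse_width / params.bit_dt))
    n_samples = (params.n_bits - 1) + width
    v = np.full(n_samples, params.v_low)
    for i, b in enumerate(bits):
        level = params.v_high if b else params.v_low
        v[i:i + width] = level
    trace = VoltageTrace.from_samples(
        v, dt=params.bit_dt, label="pulse train",
        meta={"system": "bits", "seed": params.seed, "n_bits": params.n_bits,
              "pulse_width": params.pulse_width})
    stream = BitStream(bits=bits, dt=params.bit_dt, origin="pulse_train")
    return stream, trace
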