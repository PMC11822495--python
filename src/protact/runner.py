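"""End-to-end experiment orchestration.

One experiment mirrors the per-system characterization workflow:
generate (or load) a chaotic drive, transform it through the response
surrogate (or pair it with a deposited recording), run the full analysis
suite on the input/output pair, threshold the four OTL channels, and emit
a JSON report plus optional table text and figures.  Every random element
is seeded through the config, so re-running a config is bit-identical on
all non-stochastic fields (and on the stochastic ones too, given the same
seeds).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import drives
from .metrics import (LyapunovConfig, LyapunovEstimationError, cross_correlate,
                      lyapunov_wolf, pca_input_output, spectrum, summarize)
from .otl import ThresholdSpec, otl_pipeline, write_gate_matrix
from .surrogate import SurrogateParams, apply_surrogate, load_preset
from .trace import VoltageTrace, read_trace, write_trace

__all__ = ["ExperimentConfig", "run_experiment", "analyze_pair",
            "generate_drive", "report_to_json", "ConfigError"]


class ConfigError(ValueError):
    pass


_GENERATORS = {
    "logistic": (drives.LogisticParams, drives.generate_logistic),
    "baker": (drives.BakerParams, drives.generate_baker),
    "lorenz": (drives.LorenzParams, drives.generate_lorenz),
    "rossler": (drives.RosslerParams, drives.generate_rossler),
    "fhn": (drives.FHNParams, None),           # returns the v-trace
    "bits": (drives.PulseTrainParams, None),   # returns the pulse trace
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Full parameterization of one generate->respond->analyze->OTL run.

    ``drive_params`` are keyword arguments for the chosen system's params
    dataclass; ``surrogate`` is either a :class:`SurrogateParams`, the name
    of a shipped preset, or ``None`` when ``response_path`` points at a
    recorded response trace.
    """
    system: str = "logistic"
    drive_params: dict = field(default_factory=dict)
    surrogate: SurrogateParams | str | None = "logistic"
    response_path: str | None = None
    seed: int = 0
    lyapunov: LyapunovConfig = field(default_factory=LyapunovConfig)
    otl: ThresholdSpec = field(default_factory=ThresholdSpec)
    pca_standardize: bool = False
    xcorr_max_lag: int = 500
    outdir: str | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.system not in _GENERATORS:
            raise ConfigError(
                f"unknown system {self.system!r}; choose from "
                f"{sorted(_GENERATORS)}")
        if self.surrogate is None and self.response_path is None:
            raise ConfigError("need either a surrogate or a response_path")

    def config_hash(self) -> str:
        """Stable hash of the full configuration for provenance."""
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def generate_drive(system: str, drive_params: dict, seed: int) -> VoltageTrace:
    """Instantiate a drive generator by name and produce its trace."""
    cls, fn = _GENERATORS[system]
    kwargs = dict(drive_params)
    if "seed" in {f.name for f in dataclasses.fields(cls)}:
        kwargs.setdefault("seed", seed)
    params = cls(**kwargs)
    if system == "fhn":
        v, _w = drives.generate_fhn(params)
        return v
    if system == "bits":
        _bits, tr = drives.generate_pulse_train(params)
        return tr
    return fn(params)


def analyze_pair(inp: VoltageTrace, out: VoltageTrace,
                 lyap: LyapunovConfig = LyapunovConfig(),
                 pca_standardize: bool = False,
                 xcorr_max_lag: int = 500) -> dict:
    """Full analysis block for one input/output pair.

    Returns the table-row statistics and spectrum summary per trace, the
    cross-correlation and PCA of the pair, both Lyapunov exponents, and the
    input->output ratios (sd attenuation, dominant-frequency ratio).
    """
    block: dict = {}
    for name, tr in (("input", inp), ("output", out)):
        s = summarize(tr)
        sp = spectrum(tr)
        block[name] = {
            "summary": s.as_dict(),
            "spectrum": {"mean_db": sp.mean_db, "sd_db": sp.sd_db,
                         "dominant_mode_hz": sp.dominant_mode},
            "lyapunov": _lyap_block(tr, lyap),
        }
    xc = cross_correlate(inp, out, max_lag=xcorr_max_lag)
    block["cross_correlation"] = {"max_coeff": xc.max_coeff,
                                  "argmax_lag": xc.argmax_lag}
    pca = pca_input_output(inp, out, standardize=pca_standardize)
    block["pca"] = {"var_fraction": [float(f) for f in pca.var_fraction],
                    "standardized": pca.standardized,
                    "degenerate": pca.degenerate}
    in_sd = block["input"]["summary"]["sd"]
    out_sd = block["output"]["summary"]["sd"]
    in_f = block["input"]["summary"]["dominant_freq"]
    out_f = block["output"]["summary"]["dominant_freq"]
    block["transfer"] = {
        "sd_ratio": out_sd / in_sd if in_sd > 0 else None,
        "attenuation_fold": in_sd / out_sd if out_sd > 0 else None,
        "freq_ratio": out_f / in_f if in_f > 0 else None,
        "freq_shift_hz": out_f - in_f,
    }
    return block


def _lyap_block(tr: VoltageTrace, cfg: LyapunovConfig) -> dict:
    try:
        est = lyapunov_wolf(tr, cfg)
        return {"lambda_per_step": est.lambda_per_step,
                "n_pairs": est.n_pairs}
    except LyapunovEstimationError as exc:
        return {"lambda_per_step": None, "n_pairs": 0, "error": str(exc)}


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the full chain deterministically and return the report."""
    try:
        inp = generate_drive(config.system, config.drive_params, config.seed)
    except Exception as exc:
        raise RuntimeError(
            f"[drive stage, config {config.config_hash()}] {exc}") from exc

    try:
        if config.response_path is not None:
            out = read_trace(config.response_path)
        else:
            sur = config.surrogate
            if isinstance(sur, str):
                sur = load_preset(sur)
            sur = dataclasses.replace(sur, seed=config.seed)
            out = apply_surrogate(inp, sur)
    except Exception as exc:
        raise RuntimeError(
            f"[response stage, config {config.config_hash()}] {exc}") from exc

    try:
        analysis = analyze_pair(inp, out, lyap=config.lyapunov,
                                pca_standardize=config.pca_standardize,
                                xcorr_max_lag=config.xcorr_max_lag)
    except Exception as exc:
        raise RuntimeError(
            f"[analysis stage, config {config.config_hash()}] {exc}") from exc

    try:
        # two-channel OTL: the pair of drive channels (seed, seed+1) and
        # their responses populate V1/W1
        w_in = generate_drive(config.system, config.drive_params,
                              config.seed + 1)
        if config.response_path is not None:
            w_out = out
        else:
            sur = config.surrogate
            if isinstance(sur, str):
                sur = load_preset(sur)
            sur = dataclasses.replace(sur, seed=config.seed + 1)
            w_out = apply_surrogate(w_in, sur)
        gates = otl_pipeline(inp, w_in, out, w_out, config.otl)
        switch_rate = float(np.mean(np.abs(np.diff(
            gates.column("OTL").astype(np.int8)))))
        otl_block = {"theta": config.otl.theta, "tau_min": config.otl.tau_min,
                     "high_fraction": {
                         g: float(gates.column(g).mean())
                         for g in gates.gates},
                     "otl_switch_rate": switch_rate}
    except Exception as exc:
        raise RuntimeError(
            f"[otl stage, config {config.config_hash()}] {exc}") from exc

    report = {
        "provenance": {
            "config_hash": config.config_hash(),
            "system": config.system,
            "seed": config.seed,
            "drive_params": _jsonable(config.drive_params),
            "lyapunov_config": _jsonable(asdict(config.lyapunov)),
            "theta": config.otl.theta, "tau_min": config.otl.tau_min,
        },
        "analysis": analysis,
        "otl": otl_block,
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trace(inp, outdir / "input.csv")
        write_trace(out, outdir / "output.csv")
        write_gate_matrix(gates, outdir / "gates.csv")
        (outdir / "report.json").write_text(report_to_json(report))
        (outdir / "table.txt").write_text(format_table(analysis))
        if config.make_plots:
            from .otl import plot_gate_heatmap
            plot_gate_heatmap(gates, outdir / "gates.png")
    return report


def format_table(analysis: dict) -> str:
    """Side-by-side input/output statistics in the published table layout."""
    rows = [("mean", "mean"), ("std. dev.", "sd"), ("median", "median"),
            ("max", "max"), ("min", "min"),
            ("frequency [Hz]", "dominant_freq")]
    lines = [f"{'metric':<16}{'input':>12}{'output':>12}"]
    for label, key in rows:
        a = analysis["input"]["summary"][key]
        b = analysis["output"]["summary"][key]
        lines.append(f"{label:<16}{a:>12.3f}{b:>12.3f}")
    return "\n".join(lines) + "\n"


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def report_to_json(report: dict) -> str:
    return json.dumps(_jsonable(report), indent=2, sort_keys=True)
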