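"""Experiment orchestration: config-driven sweeps with checkpointed outputs.

An experiment is a YAML config (kind + parameter template + grids +
integrator/metric settings).  `run_experiment` validates the config before
any compute, dispatches to the analysis modules, writes CSV results, a
summary JSON and the fully-resolved config next to them, and skips
completed runs (matching config hash) on re-execution.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .hybrid_model import NeuronParams, SignalParams
from .poincare_bifurcation import lyapunov_map, sweep_bifurcation
from .response_metrics import (
    lambda_binned_scatter,
    resonance_map,
    response_sweep,
    spectrum_of_model,
)

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "load_bundled_config",
    "bundled_config_names",
]

log = logging.getLogger("chaores")

KINDS = ("sweep_d", "map_cd", "response_sweep", "resonance_map", "spectrum")


def _linrange(lo: float, hi: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((hi - lo) / step))
    if n < 0:
        raise ValueError(f"empty range [{lo}, {hi}]")
    return np.round(lo + step * np.arange(n + 1), 12)


@dataclass
class ExperimentConfig:
    """Flat, fully serializable description of one experiment."""

    name: str
    kind: str
    params: dict = field(default_factory=dict)
    signal: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    integrator: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)

    def resolved(self) -> dict:
        """Config with every default filled in (what the run actually uses)."""
        out = self.to_dict()
        out["integrator"] = {
            "rtol": 1e-10, "atol": 1e-12, "max_step": 5.0, **self.integrator
        }
        metrics = dict(self.metrics)
        if self.kind in ("sweep_d", "map_cd"):
            metrics.setdefault("n_segments", 50)
        if self.kind == "sweep_d":
            metrics.setdefault("settle", 2000)
            metrics.setdefault("tail_keep", 64)
        if self.kind in ("response_sweep", "resonance_map"):
            metrics.setdefault("periods", 10_000 if self.kind == "response_sweep" else 2000)
            metrics.setdefault("n_lags", 200)
        if self.kind == "response_sweep":
            metrics.setdefault("lyapunov", "forced")
            metrics.setdefault("n_segments", 50)
            metrics.setdefault("lambda_window", 0.001)
        if self.kind == "spectrum":
            metrics.setdefault("duration", 8192.0)
            metrics.setdefault("sample_dt", 0.1)
        out["metrics"] = metrics
        return out

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}; one of {KINDS}")
        for key in ("a", "b", "c", "d", "I"):
            if key not in self.params:
                raise ValueError(f"params.{key} is required")
        self.neuron_params()  # raises on invalid constants
        if self.kind in ("sweep_d", "response_sweep"):
            s = self.sweep
            if not all(k in s for k in ("d_min", "d_max", "d_step")):
                raise ValueError("sweep needs d_min, d_max, d_step")
            if len(_linrange(s["d_min"], s["d_max"], s["d_step"])) == 0:
                raise ValueError("empty d range")
        if self.kind == "map_cd":
            s = self.sweep
            for k in ("c_min", "c_max", "c_step", "d_min", "d_max", "d_step"):
                if k not in s:
                    raise ValueError(f"sweep.{k} is required for map_cd")
        if self.kind == "resonance_map":
            s = self.sweep
            if not all(k in s for k in ("f0_values", "A_values")):
                raise ValueError("sweep needs f0_values and A_values")
            if len(s["f0_values"]) == 0 or len(s["A_values"]) == 0:
                raise ValueError("empty (f0, A) grid")
        if self.kind in ("response_sweep", "resonance_map"):
            sig = self.signal_params()
            if self.kind == "response_sweep" and sig.A <= 0:
                raise ValueError("response_sweep requires signal.A > 0")

    # -- typed accessors ---------------------------------------------------
    def neuron_params(self) -> NeuronParams:
        p = self.params
        return NeuronParams(a=p["a"], b=p["b"], c=p["c"], d=p["d"], I=p["I"])

    def signal_params(self) -> SignalParams:
        return SignalParams(
            A=self.signal.get("A", 0.0), f0=self.signal.get("f0", 0.1)
        )


def bundled_config_names() -> list[str]:
    files = resources.files("chaores") / "configs"
    return sorted(p.stem for p in files.iterdir() if p.name.endswith(".yaml"))


def load_bundled_config(name: str) -> ExperimentConfig:
    files = resources.files("chaores") / "configs" / f"{name}.yaml"
    return ExperimentConfig.from_dict(yaml.safe_load(files.read_text()))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def run_experiment(
    config: ExperimentConfig, outdir, force: bool = False
) -> dict:
    """Execute one experiment, writing results + summary under `outdir`.

    Idempotent: when a summary with a matching config hash already exists
    the run is skipped and the stored summary returned.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary_path = outdir / "summary.json"
    chash = config.config_hash()
    if summary_path.exists() and not force:
        try:
            prev = json.loads(summary_path.read_text())
        except json.JSONDecodeError:
            prev = None
        if prev is not None and prev.get("config_hash") == chash:
            log.info("experiment %s already complete, skipping", config.name)
            return prev
    resolved = config.resolved()
    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=True)
    )
    integ = resolved["integrator"]
    metrics = resolved["metrics"]
    template = config.neuron_params()
    signal = config.signal_params()
    summary: dict = {
        "name": config.name,
        "kind": config.kind,
        "config_hash": chash,
    }
    log.info("running experiment %s (%s)", config.name, config.kind)

    if config.kind == "sweep_d":
        d_values = _linrange(
            config.sweep["d_min"], config.sweep["d_max"], config.sweep["d_step"]
        )
        diagram = sweep_bifurcation(
            template, d_values, signal=signal,
            settle=metrics["settle"], tail_keep=metrics["tail_keep"],
            n_segments=metrics["n_segments"],
            rtol=integ["rtol"], atol=integ["atol"], max_step=integ["max_step"],
            progress=lambda row: log.info(
                "d=%.6g period=%s lambda1=%.5g", row["d"], row["period"], row["lambda1"]
            ),
        )
        diagram.table.to_csv(outdir / "sweep.csv", index=False)
        diagram.tails_to_frame().to_csv(outdir / "section_tails.csv", index=False)
        pts = [p.to_dict() for p in diagram.points]
        (outdir / "bifurcation_points.json").write_text(
            json.dumps(pts, indent=2, default=_json_default)
        )
        summary["bifurcation_points"] = pts
        lam = diagram.table["lambda1"].dropna()
        if len(lam):
            summary["lambda1_range"] = [float(lam.min()), float(lam.max())]

    elif config.kind == "map_cd":
        s = config.sweep
        grid = lyapunov_map(
            template,
            _linrange(s["c_min"], s["c_max"], s["c_step"]),
            _linrange(s["d_min"], s["d_max"], s["d_step"]),
            signal=signal, n_segments=metrics["n_segments"],
            rtol=integ["rtol"], atol=integ["atol"], max_step=integ["max_step"],
        )
        grid.to_csv(outdir / "lambda_map.csv", index=False)
        pos = grid[grid["lambda1"] > 0]
        summary["n_cells"] = int(len(grid))
        summary["n_chaotic_cells"] = int(len(pos))

    elif config.kind == "response_sweep":
        d_values = _linrange(
            config.sweep["d_min"], config.sweep["d_max"], config.sweep["d_step"]
        )
        table = response_sweep(
            template, d_values, signal,
            periods=metrics["periods"], n_lags=metrics["n_lags"],
            n_bins=metrics.get("n_bins"), lyapunov=metrics["lyapunov"],
            n_segments=metrics["n_segments"],
            rtol=integ["rtol"], atol=integ["atol"], max_step=integ["max_step"],
            progress=lambda row: log.info(
                "d=%.6g max_C=%.3f lambda1=%.5g",
                row["d"], row["max_C"], row["lambda1"],
            ),
        )
        table.to_csv(outdir / "response.csv", index=False)
        ok = table.dropna(subset=["max_C"])
        if len(ok):
            i = ok["max_C"].idxmax()
            summary["peak_max_C"] = float(ok.loc[i, "max_C"])
            summary["peak_d"] = float(ok.loc[i, "d"])
        if metrics["lyapunov"] is not None and ok["lambda1"].notna().any():
            binned = lambda_binned_scatter(ok, window=metrics["lambda_window"])
            binned.to_csv(outdir / "lambda_binned.csv", index=False)
            j = binned["mean_max_C"].idxmax()
            summary["peak_lambda1_bin"] = float(binned.loc[j, "lambda1_bin"])
            summary["peak_bin_mean_max_C"] = float(binned.loc[j, "mean_max_C"])

    elif config.kind == "resonance_map":
        rmap = resonance_map(
            template,
            np.asarray(config.sweep["f0_values"], dtype=float),
            np.asarray(config.sweep["A_values"], dtype=float),
            threshold=metrics.get("threshold", 0.5),
            periods=metrics["periods"], n_lags=metrics["n_lags"],
            n_bins=metrics.get("n_bins"),
            rtol=integ["rtol"], atol=integ["atol"], max_step=integ["max_step"],
            progress=lambda A, f0, c: log.info("A=%.4g f0=%.4g max_C=%.3f", A, f0, c),
        )
        rmap.to_frame().to_csv(outdir / "resonance_map.csv", index=False)
        summary["n_resonant_cells"] = int(rmap.resonant_mask.sum())
        summary["n_cells"] = int(rmap.max_C.size)

    elif config.kind == "spectrum":
        spec = spectrum_of_model(
            template, duration=metrics["duration"],
            sample_dt=metrics["sample_dt"], signal=signal,
            rtol=integ["rtol"], atol=integ["atol"],
        )
        spec.to_frame().to_csv(outdir / "spectrum.csv", index=False)
        summary["peak_frequencies"] = [float(f) for f in spec.peak_frequencies]

    summary_path.write_text(json.dumps(summary, indent=2, default=_json_default))
    log.info("experiment %s complete", config.name)
    return summary
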