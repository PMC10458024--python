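"""Experiment orchestration: validated configs, scenario runners, manifests.

A scenario is declared in a single YAML file and produces a directory of
delimited-text artifacts plus ``manifest.yaml`` listing every file with the
hash of the config that made it.  Reruns with the same config reproduce the
numeric outputs byte for byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .coupled import CouplingConfig, HybridState, PulseTrain, open_loop_response, simulate_hybrid
from .metrics import detect_spikes_channel, phase_portrait, sync_metrics
from .model import FHNParams
from .regimes import coupling_sweep, threshold_scan
from .solver import SolverConfig
from .surrogate import LFPGenConfig, NoResponseError, evoked_metrics, generate_lfp, lowpass_filter

__all__ = ["ExperimentConfig", "ConfigError", "run_experiment", "SCENARIOS"]

SCENARIOS = ("open_loop", "closed_loop", "threshold_scan", "coupling_sweep", "surrogate_demo")

_BLOCK_KEYS = {
    "unit1": {"epsilon", "I", "alpha", "beta"},
    "unit2": {"epsilon", "I", "alpha", "beta"},
    "coupling": {"k", "d", "forward_on", "feedback_on"},
    "solver": {"method", "rel_tol", "abs_tol", "max_step", "horizon", "sample_dt"},
    "stim": {"onsets", "width", "amplitude"},
    "scan": {"i_lo", "i_hi", "tol", "unit"},
    "sweep": {"d_values", "d_min", "d_max", "n_points", "calibration_anchor_ms"},
    "detection": {"up_threshold", "down_threshold", "discard_fraction"},
    "surrogate": {
        "spike_amplitude_mv", "spike_width_ms", "noise_sd_mv",
        "artifact_amplitude_mv", "artifact_polarity", "response_delay_ms",
        "response_probability", "sample_rate_khz", "template",
        "duration_ms", "stim_times_ms", "lowpass_cutoff_hz", "window_ms",
    },
}
_TOP_KEYS = {"scenario", "seed", "output_dir", "init"} | set(_BLOCK_KEYS)


class ConfigError(ValueError):
    """A config violated the schema; the message names the offending key."""


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in {where}")


@dataclass
class ExperimentConfig:
    """Validated scenario declaration.  Unknown keys are rejected by name."""

    scenario: str
    seed: int = 0
    output_dir: str = "fhnloop_out"
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        _check_keys(data, _TOP_KEYS, "config root")
        scenario = data.get("scenario")
        if scenario not in SCENARIOS:
            raise ConfigError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
        for block, allowed in _BLOCK_KEYS.items():
            if block in data:
                if not isinstance(data[block], dict):
                    raise ConfigError(f"block {block!r} must be a mapping")
                _check_keys(data[block], allowed, f"block {block!r}")
        return cls(
            scenario=scenario,
            seed=int(data.get("seed", 0)),
            output_dir=str(data.get("output_dir", "fhnloop_out")),
            raw=data,
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # --- typed accessors -------------------------------------------------
    def unit(self, which: int) -> FHNParams:
        defaults = {1: dict(epsilon=0.18, I=0.19), 2: dict(epsilon=0.19, I=0.18)}[which]
        block = {**defaults, **self.raw.get(f"unit{which}", {})}
        return FHNParams(**block)

    def coupling(self) -> CouplingConfig:
        return CouplingConfig(**self.raw.get("coupling", {}))

    def solver(self, **overrides) -> SolverConfig:
        return SolverConfig(**{**self.raw.get("solver", {}), **overrides})

    def detection(self) -> dict:
        return {
            "up_threshold": 1.0, "down_threshold": 0.0, "discard_fraction": 0.3,
            **self.raw.get("detection", {}),
        }

    def stim(self) -> PulseTrain | None:
        block = self.raw.get("stim")
        if block is None:
            return None
        return PulseTrain(tuple(block.get("onsets", ())),
                          block.get("width", 1.0), block.get("amplitude", 0.5))

    def init_state(self) -> HybridState | None:
        if "init" not in self.raw:
            return None
        return HybridState(*[float(x) for x in self.raw["init"]])

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _dump_yaml(path: Path, payload: dict) -> None:
    path.write_text(yaml.safe_dump(fio._pyify(payload), sort_keys=True))


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Run one scenario end to end; returns the manifest as a dict.

    Writes every artifact under ``out_dir`` (default: config.output_dir)
    and a ``manifest.yaml`` listing the files with the config hash.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = {
        "closed_loop": _run_closed_loop,
        "open_loop": _run_open_loop,
        "threshold_scan": _run_threshold_scan,
        "coupling_sweep": _run_coupling_sweep,
        "surrogate_demo": _run_surrogate_demo,
    }[config.scenario]
    files = runner(config, out)
    manifest = {
        "scenario": config.scenario,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "files": sorted(str(Path(f).name) for f in files),
    }
    _dump_yaml(out / "manifest.yaml", manifest)
    return manifest


def _run_closed_loop(cfg: ExperimentConfig, out: Path) -> list:
    traj = simulate_hybrid(cfg.unit(1), cfg.unit(2), cfg.coupling(),
                           init=cfg.init_state(), cfg=cfg.solver())
    det = cfg.detection()
    sm = sync_metrics(traj, det["up_threshold"], det["down_threshold"],
                      det["discard_fraction"])
    portrait = phase_portrait(traj, 0, 2, det["discard_fraction"])
    files = [fio.save_trajectory(traj, out / "trajectory.tsv")]
    np.savetxt(out / "phase_portrait.tsv", portrait, fmt="%.12g",
               delimiter="\t", header="u1\tu2", comments="")
    files.append(out / "phase_portrait.tsv")
    summary = out / "sync_metrics.yaml"
    _dump_yaml(summary, {
        "freq1": sm.freq1, "freq2": sm.freq2, "freq_ratio": sm.freq_ratio,
        "plv": sm.plv, "lag": sm.lag,
    })
    files.append(summary)
    return files


def _run_open_loop(cfg: ExperimentConfig, out: Path) -> list:
    det = cfg.detection()
    traj = open_loop_response(cfg.unit(1), cfg.unit(2), cfg.coupling(),
                              cfg.stim(), cfg=cfg.solver(), init=cfg.init_state())
    files = [fio.save_trajectory(traj, out / "trajectory.tsv")]
    train = detect_spikes_channel(traj, 2, det["up_threshold"], det["down_threshold"])
    stim = cfg.stim()
    delays = []
    if stim is not None:
        for onset in stim.onsets:
            later = train.spike_times[train.spike_times > onset]
            if later.size:
                delays.append(float(later[0] - onset))
    summary = out / "response.yaml"
    _dump_yaml(summary, {
        "n_spikes_channel2": len(train),
        "spike_times": train.spike_times,
        "stimulus_onsets": list(stim.onsets) if stim else [],
        "delays": delays,
    })
    files.append(summary)
    return files


def _run_threshold_scan(cfg: ExperimentConfig, out: Path) -> list:
    block = cfg.raw.get("scan", {})
    which = int(block.get("unit", 1))
    res = threshold_scan(cfg.unit(which), block.get("i_lo", 0.12),
                         block.get("i_hi", 0.35), block.get("tol", 1e-4),
                         cfg.solver())
    summary = out / "threshold.yaml"
    _dump_yaml(summary, {
        "i_star": res.i_star, "bracket": list(res.bracket),
        "label_lo": res.label_lo, "label_hi": res.label_hi, "unit": which,
    })
    return [summary]


def _run_coupling_sweep(cfg: ExperimentConfig, out: Path) -> list:
    block = cfg.raw.get("sweep", {})
    if "d_values" in block:
        d_values = np.asarray(block["d_values"], dtype=float)
    else:
        d_values = np.linspace(block.get("d_min", 0.05), block.get("d_max", 0.2),
                               int(block.get("n_points", 11)))
    curve = coupling_sweep(
        cfg.unit(1), cfg.unit(2), cfg.coupling(), d_values, cfg.solver(),
        discard_fraction=cfg.detection()["discard_fraction"],
        calibration_anchor_ms=block.get("calibration_anchor_ms", 25.0),
    )
    return [fio.save_frequency_curve(curve, out / "frequency_curve.tsv")]


def _run_surrogate_demo(cfg: ExperimentConfig, out: Path) -> list:
    block = dict(cfg.raw.get("surrogate", {}))
    duration = block.pop("duration_ms", 1000.0)
    stim_times = block.pop("stim_times_ms", None)
    cutoff = block.pop("lowpass_cutoff_hz", None)
    window = block.pop("window_ms", 40.0)
    if "spike_amplitude_mv" in block:
        block["spike_amplitude_mv"] = tuple(block["spike_amplitude_mv"])
    gen = LFPGenConfig(seed=cfg.seed, **block)
    rec = generate_lfp(gen, duration, stim_times)
    files = [fio.save_recording(rec, out / "recording.tsv")]
    if cutoff is not None:
        rec = lowpass_filter(rec, cutoff)
        files.append(fio.save_recording(rec, out / "recording_filtered.tsv"))
    per_stim = []
    for s in rec.stim_times_ms:
        try:
            m = evoked_metrics(rec, float(s), window)
            per_stim.append({
                "stim_ms": float(s), "responded": True,
                "amplitude_mv": m.amplitude_mv, "slope_mv_per_ms": m.slope_mv_per_ms,
                "onset_ms": m.onset_ms, "polarity": m.polarity,
            })
        except NoResponseError:
            per_stim.append({"stim_ms": float(s), "responded": False})
    summary = out / "evoked_metrics.yaml"
    _dump_yaml(summary, {"responses": per_stim})
    files.append(summary)
    return files
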