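"""Configuration loading and run manifests.

A run is described by a single YAML (or JSON) document with three optional
sections — ``design``, ``trial`` and ``scenarios`` — validated strictly:
unknown keys are rejected so that typos fail loudly rather than silently
falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .design import DesignConfig, GSDesign, build_gs_design
from .engine import Scenario, TrialConfig, default_scenarios
from .historical import read_historical_csv
from .mixture import BetaMixture

__all__ = ["RunManifest", "LoadedConfig", "load_config", "write_manifest"]

_DESIGN_KEYS = {
    "alpha",
    "beta_err",
    "margin_m",
    "theta_control",
    "n_analyses",
    "info_fractions",
    "gamma_alpha",
    "gamma_beta",
    "binding",
    "sample_size_rule",
}
_TRIAL_KEYS = {
    "theta_h_hat",
    "delta",
    "margin_m",
    "weight_mode",
    "fixed_weight",
    "weak_prior_kind",
    "ess_weak",
    "borrow_first_stage",
    "map_em",
    "historical_csv",
}
_SCENARIO_KEYS = {
    "id",
    "theta_h",
    "theta_c",
    "theta_t",
    "delta",
    "margin_m",
    "hypothesis",
    "congruent",
}


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    version: str
    created_utc: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class LoadedConfig:
    design_config: DesignConfig
    design: GSDesign
    trial: TrialConfig
    scenarios: list[Scenario]
    raw: dict


def _reject_unknown(section: dict, allowed: set, name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{name}' section: {sorted(unknown)}")


def load_config(path: str | Path) -> LoadedConfig:
    """Load, validate and resolve a YAML/JSON run configuration.

    The ``trial.map_em`` entry may be an inline mixture object or a path to
    a mixture JSON file; ``trial.historical_csv`` is accepted (and checked
    for existence) so a config can carry its provenance, but prior fitting
    itself is a separate step.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _reject_unknown(raw, {"design", "trial", "scenarios"}, "root")

    design_section = dict(raw.get("design") or {})
    _reject_unknown(design_section, _DESIGN_KEYS, "design")
    if "info_fractions" in design_section and design_section["info_fractions"] is not None:
        design_section["info_fractions"] = tuple(design_section["info_fractions"])
    design_cfg = DesignConfig(**design_section)
    design = build_gs_design(design_cfg)

    trial_section = dict(raw.get("trial") or {})
    _reject_unknown(trial_section, _TRIAL_KEYS, "trial")
    csv_path = trial_section.pop("historical_csv", None)
    if csv_path is not None:
        csv_path = (path.parent / csv_path).resolve()
        read_historical_csv(csv_path)  # validates early
    map_em = trial_section.pop("map_em", None)
    if map_em is None:
        raise ValueError("trial section requires 'map_em' (inline mixture or JSON path)")
    if isinstance(map_em, str):
        mixture = BetaMixture.from_json(str((path.parent / map_em).resolve()))
    else:
        mixture = BetaMixture.from_dict(map_em)
    trial_section.setdefault("theta_h_hat", mixture.mean)
    trial_section.setdefault("delta", 0.02)
    trial_section.setdefault("margin_m", design_cfg.margin_m)
    trial = TrialConfig(design=design, map_em=mixture, **trial_section)

    scen_section = raw.get("scenarios")
    if scen_section is None:
        scenarios = default_scenarios(trial.theta_h_hat, trial.delta, trial.margin_m)
    else:
        scenarios = []
        for entry in scen_section:
            _reject_unknown(dict(entry), _SCENARIO_KEYS, "scenarios[]")
            entry = dict(entry)
            entry["id"] = str(entry.get("id", len(scenarios) + 1))
            scenarios.append(Scenario(**entry))
    return LoadedConfig(
        design_config=design_cfg, design=design, trial=trial, scenarios=scenarios, raw=raw
    )


def config_hash(raw: dict) -> str:
    """Stable digest of a resolved configuration mapping."""
    canon = json.dumps(raw, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, raw_config: dict, seed: int) -> RunManifest:
    """Write the run manifest (before any results) and return it."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(raw_config),
        seed=seed,
        version=__version__,
        created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=1)
        fh.write("\n")
    return manifest
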