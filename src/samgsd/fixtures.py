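"""Deterministic fixture bundle: the worked example's printed inputs.

Packages the historical-study table, the published MAP-EM mixture, the
eight-scenario grid and a small synthetic MCMC draw file so that examples,
tests and the command-line tool can run without refitting anything.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .engine import default_scenarios
from .mixture import BetaMixture

__all__ = [
    "HISTORICAL_STUDIES",
    "MAP_EM_MIXTURE",
    "THETA_H_HAT",
    "DELTA",
    "MARGIN_M",
    "generate_fixtures",
]

# four historical control arms of the device worked example: (patients, events)
HISTORICAL_STUDIES: tuple[tuple[int, int], ...] = ((204, 30), (220, 20), (499, 14), (60, 10))

# published EM approximation of the MAP prior for the control rate
MAP_EM_MIXTURE = BetaMixture([(10.59, 54.71), (4.53, 17.92)], [0.58, 0.42])

THETA_H_HAT = 0.179  # design-time point estimate of the historical rate
DELTA = 0.02  # congruence margin
MARGIN_M = 0.04  # noninferiority margin


def generate_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the fixture bundle into ``out_dir``; byte-identical for a
    fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    csv = out / "historical_studies.csv"
    lines = ["study_id,n_patients,n_events"]
    lines += [f"S{i + 1},{n},{y}" for i, (n, y) in enumerate(HISTORICAL_STUDIES)]
    csv.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths["historical_csv"] = csv

    mix_json = out / "map_em_mixture.json"
    MAP_EM_MIXTURE.to_json(mix_json)
    paths["map_em_json"] = mix_json

    scen_csv = out / "scenarios.csv"
    rows = ["id,theta_h,theta_c,theta_t,delta,margin_m,hypothesis,congruent"]
    for s in default_scenarios(THETA_H_HAT, DELTA, MARGIN_M):
        rows.append(
            f"{s.id},{s.theta_h},{s.theta_c:.4f},{s.theta_t:.4f},"
            f"{s.delta},{s.margin_m},{s.hypothesis},{int(s.congruent)}"
        )
    scen_csv.write_text("\n".join(rows) + "\n", encoding="utf-8")
    paths["scenarios_csv"] = scen_csv

    # small synthetic draw file (labelled synthetic: these are NOT the
    # paper's MCMC draws, just samples from the published approximation)
    rng = np.random.default_rng(seed)
    draws = MAP_EM_MIXTURE.rvs(2000, rng)
    draw_file = out / "synthetic_map_draws.csv"
    draw_file.write_text(
        "theta_h\n" + "\n".join(f"{d:.6f}" for d in draws) + "\n", encoding="utf-8"
    )
    paths["synthetic_draws"] = draw_file
    return paths
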