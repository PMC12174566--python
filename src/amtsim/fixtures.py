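"""Materialization of ready-to-run input files.

Writes the meridian registry, the sixteen case-study protocol files, the
Meniere's initial-state file and a pair of synthetic evaluation trajectories
with known component scores, so the command-line workflow can be exercised
end to end without hand-typing any inputs.  Every generated file round-trips
through the package's own parsers.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import organ_registry as reg
from .amt_model import ModelParams, Trajectory, initial_states, simulate
from .explorer import load_fixture_protocols

#: Initial organ states of the Meniere's pattern: liver in excess, spleen
#: and kidney deficient, all other organs balanced.
MENIERE_INITIAL = {"liver": 5.0, "spleen": 1.0, "kidney": 1.0}


def meniere_initial_states() -> dict[str, float]:
    return initial_states(**MENIERE_INITIAL)


def synthetic_half_inside_trajectory(steps: int = 50) -> Trajectory:
    """Synthetic stand-in trajectory (not a simulation): one organ alternates
    between the healthy target and a far-outside value so that exactly half
    of its recorded points fall inside any tight band around the target."""
    rows = []
    for tau in range(steps + 1):
        row = {o: 3.0 for o in reg.ALL_ORGANS}
        if tau >= 1 and tau % 2 == 0:
            row["liver"] = 5.0
        row.update({"qi": 3.0, "blood": 3.0, "fluid": 3.0})
        rows.append(row)
    return Trajectory.from_records(rows)


def make_fixtures(output_dir) -> list[Path]:
    """Write all fixture files into ``output_dir``; returns the paths."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    registry_path = out / "registry.json"
    registry_path.write_text(json.dumps(reg.registry_payload(), indent=1) + "\n")
    written.append(registry_path)

    proto_dir = out / "protocols"
    proto_dir.mkdir(exist_ok=True)
    for group, protocol in load_fixture_protocols().items():
        path = proto_dir / f"{group}.json"
        config = {
            "initial": meniere_initial_states(),
            "acupoints": protocol,
            "steps": 50,
            "mode": "direct",
            "seed": 0,
        }
        path.write_text(json.dumps(config, indent=1) + "\n")
        written.append(path)

    initial_path = out / "initial_menieres.json"
    initial_path.write_text(json.dumps(meniere_initial_states(), indent=1) + "\n")
    written.append(initial_path)

    # synthetic evaluation fixtures with known scores
    eval_dir = out / "evaluation"
    eval_dir.mkdir(exist_ok=True)
    healthy = simulate(initial_states(), {}, 50, ModelParams())
    healthy_path = eval_dir / "constant_healthy.csv"
    healthy.to_csv(healthy_path)
    written.append(healthy_path)

    half = synthetic_half_inside_trajectory(50)
    half_path = eval_dir / "synthetic_half_inside.csv"
    half.to_csv(half_path)
    written.append(half_path)

    return written
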