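"""Configuration, fixtures, and result serialization.

The reference tables shipped here transcribe the benchmark flexion-load
results for the five rod designs (intervertebral sagittal moments in N*m
and per-screw force magnitudes in N, left/right); they serve as inputs to
the metrics module and as ground truth for its summary arithmetic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .geometry import SagittalProfile
from .solver import SolveSettings
from .surgery import SurgicalPlan

log = logging.getLogger(__name__)

SCENARIO_NAMES = ("constant-6.0", "stepped-6.0-5.0", "bezier-6.0-5.5-5.0",
                  "constant-5.5", "bezier-5.5-5.0-4.75")

NA = None

# Intervertebral sagittal moment (N*m) under flexion, per junction.
REFERENCE_MOMENTS = {
    "T1-T2":  (8.7, 8.4, 8.1, 7.9, 7.1),
    "T2-T3":  (8.7, 8.5, 8.1, 7.9, 7.2),
    "T3-T4":  (8.8, 8.5, 8.2, 8.0, 7.2),
    "T4-T5":  (8.9, 8.6, 8.3, 8.1, 7.3),
    "T5-T6":  (9.0, 8.7, 8.4, 8.1, 7.4),
    "T6-T7":  (9.0, 8.7, 8.4, 8.2, 7.5),
    "T7-T8":  (9.0, 8.7, 8.4, 8.2, 7.5),
    "T8-T9":  (9.0, 8.7, 8.4, 8.2, 7.5),
    "T9-T10": (9.0, 8.7, 8.4, 8.2, 7.5),   # UIV+1
    "T10-T11": (4.5, 6.5, 6.6, 5.5, 5.5),  # UIV
    "T11-T12": (4.3, 3.4, 2.5, 4.4, 1.6),
    "T12-L1": (5.4, 5.8, 4.0, 4.3, 3.0),
    "L1-L2":  (2.5, 2.1, 2.3, 2.1, 1.9),
    "L2-L3":  (NA, NA, NA, NA, NA),        # across the osteotomy
    "L3-L4":  (NA, NA, NA, NA, NA),
    "L4-L5":  (2.6, 2.6, 2.1, 3.0, 2.4),
    "L5-S1":  (10.9, 10.7, 10.7, 10.3, 9.5),
}

# Screw force magnitudes (N) under flexion: (left, right) per scenario.
REFERENCE_SCREW_FORCES = {
    "T10": ((359, 628), (292, 485), (278, 446), (232, 430), (211, 330)),
    "T11": ((145, 233), (152, 167), (131, 151), (231, 214), (162, 190)),
    "T12": ((206, 574), (220, 613), (208, 620), (442, 522), (193, 530)),
    "L1":  ((183, 180), (423, 251), (193, 232), (109, 145), (180, 243)),
    "L2":  ((238, 120), (340, 213), (216, 147), (203, 93), (206, 156)),
    "L3":  ((NA, NA),) * 5,                # PSO level: no screws
    "L4":  ((181, 148), (170, 145), (156, 221), (151, 114), (160, 131)),
    "L5":  ((1354, 965), (1283, 930), (1202, 1084), (1112, 772), (1061, 763)),
    "S1":  ((1111, 918), (1053, 890), (1004, 964), (918, 752), (867, 719)),
}

DEFAULT_CASE_YAML = """\
# Default study case: severe sagittal imbalance from thoracolumbar kyphosis.
# PI is set to 60 deg for consistency with the pre-operative PI-LL mismatch
# of 72 deg (with LL = -12 deg).
patient:
  PI: 60.0
  PT: 49.0
  TK: 50.0
  LL: -12.0
  lumbar_cobb_coronal: 2.5
  body_mass: 60.0
plan:
  pso_level: L3
  ll_target: 48.0
  facetectomy_factor: 0.5
  max_pso_wedge: 35.0
  flexion_deg: 10.0
solver:
  load_steps: 10
  tolerance: 1.0e-6
  max_iterations: 50
scenarios: all
seed: 0
"""


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    profile: SagittalProfile
    plan: SurgicalPlan
    settings: SolveSettings
    scenarios: tuple[str, ...] = SCENARIO_NAMES
    seed: int = 0
    outdir: str = "results"

    def echo(self) -> dict:
        return {
            "patient": {"PI": self.profile.PI, "PT": self.profile.PT,
                        "SS": self.profile.SS, "TK": self.profile.TK,
                        "LL": self.profile.LL,
                        "body_mass": self.profile.body_mass},
            "plan": {"pso_level": self.plan.pso_level,
                     "ll_target": self.plan.ll_target,
                     "pso_wedge": self.plan.pso_wedge,
                     "facetectomy_factor": self.plan.facetectomy_factor,
                     "flexion_deg": self.plan.flexion_deg},
            "solver": {"load_steps": self.settings.load_steps,
                       "tolerance": self.settings.tolerance,
                       "max_iterations": self.settings.max_iterations},
            "scenarios": list(self.scenarios), "seed": self.seed,
        }


_PATIENT_KEYS = {"PI", "PT", "SS", "TK", "LL", "lumbar_cobb_coronal",
                 "body_mass"}
_PLAN_KEYS = {"instrumented", "pso_level", "pso_wedge", "max_pso_wedge",
              "facetectomy_factor", "ll_target", "flexion_deg"}
_SOLVER_KEYS = {"load_steps", "tolerance", "max_iterations", "line_search"}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Missing sections fall back to the default study case; unknown keys
    are rejected with a message listing the offending entries.
    """
    defaults = yaml.safe_load(DEFAULT_CASE_YAML)
    if path is None:
        raw = {}
    else:
        text = Path(path).read_text()
        raw = (json.loads(text) if str(path).endswith(".json")
               else yaml.safe_load(text)) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    bad_top = set(raw) - {"patient", "plan", "solver", "scenarios", "seed",
                          "outdir"}
    if bad_top:
        raise ConfigError(f"unknown config keys: {sorted(bad_top)}")
    patient = {**defaults["patient"], **(raw.get("patient") or {})}
    plan = {**defaults["plan"], **(raw.get("plan") or {})}
    solver = {**defaults["solver"], **(raw.get("solver") or {})}
    for name, d, allowed in (("patient", patient, _PATIENT_KEYS),
                             ("plan", plan, _PLAN_KEYS),
                             ("solver", solver, _SOLVER_KEYS)):
        bad = set(d) - allowed
        if bad:
            raise ConfigError(f"unknown {name} keys: {sorted(bad)}")
    try:
        profile = SagittalProfile(**patient)
        if "instrumented" in plan:
            plan["instrumented"] = tuple(plan["instrumented"])
        splan = SurgicalPlan(**plan)
        settings = SolveSettings(**solver)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    scen = raw.get("scenarios", defaults["scenarios"])
    if scen in ("all", None):
        scen = SCENARIO_NAMES
    elif isinstance(scen, str):
        scen = (scen,)
    else:
        scen = tuple(scen)
    unknown = [s for s in scen if s not in SCENARIO_NAMES]
    if unknown:
        raise ConfigError(f"unknown scenarios {unknown}; "
                          f"valid names: {list(SCENARIO_NAMES)}")
    return RunConfig(profile=profile, plan=splan, settings=settings,
                     scenarios=scen,
                     seed=int(raw.get("seed", defaults["seed"])),
                     outdir=str(raw.get("outdir", "results")))


def reference_moment_table():
    """The shipped flexion moment table as a metrics MomentTable."""
    import pandas as pd
    from .metrics import MomentTable
    df = pd.DataFrame.from_dict(REFERENCE_MOMENTS, orient="index",
                                columns=list(SCENARIO_NAMES), dtype=float)
    return MomentTable(df, uiv="T10")


def reference_screw_table():
    """The shipped screw force table as a metrics ScrewForceTable."""
    import pandas as pd
    from .metrics import ScrewForceTable
    cols = {}
    for k, name in enumerate(SCENARIO_NAMES):
        cols[(name, "left")] = {lv: REFERENCE_SCREW_FORCES[lv][k][0]
                                for lv in REFERENCE_SCREW_FORCES}
        cols[(name, "right")] = {lv: REFERENCE_SCREW_FORCES[lv][k][1]
                                 for lv in REFERENCE_SCREW_FORCES}
    df = pd.DataFrame(cols, dtype=float).loc[list(REFERENCE_SCREW_FORCES)]
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["scenario", "side"])
    return ScrewForceTable(df)


def make_fixtures(outdir: str | Path) -> list[Path]:
    """Write the reference tables and default case config to ``outdir``.

    Re-running produces byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    p = out / "reference_moments.csv"
    reference_moment_table().to_csv(p)
    paths.append(p)
    p = out / "reference_screw_forces.csv"
    reference_screw_table().to_csv(p)
    paths.append(p)
    p = out / "default_case.yaml"
    p.write_text(DEFAULT_CASE_YAML)
    paths.append(p)
    return paths


def save_results(states_by_scenario, outdir: str | Path,
                 config: RunConfig | None = None) -> Path:
    """Write per-scenario stage results (JSON) + tables (CSV) + manifest."""
    from . import __version__
    from .metrics import MomentTable, ScrewForceTable, compare_scenarios
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, states in states_by_scenario.items():
        with open(out / f"{name}.json", "w") as fh:
            json.dump({stg: st.to_dict() for stg, st in states.items()},
                      fh, indent=1)
    MomentTable.from_states(states_by_scenario).to_csv(
        out / "moments_flexion_nm.csv")
    ScrewForceTable.from_states(states_by_scenario).to_csv(
        out / "screw_forces_flexion_n.csv")
    ref = ("constant-6.0" if "constant-6.0" in states_by_scenario
           else next(iter(states_by_scenario)))
    summary = compare_scenarios(states_by_scenario, reference=ref)
    summary.to_csv(out / "comparison_summary.csv")
    manifest = {
        "version": __version__,
        "scenarios": list(states_by_scenario),
        "config": config.echo() if config else None,
        "seed": config.seed if config else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
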