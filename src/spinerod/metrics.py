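"""Outcome metrics: junctional loads, screw forces, ROM, rod stresses.

Works both on simulated stage states and on externally supplied tables
(the shipped reference tables for the five rod designs are fixtures of
the same shape), and renders the cross-scenario comparison used to argue
for a "soft landing" at the proximal junction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import JUNCTIONS
from .surgery import StageState

log = logging.getLogger(__name__)

INSTRUMENTED_JUNCTIONS = ("T10-T11", "T11-T12", "T12-L1", "L1-L2",
                          "L2-L3", "L3-L4", "L4-L5", "L5-S1")
DEFAULT_UIV = "T10"


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (forces print as integers)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percent_reduction(reference: float, value: float) -> float:
    """100 * (reference - value) / reference."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (reference - value) / reference


class MomentTable:
    """Intervertebral sagittal moments (N*m) per junction x scenario."""

    def __init__(self, frame: pd.DataFrame, uiv: str = DEFAULT_UIV):
        order = [j for j in JUNCTIONS if j in frame.index]
        if list(frame.index) != order:
            frame = frame.loc[order]
        self.frame = frame
        self.uiv = uiv
        i = next(k for k, j in enumerate(JUNCTIONS) if j.split("-")[0] == uiv)
        self.uiv_junction = JUNCTIONS[i]
        self.uiv_plus1_junction = JUNCTIONS[i - 1]

    @classmethod
    def from_states(cls, states: Mapping[str, Mapping[str, StageState]],
                    stage: str = "flexed", uiv: str = DEFAULT_UIV
                    ) -> "MomentTable":
        cols = {}
        for name, stg in states.items():
            if stage not in stg:
                raise KeyError(f"scenario {name} is missing stage {stage!r}")
            mom = stg[stage].joint_moment_nm
            cols[name] = {j: abs(mom[j]) for j in JUNCTIONS}
        return cls(pd.DataFrame(cols), uiv=uiv)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        idx = []
        for j in out.index:
            if j == self.uiv_junction:
                idx.append(f"{j} (UIV)")
            elif j == self.uiv_plus1_junction:
                idx.append(f"{j} (UIV+1)")
            else:
                idx.append(j)
        out.index = idx
        out.index.name = "junction"
        out.to_csv(path, na_rep="NA", float_format="%.4g")

    @classmethod
    def from_csv(cls, path) -> "MomentTable":
        df = pd.read_csv(path, index_col="junction", na_values=["NA"])
        uiv = DEFAULT_UIV
        idx = []
        for j in df.index:
            base = j.split(" (")[0]
            if "(UIV)" in j:
                uiv = base.split("-")[0]
            idx.append(base)
        df.index = idx
        df.index.name = None
        return cls(df, uiv=uiv)

    def uiv_plus1_moment(self, scenario: str) -> float:
        v = self.frame.loc[self.uiv_plus1_junction, scenario]
        if pd.isna(v):
            raise ValueError(f"UIV+1 moment is NA for scenario {scenario}")
        return float(v)

    def transition_smoothness(self, scenario: str) -> float:
        """Max |moment jump| between adjacent junctions, UIV+1 .. UIV-2.

        Operationalizes "smoother load transition": the largest step in
        the junction-moment profile across the proximal transition, NA
        rows excluded.  Lower is smoother; a constant profile scores 0.
        """
        i = JUNCTIONS.index(self.uiv_plus1_junction)
        rows = JUNCTIONS[i: i + 4]  # UIV+1, UIV, UIV-1, UIV-2
        vals = [float(self.frame.loc[j, scenario]) for j in rows
                if j in self.frame.index
                and not pd.isna(self.frame.loc[j, scenario])]
        if len(vals) < 2:
            return 0.0
        return float(np.max(np.abs(np.diff(vals))))


class ScrewForceTable:
    """Screw force magnitudes (N) per level x scenario, left/right."""

    def __init__(self, frame: pd.DataFrame):
        # columns: MultiIndex (scenario, side) with side in {left, right}
        self.frame = frame

    @classmethod
    def from_states(cls, states: Mapping[str, Mapping[str, StageState]],
                    stage: str = "flexed") -> "ScrewForceTable":
        cols = {}
        for name, stg in states.items():
            forces = stg[stage].screw_force_n
            levels = [lv for lv in forces if lv != "pelvis"]
            # sagittal symmetry: per-screw force identical left and right
            cols[(name, "left")] = {lv: forces[lv] for lv in levels}
            cols[(name, "right")] = {lv: forces[lv] for lv in levels}
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(df.columns,
                                               names=["scenario", "side"])
        order = [lv for lv in
                 [j.split("-")[0] for j in JUNCTIONS] + ["S1"]
                 if lv in df.index]
        return cls(df.loc[order])

    def to_csv(self, path) -> None:
        flat = self.frame.copy()
        flat.columns = [f"{a}|{b}" for a, b in flat.columns]
        flat.index.name = "level"
        flat.to_csv(path, na_rep="NA")

    @classmethod
    def from_csv(cls, path) -> "ScrewForceTable":
        df = pd.read_csv(path, index_col="level", na_values=["NA"])
        df.index.name = None
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split("|")) for c in df.columns],
            names=["scenario", "side"])
        return cls(df)

    @property
    def scenarios(self) -> list[str]:
        return list(dict.fromkeys(self.frame.columns.get_level_values(0)))

    def mean_construct_force(self, scenario: str) -> int:
        """Mean of all non-NA left+right magnitudes, rounded to integer N."""
        v = self.frame[scenario].to_numpy(dtype=float).ravel()
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise ValueError(f"no screw forces for scenario {scenario}")
        return round_half_away(float(v.mean()))

    def uiv_screw_force(self, scenario: str, uiv: str = DEFAULT_UIV) -> int:
        """Mean of left and right force at the UIV, rounded to integer N."""
        if uiv not in self.frame.index:
            raise ValueError(f"UIV row {uiv} missing")
        row = self.frame.loc[uiv, scenario].to_numpy(dtype=float)
        if np.any(np.isnan(row)):
            raise ValueError(f"NA screw force at UIV for scenario {scenario}")
        return round_half_away(float(row.mean()))


def rom_summary(states: Mapping[str, StageState],
                reference_stage: str = "postop_standing",
                moving_stage: str = "flexed") -> dict[str, float]:
    """Per-junction range of motion (deg) between two solved stages."""
    a = states[reference_stage].joint_rotation_deg
    b = states[moving_stage].joint_rotation_deg
    return {j: abs(b[j] - a[j]) for j in a}


def transition_stress_excess(state_a: StageState, state_b: StageState,
                             junction: str = "T11-T12",
                             span_levels: int = 1) -> float:
    """Max pointwise outer-fiber stress excess of rod A over rod B (MPa)
    within ``span_levels`` instrumented levels of a section-change junction.

    Positive means rod A carries locally higher stress at the same arc
    position under the identical protocol (the step concentration).
    """
    rod_a, rod_b = state_a.rod, state_b.rod
    if rod_a is None or rod_b is None:
        raise ValueError("both states must carry rod results")
    anch = rod_a["anchor_s_mm"]
    upper, lower = junction.split("-")
    if upper not in anch or lower not in anch:
        raise ValueError(f"junction {junction} not bracketed by screws")
    levels = list(anch)  # distal -> proximal screw order
    iu = levels.index(upper)
    lo_idx = max(0, levels.index(lower) - (span_levels - 1))
    hi_idx = min(len(levels) - 1, iu + span_levels)
    lo, hi = sorted((anch[levels[lo_idx]], anch[levels[hi_idx]]))
    sa = np.asarray(rod_a["s_mm"])
    sb = np.asarray(rod_b["s_mm"])
    ga = np.asarray(rod_a["outer_stress_mpa"])
    gb = np.asarray(rod_b["outer_stress_mpa"])
    mask = (sa >= lo) & (sa <= hi)
    excess = [ga[i] - gb[np.argmin(np.abs(sb - sa[i]))]
              for i in np.flatnonzero(mask)]
    return float(np.max(excess))


@dataclass
class ComparisonSummary:
    """Cross-scenario comparison, percent reductions vs a reference rod."""

    reference: str
    table: pd.DataFrame  # one row per scenario

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.6g")

    def to_text(self) -> str:
        lines = [f"Comparison vs reference scenario {self.reference!r}", ""]
        lines.append(self.table.to_string(float_format=lambda x: f"{x:.3g}"))
        return "\n".join(lines)


def compare_scenarios(states: Mapping[str, Mapping[str, StageState]],
                      reference: str = "constant-6.0",
                      uiv: str = DEFAULT_UIV) -> ComparisonSummary:
    """Build the headline comparison from full protocol runs."""
    if reference not in states:
        raise ValueError(f"reference scenario {reference!r} not in results")
    moments = MomentTable.from_states(states, uiv=uiv)
    screws = ScrewForceTable.from_states(states)
    rows = {}
    for name, stg in states.items():
        rom = rom_summary(stg)
        instr = [j for j in INSTRUMENTED_JUNCTIONS if j in rom]
        rod = stg["flexed"].rod
        peak_i = int(np.argmax(rod["outer_stress_mpa"])) if rod else -1
        prof = stg["postop_standing"].profile
        rows[name] = {
            "postop_ll_deg": prof.LL,
            "pi_ll_mismatch_deg": prof.PI - prof.LL,
            "uiv_plus1_moment_nm": moments.uiv_plus1_moment(name),
            "uiv_screw_force_n": screws.uiv_screw_force(name, uiv=uiv),
            "mean_construct_force_n": screws.mean_construct_force(name),
            "max_instrumented_rom_deg": max(rom[j] for j in instr),
            "peak_rod_stress_mpa": (float(rod["outer_stress_mpa"][peak_i])
                                    if rod else np.nan),
            "peak_stress_s_mm": (float(rod["s_mm"][peak_i]) if rod else np.nan),
            "transition_smoothness_nm": moments.transition_smoothness(name),
        }
    df = pd.DataFrame(rows).T
    ref = df.loc[reference]
    df["uiv_plus1_moment_reduction_pct"] = [
        percent_reduction(ref["uiv_plus1_moment_nm"], v)
        for v in df["uiv_plus1_moment_nm"]]
    df["uiv_screw_force_reduction_pct"] = [
        percent_reduction(ref["uiv_screw_force_n"], v)
        for v in df["uiv_screw_force_n"]]
    df["uiv_plus1_moment_rank"] = (
        df["uiv_plus1_moment_nm"].rank(ascending=False).astype(int))
    return ComparisonSummary(reference=reference, table=df)
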