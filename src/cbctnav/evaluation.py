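"""Targeting-error metrics and study-level statistics.

Per needle, three deviations are computed from the planned entry A,
planned target B and actual tip C (the planned and actual entry points
are treated as identical, which holds at the control-scan resolution):

* angular deviation D — the angle between the planned trajectory AB and
  the actual needle AC;
* absolute deviation |BC| — distance from planned target to actual tip;
* longitudinal deviation |CC'| — with C' the point at planned depth
  |AB| along the *actual* trajectory, so this isolates the manual
  insertion-depth error.

Study-level summaries mirror the in-plane / out-of-plane / overall
layout, with a single-factor ANOVA between the two trajectory groups
computed from first principles (sums of squares).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .phantom import NeedleOutcome

__all__ = [
    "DeviationMetrics",
    "GroupSummary",
    "AnovaResult",
    "targeting_errors",
    "summarize_group",
    "one_way_anova",
    "study_summary",
    "StudyReport",
    "format_report_table",
]

METRIC_NAMES = ("angular_deg", "absolute_mm", "longitudinal_mm",
                "iterations", "procedural_time_s")


@dataclass(frozen=True)
class DeviationMetrics:
    """The per-needle error triple (degrees / mm / mm)."""

    angular_deg: float
    absolute_mm: float
    longitudinal_mm: float


@dataclass(frozen=True)
class GroupSummary:
    """Sample statistics of one quantity in one trajectory group."""

    n: int
    mean: float
    std: float  # sample standard deviation (n - 1 denominator)
    min: float
    max: float
    degenerate: bool = False  # single-sample group: std reported as 0


@dataclass(frozen=True)
class AnovaResult:
    """Single-factor ANOVA between trajectory groups."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float


def targeting_errors(A: np.ndarray, B: np.ndarray, C: np.ndarray) -> DeviationMetrics:
    """Compute the error triple for one needle placement.

    C' is defined as ``A + |AB| * (C - A)/|C - A|``: the point the tip
    would have reached at the planned depth along the trajectory it
    actually took.  Hence ``|CC'| = | |CA| - |AB| |``.

    Raises
    ------
    ValueError
        If C coincides with A (the actual trajectory, and with it the
        angle, is undefined) or A coincides with B.
    """
    A = np.asarray(A, float).reshape(3)
    B = np.asarray(B, float).reshape(3)
    C = np.asarray(C, float).reshape(3)
    ab = B - A
    ac = C - A
    nab = np.linalg.norm(ab)
    nac = np.linalg.norm(ac)
    if nab <= 0:
        raise ValueError("entry A and target B coincide: no planned trajectory")
    if nac <= 0:
        raise ValueError("tip C coincides with entry A: angle undefined")
    cosang = np.clip(np.dot(ab, ac) / (nab * nac), -1.0, 1.0)
    return DeviationMetrics(
        angular_deg=float(np.degrees(np.arccos(cosang))),
        absolute_mm=float(np.linalg.norm(C - B)),
        longitudinal_mm=float(abs(nac - nab)),
    )


def summarize_group(values: Sequence[float]) -> GroupSummary:
    """Mean / sample STD / min / max of a group of measurements.

    A single-value group cannot support an (n-1)-denominator standard
    deviation; it is reported as 0 with the ``degenerate`` flag set.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    degenerate = v.size == 1
    return GroupSummary(
        n=int(v.size),
        mean=float(v.mean()),
        std=0.0 if degenerate else float(v.std(ddof=1)),
        min=float(v.min()),
        max=float(v.max()),
        degenerate=degenerate,
    )


def one_way_anova(group_a: Sequence[float], group_b: Sequence[float]) -> AnovaResult:
    """Single-factor ANOVA for two groups, from sums of squares.

    F = (SSB / df_between) / (SSW / df_within); the p-value is the upper
    tail of the F distribution.  With zero within-group variance and
    unequal means the statistic is reported as infinite (p = 0); with
    identical constant groups F = 0 and p = 1.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    n = a.size + b.size
    grand = (a.sum() + b.sum()) / n
    ssb = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ssw = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    df_between, df_within = 1, n - 2
    if ssw <= 0.0:
        if ssb <= 1e-300:
            return AnovaResult(0.0, df_between, df_within, 1.0)
        return AnovaResult(math.inf, df_between, df_within, 0.0)
    f = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, p)


@dataclass(frozen=True)
class StudyReport:
    """Table-style study summary: groups × quantities, plus tests.

    ``summaries[group][metric]`` with groups ``overall`` / ``in_plane``
    / ``out_of_plane`` and the five quantities: angular deviation [°],
    absolute deviation [mm], longitudinal deviation [mm], iterations and
    procedural time [s].  ``anova_p[metric]`` compares the two groups.
    """

    n_total: int
    n_in_plane: int
    n_out_of_plane: int
    summaries: dict[str, dict[str, GroupSummary]]
    anova_p: dict[str, float]
    technical_success_rate: float
    per_needle: tuple[DeviationMetrics, ...]


def study_summary(
    outcomes: Sequence[NeedleOutcome],
    lesion_radius_mm: float = 5.0,
) -> StudyReport:
    """Summarise simulated needle outcomes the way the study tabulates them.

    Technical success counts a needle whose tip lies inside the target
    lesion sphere (``|C - B| <= lesion_radius_mm``); the radius is a
    parameter because the phantom's lesion sizes are not published.
    """
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    metrics = [targeting_errors(o.entry_A, o.target_B, o.tip_C) for o in outcomes]
    values = {
        "angular_deg": np.array([m.angular_deg for m in metrics]),
        "absolute_mm": np.array([m.absolute_mm for m in metrics]),
        "longitudinal_mm": np.array([m.longitudinal_mm for m in metrics]),
        "iterations": np.array([o.iterations for o in outcomes], float),
        "procedural_time_s": np.array([o.procedural_time for o in outcomes]),
    }
    in_mask = np.array([o.group_label == "in_plane" for o in outcomes])

    summaries: dict[str, dict[str, GroupSummary]] = {}
    for group, mask in (("overall", np.ones(len(outcomes), bool)),
                        ("in_plane", in_mask), ("out_of_plane", ~in_mask)):
        if mask.any():
            summaries[group] = {k: summarize_group(v[mask]) for k, v in values.items()}

    anova_p: dict[str, float] = {}
    if in_mask.sum() >= 2 and (~in_mask).sum() >= 2:
        for k, v in values.items():
            anova_p[k] = one_way_anova(v[in_mask], v[~in_mask]).p_value

    hits = values["absolute_mm"] <= lesion_radius_mm
    return StudyReport(
        n_total=len(outcomes),
        n_in_plane=int(in_mask.sum()),
        n_out_of_plane=int((~in_mask).sum()),
        summaries=summaries,
        anova_p=anova_p,
        technical_success_rate=float(hits.mean()),
        per_needle=tuple(metrics),
    )


_COLUMNS = [
    ("angular_deg", "Angular dev [deg]"),
    ("absolute_mm", "Absolute dev [mm]"),
    ("longitudinal_mm", "Longitudinal dev [mm]"),
    ("iterations", "Iterations"),
    ("procedural_time_s", "Time [s]"),
]


def format_report_table(report: StudyReport) -> str:
    """Render the study report as an aligned text table."""
    rows = [g for g in ("overall", "in_plane", "out_of_plane") if g in report.summaries]
    header = f"{'group':<14}" + "".join(f"{title:>24}" for _, title in _COLUMNS)
    lines = [header, "-" * len(header)]
    for g in rows:
        cells = []
        for key, _ in _COLUMNS:
            s = report.summaries[g][key]
            cells.append(f"{s.mean:8.2f} ± {s.std:6.2f}".rjust(24))
        lines.append(f"{g:<14}" + "".join(cells))
    if report.anova_p:
        pcells = [f"p={report.anova_p[key]:.4f}".rjust(24) for key, _ in _COLUMNS]
        lines.append(f"{'anova in/out':<14}" + "".join(pcells))
    lines.append(f"technical success rate: {100.0 * report.technical_success_rate:.1f}%"
                 f"  (n = {report.n_total})")
    return "\n".join(lines)
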