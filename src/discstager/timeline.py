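"""Relative developmental time, milestone alignment and Sens-vs-Ac tests.

Conditions that differ in rearing temperature or ecdysone timing differ in
the absolute duration of the third instar, so stage-assignment profiles
are compared on *relative developmental time*: hours after the moult to
the third instar divided by the condition's mean pupariation time.  On
that axis, alignment between two conditions at a developmental milestone
(moult, wandering, pupariation) is judged by a two-part criterion: equal
modal disc stage and small total-variation distance between the stage
distributions.

Independently of time, the progression of Senseless relative to Achaete
(two genes of the same proneural cascade) is compared between conditions
with per-Ac-stage Wilcoxon rank-sum tests under Holm's step-down multiple
testing adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .observations import ObservationSet

logger = logging.getLogger(__name__)

MILESTONES = ("moult", "wandering", "pupariation")

#: Largest group size for which the Wilcoxon p-value is computed by exact
#: permutation enumeration rather than the tie-corrected normal approximation.
EXACT_MAX_N = 8

#: Default total-variation threshold for milestone alignment.
DEFAULT_TV_THRESHOLD = 0.25


@dataclass(frozen=True)
class EventTimes:
    """Mean developmental-event times of one condition, in h AL3E."""

    condition: str
    wandering_h: float
    pupariation_h: float
    moult_h: float = 0.0
    wandering_ci: tuple[float, float] | None = None
    pupariation_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.wandering_h < self.pupariation_h:
            raise ValueError(
                f"{self.condition!r}: need 0 <= wandering_h < pupariation_h, "
                f"got {self.wandering_h} / {self.pupariation_h}"
            )


def read_event_times(path: str | Path) -> dict[str, EventTimes]:
    """Read a per-condition event-time CSV keyed by condition name."""
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        def _ci(lo, hi):
            if pd.isna(row.get(lo, float("nan"))) or pd.isna(row.get(hi, float("nan"))):
                return None
            return (float(row[lo]), float(row[hi]))

        et = EventTimes(
            condition=str(row["condition"]),
            wandering_h=float(row["wandering_h"]),
            pupariation_h=float(row["pupariation_h"]),
            wandering_ci=_ci("wandering_ci_lo", "wandering_ci_hi"),
            pupariation_ci=_ci("pupariation_ci_lo", "pupariation_ci_hi"),
        )
        out[et.condition] = et
    return out


def relative_time(
    time_h: float, events: EventTimes, event: str = "none"
) -> float:
    """Map a dissection time to the [0, 1] relative-developmental-time axis.

    Discs labelled ``wandering`` use the condition's mean wandering time;
    ``pupariation`` discs return exactly 1.  Times slightly above
    pupariation are clamped to 1 with a warning.
    """
    if events.pupariation_h <= 0:
        raise ValueError("pupariation_h must be positive")
    if event == "pupariation":
        return 1.0
    if event == "wandering":
        time_h = events.wandering_h
    if time_h < 0:
        raise ValueError(f"negative time {time_h}")
    rel = time_h / events.pupariation_h
    if rel > 1.0:
        logger.warning(
            "%r: time %.3g h exceeds pupariation %.3g h; clamped to 1",
            events.condition, time_h, events.pupariation_h,
        )
        rel = 1.0
    return rel


@dataclass
class ProgressionProfile:
    """Stage-assignment proportions on the relative-time axis.

    ``frame`` has one row per time point, sorted by ``relative_time``, with
    columns ``relative_time``, ``time_h``, ``event``, ``milestone`` (one of
    the milestone names or ``""``) and one proportion column per disc
    stage.
    """

    condition: str
    frame: pd.DataFrame
    stage_columns: list[str]

    def milestone_row(self, milestone: str) -> pd.Series:
        hit = self.frame[self.frame["milestone"] == milestone]
        if hit.empty:
            raise KeyError(
                f"milestone {milestone!r} absent from profile of "
                f"{self.condition!r}"
            )
        return hit.iloc[0]

    def nearest_row(self, rel_time: float) -> pd.Series:
        i = (self.frame["relative_time"] - rel_time).abs().idxmin()
        return self.frame.loc[i]


def progression_profile(assignment, events: EventTimes) -> ProgressionProfile:
    """Place an assignment table on the relative-time axis.

    Milestone rows are flagged: the row at 0 h (or event ``moult``) as
    ``moult``, and wandering/pupariation rows by their event label even
    when the clock time coincides with a numbered time point.
    """
    stage_cols = list(assignment.frame.columns)
    rows = []
    for (time_h, event), props in assignment.frame.iterrows():
        rel = relative_time(time_h, events, event=event)
        if event in ("wandering", "pupariation"):
            milestone = event
        elif event == "moult" or time_h == 0:
            milestone = "moult"
        else:
            milestone = ""
        rows.append(
            {"relative_time": rel, "time_h": time_h, "event": event,
             "milestone": milestone, **props.to_dict()}
        )
    frame = pd.DataFrame(rows).sort_values("relative_time", kind="stable")
    frame = frame.reset_index(drop=True)
    return ProgressionProfile(
        condition=assignment.condition, frame=frame, stage_columns=stage_cols
    )


@dataclass(frozen=True)
class AlignmentVerdict:
    """Outcome of comparing two conditions at one milestone/time point."""

    where: str
    modal_stage_a: str
    modal_stage_b: str
    tv_distance: float
    threshold: float
    aligned: bool


def _modal_stage(row: pd.Series, stage_cols: Sequence[str]) -> str:
    vals = row[list(stage_cols)].astype(float)
    return vals.idxmax()  # first max in column (rank) order -> earliest stage


def total_variation(p: pd.Series, q: pd.Series) -> float:
    """Total-variation distance between two stage distributions."""
    cols = p.index.union(q.index)
    a = p.reindex(cols, fill_value=0.0).astype(float)
    b = q.reindex(cols, fill_value=0.0).astype(float)
    return 0.5 * float((a - b).abs().sum())


def milestone_alignment(
    profile_a: ProgressionProfile,
    profile_b: ProgressionProfile,
    where: str | float,
    threshold: float = DEFAULT_TV_THRESHOLD,
) -> AlignmentVerdict:
    """Judge whether two conditions agree in disc stage at a milestone.

    *where* is a milestone name (``moult``/``wandering``/``pupariation``)
    or a relative time, matched to each profile's nearest row (stage
    distributions are categorical; no interpolation).  The verdict is
    symmetric: aligned iff the modal stages agree and the total-variation
    distance between the stage distributions is at most *threshold*.
    """
    if isinstance(where, str):
        if where not in MILESTONES:
            raise ValueError(f"unknown milestone {where!r}")
        row_a = profile_a.milestone_row(where)
        row_b = profile_b.milestone_row(where)
        tag = where
    else:
        row_a = profile_a.nearest_row(float(where))
        row_b = profile_b.nearest_row(float(where))
        tag = f"rel_time={float(where):.3f}"
    cols_a, cols_b = profile_a.stage_columns, profile_b.stage_columns
    dist_a = row_a[cols_a].astype(float)
    dist_b = row_b[cols_b].astype(float)
    modal_a = _modal_stage(row_a, cols_a)
    modal_b = _modal_stage(row_b, cols_b)
    tv = total_variation(dist_a, dist_b)
    return AlignmentVerdict(
        where=tag,
        modal_stage_a=modal_a,
        modal_stage_b=modal_b,
        tv_distance=tv,
        threshold=threshold,
        aligned=(modal_a == modal_b) and tv <= threshold,
    )


# -- multiple testing -------------------------------------------------------


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in the input order.

    Sort ascending, multiply the i-th smallest (0-based) by ``m - i``,
    enforce monotone non-decreasing along the sorted order, cap at 1.
    """
    p = list(pvalues)
    for x in p:
        if not 0.0 <= x <= 1.0 or math.isnan(x):
            raise ValueError(f"p-value outside [0, 1]: {x}")
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 0.0
    for i, idx in enumerate(order):
        val = min(1.0, (m - i) * p[idx])
        running = max(running, val)
        adj[idx] = running
    return adj


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) statistic and p-value.

    Exact permutation enumeration when both groups have at most
    ``EXACT_MAX_N`` observations (small, heavily tied per-stage samples);
    tie-corrected normal approximation with continuity correction
    otherwise.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # degenerate: every observation tied -> no evidence of a shift
        return float(len(x) * len(y) / 2.0), 1.0
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        method = stats.PermutationMethod(n_resamples=50_000)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _sens_by_ac(obs: ObservationSet) -> dict[int, np.ndarray]:
    """Group Sens stages by Ac stage over co-scored discs."""
    groups: dict[int, list[int]] = {}
    for d in obs.discs:
        if "Ac" in d.scored and "Sens" in d.scored:
            groups.setdefault(d.scored["Ac"], []).append(d.scored["Sens"])
    return {k: np.array(v) for k, v in groups.items()}


def sens_vs_ac_tests(
    obs_a: ObservationSet,
    obs_b: ObservationSet,
    alpha: float = 0.01,
    min_n: int = 2,
) -> pd.DataFrame:
    """Compare Sens progression against Ac stage between two conditions.

    For every Ac stage with at least *min_n* co-scored discs in both sets,
    Sens stages are compared with a two-sided Wilcoxon rank-sum test; raw
    p-values are Holm-adjusted across the Ac stages of this condition
    pair, and a stage is flagged significant when the adjusted p-value is
    below *alpha*.

    Returns a DataFrame with columns ``ac_stage, n_a, n_b, statistic,
    p_raw, p_holm, significant``, one row per tested Ac stage.
    """
    ga, gb = _sens_by_ac(obs_a), _sens_by_ac(obs_b)
    if not ga or not gb:
        raise ValueError("both observation sets need Ac+Sens co-scored discs")
    rows = []
    for ac in sorted(set(ga) & set(gb)):
        x, y = ga[ac], gb[ac]
        if len(x) < min_n or len(y) < min_n:
            logger.info(
                "Ac stage %d skipped: n_a=%d, n_b=%d below %d",
                ac, len(x), len(y), min_n,
            )
            continue
        stat, p = _wilcoxon_rank_sum(x, y)
        rows.append(
            {"ac_stage": ac, "n_a": len(x), "n_b": len(y),
             "statistic": stat, "p_raw": p}
        )
    df = pd.DataFrame(
        rows, columns=["ac_stage", "n_a", "n_b", "statistic", "p_raw"]
    )
    if df.empty:
        df["p_holm"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["p_holm"] = holm_adjust(df["p_raw"].tolist())
    df["significant"] = df["p_holm"] < alpha
    return df
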