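"""Synthetic cohort generator emulating the dissected-disc study design.

Generates per-disc observation tables, event times and the latent ground
truth behind them, so the whole staging pipeline can be exercised and its
inferences checked against a known answer.  A cohort is driven by a latent
patterning-progression curve on relative developmental time: the identity
when tissue and whole-body development advance in lock-step, or a curve
deflected mid-instar (while pinned to the endpoints) when patterning
drifts between milestones but re-converges at the moult and pupariation.
Discs sampled at a time point scatter around the latent value with a
small disc-level jitter and are scored for the scheme's canonical gene
stages at their true disc stage, in groups mirroring the staining design
(Ac and Sens co-scored on one disc, other genes singly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicHermiteSpline

from .observations import DiscObservation, ObservationSet
from .scheme import StagingScheme
from .timeline import EventTimes, relative_time

#: Default staining design: Ac+Sens co-scored, Dac and Wg singly.
DEFAULT_PAIRING: tuple[tuple[str, ...], ...] = (("Ac", "Sens"), ("Dac",), ("Wg",))

#: Observed range of discs per gene per time point in the study.
DEFAULT_N_RANGE = (5, 16)

#: Disc-level jitter (sd) on the latent progression axis.  0.03 of the
#: instar spreads discs over the one-to-two neighbouring stages typically
#: seen within a time point.
DEFAULT_NOISE_SD = 0.03


@dataclass
class CohortParams:
    """Parameters of one synthetic condition.

    ``progression_lag`` is the signed mid-instar deflection of the latent
    progression relative to lock-step development: negative values delay
    patterning mid-instar.  With ``anchor_milestones`` the curve passes
    exactly through 0 at the moult and 1 at pupariation (the milestone
    hypothesis); without, the whole curve is shifted by the lag (clipped
    to [0, 1]), so patterning misses the final stage at pupariation.
    """

    condition: str = "synthetic"
    pupariation_h: float = 49.0
    wandering_h: float = 46.0
    timepoints: Sequence[float] = (0, 5, 10, 15, 20, 25, 30, 35, 40)
    n_range: tuple[int, int] = DEFAULT_N_RANGE
    pairing: Sequence[tuple[str, ...]] = DEFAULT_PAIRING
    anchor_milestones: bool = True
    progression_lag: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD
    #: With anchoring, disc-level jitter attenuates linearly to zero inside
    #: this relative-time distance of the anchored milestones: milestone
    #: anchoring means patterning *converges* there, so anchored cohorts
    #: show no disc scatter at the moult or pupariation themselves.
    anchor_window: float = 0.05
    seed: int = 0
    include_events: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.anchor_window <= 0:
            raise ValueError("anchor_window must be > 0")
        lo, hi = self.n_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid n_range {self.n_range}")
        for t in self.timepoints:
            if not 0 <= t <= self.pupariation_h:
                raise ValueError(
                    f"time point {t} outside [0, {self.pupariation_h}]"
                )

    @property
    def events(self) -> EventTimes:
        return EventTimes(
            condition=self.condition,
            wandering_h=self.wandering_h,
            pupariation_h=self.pupariation_h,
        )


@dataclass
class GroundTruth:
    """Per-time-point latent progression and true disc stage."""

    condition: str
    anchored: bool
    frame: pd.DataFrame  # columns: time_h, event, rel_time, latent, true_stage

    def true_stage(self, time_h: float, event: str = "none") -> str:
        hit = self.frame[
            (self.frame["time_h"] == time_h) & (self.frame["event"] == event)
        ]
        if hit.empty:
            raise KeyError(f"no ground truth at time_h={time_h}, event={event}")
        return hit["true_stage"].iloc[0]


def latent_progression(rel_time: float, params: CohortParams) -> float:
    """Latent patterning progression at a relative time, in [0, 1].

    Anchored: identity plus a piecewise-cubic deflection with knots at
    relative time 0, 0.5 and 1 (zero slope at the knots) peaking at
    ``progression_lag`` mid-instar — monotone for ``|lag| < 1/3``.
    Unanchored: a uniform shift by the lag, clipped to [0, 1].
    """
    if not 0.0 <= rel_time <= 1.0:
        raise ValueError(f"rel_time {rel_time} outside [0, 1]")
    lag = params.progression_lag
    if not params.anchor_milestones:
        return float(np.clip(rel_time + lag, 0.0, 1.0))
    if abs(lag) >= 1.0 / 3.0:
        raise ValueError(
            f"|progression_lag| = {abs(lag):.3f} >= 1/3 breaks monotonicity "
            "of the anchored progression curve"
        )
    if lag == 0.0:
        return float(rel_time)
    bump = CubicHermiteSpline([0.0, 0.5, 1.0], [0.0, lag, 0.0], [0.0, 0.0, 0.0])
    return float(np.clip(rel_time + bump(rel_time), 0.0, 1.0))


def _stage_rel_times(scheme: StagingScheme) -> np.ndarray:
    times = np.array([s.nominal_time_h for s in scheme.stages], dtype=float)
    return times / times[-1]


def nearest_stage(latent: float, scheme: StagingScheme) -> str:
    """The stage whose nominal relative time is nearest to *latent*.

    Ties break to the earlier stage.
    """
    rel = _stage_rel_times(scheme)
    return scheme.stages[int(np.argmin(np.abs(rel - latent)))].label


def emit_disc(
    latent: float,
    scheme: StagingScheme,
    genes: Sequence[str],
    rng: np.random.Generator,
    noise_sd: float = DEFAULT_NOISE_SD,
    disc_id: str = "disc",
    condition: str = "synthetic",
    time_h: float = 0.0,
    event: str = "none",
) -> DiscObservation:
    """Sample one disc around a latent progression value.

    The disc's true stage is the scheme stage nearest (on nominal relative
    time) to ``latent`` plus a Gaussian disc-level jitter; the scored
    genes take the scheme's canonical values at that stage.
    """
    if not 0.0 <= latent <= 1.0:
        raise ValueError(f"latent {latent} outside [0, 1]")
    z = float(np.clip(latent + rng.normal(0.0, noise_sd), 0.0, 1.0))
    label = nearest_stage(z, scheme)
    combo = scheme.stage(label).combo
    return DiscObservation(
        disc_id=disc_id,
        condition=condition,
        time_h=time_h,
        event=event,
        scored={g: combo[g] for g in genes},
    )


def generate_cohort(
    params: CohortParams, scheme: StagingScheme
) -> tuple[ObservationSet, EventTimes, GroundTruth]:
    """Generate a full synthetic condition: observations + events + truth.

    Per time point (the numbered hours plus, when ``include_events`` is
    set, a wandering and a pupariation point), each staining group in
    ``params.pairing`` receives an independently drawn number of discs in
    ``params.n_range``.  Deterministic under ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    events = params.events
    points: list[tuple[float, str]] = [
        (float(t), "moult" if t == 0 else "none") for t in params.timepoints
    ]
    if params.include_events:
        points.append((params.wandering_h, "wandering"))
        points.append((params.pupariation_h, "pupariation"))
    discs: list[DiscObservation] = []
    truth_rows = []
    lo, hi = params.n_range
    for time_h, event in points:
        rel = relative_time(time_h, events, event=event)
        latent = latent_progression(rel, params)
        if params.anchor_milestones:
            # convergence at milestones: jitter dies out at the anchors
            dist = min(rel, 1.0 - rel)
            eff_sd = params.noise_sd * min(1.0, dist / params.anchor_window)
        else:
            eff_sd = params.noise_sd
        truth_rows.append(
            {"time_h": time_h, "event": event, "rel_time": rel,
             "latent": latent, "true_stage": nearest_stage(latent, scheme)}
        )
        for group in params.pairing:
            n = int(rng.integers(lo, hi + 1))
            for i in range(n):
                disc_id = (
                    f"{params.condition}_t{time_h:g}_{event}_"
                    f"{'+'.join(group)}_{i}"
                )
                discs.append(
                    emit_disc(
                        latent, scheme, group, rng,
                        noise_sd=eff_sd,
                        disc_id=disc_id, condition=params.condition,
                        time_h=time_h, event=event,
                    )
                )
    truth = GroundTruth(
        condition=params.condition,
        anchored=params.anchor_milestones,
        frame=pd.DataFrame(
            truth_rows,
            columns=["time_h", "event", "rel_time", "latent", "true_stage"],
        ),
    )
    obs = ObservationSet(
        discs=discs,
        provenance=f"synthetic cohort {params.condition!r}, seed {params.seed}",
    )
    return obs, events, truth
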