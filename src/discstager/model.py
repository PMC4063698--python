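"""Model/Results interface over the staging pipeline.

``DiscStagingModel`` binds an observation set to a staging scheme and a
marker panel; ``fit`` runs the permute-and-classify computation (simulate
fully-stained discs from each time point's per-gene marginals, assign
each to a disc stage with the scheme-trained Naive Bayes classifier) and
returns a ``DiscStagingResults`` carrying the per-time-point stage
assignment probabilities, with ``summary()``, progression profiles,
milestone-alignment verdicts and bubble-plot rendering hanging off it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import simclassify, timeline
from .observations import (
    MarginalTable,
    NoDataError,
    ObservationSet,
    marginal_table,
    read_observations,
)
from .scheme import StagingScheme, load_default_scheme
from .simclassify import (
    DEFAULT_ALPHA,
    DEFAULT_N_SIM,
    AssignmentTable,
    NBCModel,
    SimulatedDiscSet,
)
from .timeline import AlignmentVerdict, EventTimes, ProgressionProfile

logger = logging.getLogger(__name__)

DEFAULT_MARKERS = ("Ac", "Sens", "Dac")


class DiscStagingModel:
    """Stage-assignment model for dissected-disc observation tables.

    Parameters
    ----------
    observations
        Per-disc gene-stage scores, real or synthetic.
    scheme
        Staging scheme; defaults to the packaged 11-stage scheme.
    markers
        Gene panel used for simulation and classification.  The default
        Ac/Sens/Dac panel resolves ten of the eleven stages (F and G
        merge); the full six-gene panel resolves all eleven.
    alpha
        Laplace smoothing weight of the classifier.
    """

    def __init__(
        self,
        observations: ObservationSet,
        scheme: StagingScheme | None = None,
        markers: Iterable[str] = DEFAULT_MARKERS,
        alpha: float = DEFAULT_ALPHA,
    ) -> None:
        self.observations = observations
        self.scheme = scheme if scheme is not None else load_default_scheme()
        self.markers = tuple(markers)
        self.alpha = alpha
        self.nbc: NBCModel = simclassify.train_nbc(
            self.scheme, self.markers, alpha=alpha
        )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        scheme: StagingScheme | None = None,
        markers: Iterable[str] = DEFAULT_MARKERS,
        alpha: float = DEFAULT_ALPHA,
    ) -> "DiscStagingModel":
        """Build from a long-format frame (disc_id, condition, time_h,
        event, gene, stage), the same layout the observation CSV uses."""
        import io

        buf = io.StringIO()
        data.to_csv(buf, index=False)
        buf.seek(0)
        obs = read_observations(buf, provenance="<dataframe>")
        return cls(obs, scheme=scheme, markers=markers, alpha=alpha)

    @classmethod
    def from_csv(
        cls,
        path,
        scheme: StagingScheme | None = None,
        markers: Iterable[str] = DEFAULT_MARKERS,
        alpha: float = DEFAULT_ALPHA,
    ) -> "DiscStagingModel":
        return cls(
            read_observations(path), scheme=scheme, markers=markers, alpha=alpha
        )

    # -- fitting -----------------------------------------------------------

    def marginals(
        self, condition: str, time_h: float, event: str
    ) -> list[MarginalTable]:
        """Per-marker marginal tables at one time point.

        Raises :class:`NoDataError` if any requested marker has no scores
        there; callers decide whether to skip the time point.
        """
        return [
            marginal_table(
                self.observations, condition, g, time_h=time_h, event=event
            )
            for g in self.markers
        ]

    def fit(
        self,
        n_sim: int = DEFAULT_N_SIM,
        seed: int = 0,
        conditions: Sequence[str] | None = None,
    ) -> "DiscStagingResults":
        """Simulate and classify every time point of every condition.

        Time points where some requested marker was never scored are
        skipped with a warning.  Per-time-point RNG streams derive
        deterministically from *seed*, so results do not depend on
        processing order.
        """
        conds = list(conditions) if conditions else self.observations.conditions
        assignments: dict[str, AssignmentTable] = {}
        simsets: dict[str, list[SimulatedDiscSet]] = {}
        for cond in conds:
            sets = []
            for time_h, event in self.observations.timepoints(cond):
                try:
                    margs = self.marginals(cond, time_h, event)
                except NoDataError as err:
                    logger.warning("skipping time point: %s", err)
                    continue
                s = simclassify.simulate_discs(
                    margs,
                    n=n_sim,
                    seed=simclassify.child_seed(seed, cond, time_h, event),
                )
                sets.append(s)
            if not sets:
                raise NoDataError(
                    f"condition {cond!r}: no time point has scores for all "
                    f"markers {self.markers}"
                )
            simsets[cond] = sets
            assignments[cond] = simclassify.assignment_table(self.nbc, sets)
        return DiscStagingResults(
            model=self,
            assignments=assignments,
            simulated=simsets,
            n_sim=n_sim,
            seed=seed,
        )


@dataclass
class DiscStagingResults:
    """Fitted stage-assignment probabilities and derived analyses."""

    model: DiscStagingModel
    assignments: dict[str, AssignmentTable]
    simulated: dict[str, list[SimulatedDiscSet]]
    n_sim: int
    seed: int
    _profiles: dict[str, ProgressionProfile] = field(default_factory=dict)

    @property
    def conditions(self) -> list[str]:
        return list(self.assignments)

    def assignment_frame(self) -> pd.DataFrame:
        """All conditions' stage proportions in long format."""
        return pd.concat(
            [t.to_long() for t in self.assignments.values()], ignore_index=True
        )

    def profile(
        self, condition: str, events: EventTimes
    ) -> ProgressionProfile:
        """Stage-assignment profile on the relative-time axis."""
        prof = timeline.progression_profile(
            self.assignments[condition], events
        )
        self._profiles[condition] = prof
        return prof

    def alignment(
        self,
        condition_a: str,
        condition_b: str,
        where: str | float,
        events: Mapping[str, EventTimes],
        threshold: float = timeline.DEFAULT_TV_THRESHOLD,
    ) -> AlignmentVerdict:
        """Milestone-alignment verdict between two fitted conditions."""
        pa = self.profile(condition_a, events[condition_a])
        pb = self.profile(condition_b, events[condition_b])
        return timeline.milestone_alignment(pa, pb, where, threshold=threshold)

    def summary(self) -> str:
        """Per-condition, per-time-point modal stage table."""
        lines = [
            "Disc stage assignment (Naive Bayes over scheme "
            f"{', '.join(self.model.scheme.labels)})",
            f"markers: {', '.join(self.model.markers)}   "
            f"alpha: {self.model.alpha}   n simulated discs: {self.n_sim}   "
            f"seed: {self.seed}",
            "",
            f"{'condition':<14} {'time_h':>7} {'event':<12} "
            f"{'modal':>5} {'prop':>6}  assigned stages",
        ]
        for cond, table in self.assignments.items():
            for (time_h, event), row in table.frame.iterrows():
                nonzero = row[row > 0].sort_values(ascending=False)
                modal = nonzero.index[0]
                detail = ", ".join(
                    f"{k}:{v:.2f}" for k, v in nonzero.items()
                )
                lines.append(
                    f"{cond:<14} {time_h:>7g} {event:<12} "
                    f"{modal:>5} {nonzero.iloc[0]:>6.2f}  {detail}"
                )
        return "\n".join(lines)

    def plot_bubbles(
        self,
        condition: str,
        events: EventTimes | None = None,
        ax=None,
        color="C0",
        max_area: float = 600.0,
    ):
        """Bubble chart of stage-assignment proportions over time.

        With *events*, the x axis is relative developmental time and
        milestone rows are annotated; otherwise absolute hours are used.
        Bubble area is proportional to the assignment probability.
        """
        from .plotting import bubble_plot

        return bubble_plot(
            self.assignments[condition],
            events=events,
            ax=ax,
            color=color,
            max_area=max_area,
        )
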