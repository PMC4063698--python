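"""Per-disc observation tables and per-gene marginal stage distributions.

A real dissected disc can be stained for at most two gene products (by
default Achaete and Senseless co-scored, every other gene singly), so an
observation table holds one row per (disc, gene) score.  Tallying the
scores of one gene at one condition/time point gives that gene's empirical
marginal stage distribution — the object the permutation simulation
resamples from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .scheme import SCHEME_GENES

logger = logging.getLogger(__name__)

EVENTS = ("none", "moult", "wandering", "pupariation")

#: Observed per-gene disc counts in the study design; counts outside this
#: range are legal but warned about.
TYPICAL_N_RANGE = (5, 16)

OBS_COLUMNS = ["disc_id", "condition", "time_h", "event", "gene", "stage"]


class NoDataError(LookupError):
    """No discs match the requested condition / time point / gene."""


@dataclass(frozen=True)
class DiscObservation:
    """One dissected (or simulated) disc with its scored gene stages."""

    disc_id: str
    condition: str
    time_h: float
    event: str = "none"
    scored: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scored:
            raise ValueError(f"disc {self.disc_id!r}: no scored genes")
        if self.event not in EVENTS:
            raise ValueError(
                f"disc {self.disc_id!r}: unknown event {self.event!r}"
            )
        for g, st in self.scored.items():
            if st < 0:
                raise ValueError(
                    f"disc {self.disc_id!r}: negative stage for {g!r}"
                )


@dataclass
class ObservationSet:
    """A collection of disc observations with unique disc ids."""

    discs: list[DiscObservation]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [d.disc_id for d in self.discs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate disc_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.discs)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.discs:
            seen.setdefault(d.condition)
        return list(seen)

    def timepoints(self, condition: str) -> list[tuple[float, str]]:
        """Ordered (time_h, event) time points present for *condition*.

        Discs carrying a wandering/pupariation event label form their own
        time point keyed by the event, regardless of individual dissection
        time (wandering spans several hours); other discs group by exact
        ``time_h``.
        """
        keys: set[tuple[float, str]] = set()
        for d in self.discs:
            if d.condition != condition:
                continue
            keys.add(_timepoint_key(d))
        return sorted(keys, key=lambda k: (k[0], k[1]))

    def select(
        self,
        condition: str,
        time_h: float | None = None,
        event: str | None = None,
    ) -> list[DiscObservation]:
        """Discs of one condition at one time point.

        Pass ``event`` for milestone time points (wandering/pupariation);
        otherwise discs are matched exactly on ``time_h``.
        """
        out = []
        for d in self.discs:
            if d.condition != condition:
                continue
            if event is not None and event != "none":
                if d.event == event:
                    out.append(d)
            elif d.event in ("none", "moult") and time_h is not None and (
                d.time_h == time_h
            ):
                out.append(d)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"disc_id": d.disc_id, "condition": d.condition,
             "time_h": d.time_h, "event": d.event, "gene": g, "stage": st}
            for d in self.discs
            for g, st in d.scored.items()
        ]
        return pd.DataFrame(rows, columns=OBS_COLUMNS)


def _timepoint_key(d: DiscObservation) -> tuple[float, str]:
    if d.event in ("wandering", "pupariation"):
        return (d.time_h, d.event)
    return (d.time_h, "none" if d.event == "none" else d.event)


@dataclass(frozen=True)
class MarginalTable:
    """Empirical stage distribution of one gene at one condition/time."""

    condition: str
    time_h: float
    event: str
    gene: str
    counts: Mapping[int, int]
    n: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n:
            raise ValueError("counts do not sum to n")
        if self.n < 1:
            raise ValueError("marginal table needs at least one disc")

    @property
    def support(self) -> list[int]:
        return sorted(self.counts)

    def probabilities(self) -> dict[int, float]:
        return {s: c / self.n for s, c in self.counts.items()}


# -- I/O --------------------------------------------------------------------


def read_observations(
    path: str | Path,
    known_genes: Iterable[str] = SCHEME_GENES,
    provenance: str | None = None,
) -> ObservationSet:
    """Read a per-disc observation CSV into a validated ObservationSet.

    The file has columns ``disc_id, condition, time_h, event, gene, stage``,
    one row per scored gene; rows sharing a ``disc_id`` describe co-scored
    genes on the same disc.
    """
    df = pd.read_csv(path)
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    known = set(known_genes)
    bad = set(df["gene"]) - known
    if bad:
        raise ValueError(f"unknown gene(s): {sorted(bad)}")
    if (df["stage"] < 0).any():
        bad_rows = df.index[df["stage"] < 0].tolist()
        raise ValueError(f"negative stage at row(s) {bad_rows}")
    discs = []
    for disc_id, grp in df.groupby("disc_id", sort=False):
        meta = grp.iloc[0]
        genes = grp["gene"].tolist()
        if len(set(genes)) != len(genes):
            raise ValueError(f"disc {disc_id!r}: gene scored twice")
        discs.append(
            DiscObservation(
                disc_id=str(disc_id),
                condition=str(meta["condition"]),
                time_h=float(meta["time_h"]),
                event=str(meta["event"]),
                scored={g: int(s) for g, s in zip(genes, grp["stage"])},
            )
        )
    return ObservationSet(
        discs=discs, provenance=provenance or str(path)
    )


def write_observations(obs: ObservationSet, path: str | Path) -> None:
    obs.to_frame().to_csv(path, index=False)


# -- tallying ---------------------------------------------------------------


def marginal_table(
    obs: ObservationSet,
    condition: str,
    gene: str,
    time_h: float | None = None,
    event: str | None = None,
) -> MarginalTable:
    """Tally one gene's observed stages at one condition/time point.

    Raises
    ------
    NoDataError
        If no disc at that time point was scored for *gene*.  Callers may
        catch this to skip a time point.
    """
    discs = obs.select(condition, time_h=time_h, event=event)
    stages = [d.scored[gene] for d in discs if gene in d.scored]
    if not stages:
        raise NoDataError(
            f"no {gene} scores for condition {condition!r} at "
            f"time_h={time_h!r} event={event!r}"
        )
    counts: dict[int, int] = {}
    for s in stages:
        counts[s] = counts.get(s, 0) + 1
    n = len(stages)
    lo, hi = TYPICAL_N_RANGE
    if not lo <= n <= hi:
        logger.warning(
            "condition %r time_h=%s event=%s gene %s: n=%d outside the "
            "typical %d-%d range", condition, time_h, event, gene, n, lo, hi,
        )
    when = time_h if time_h is not None else float("nan")
    return MarginalTable(
        condition=condition,
        time_h=when,
        event=event or "none",
        gene=gene,
        counts=counts,
        n=n,
    )


def marginals_frame(tables: Iterable[MarginalTable]) -> pd.DataFrame:
    """Long-format export of marginal tables."""
    rows = [
        {"condition": t.condition, "time_h": t.time_h, "event": t.event,
         "gene": t.gene, "stage": s, "count": c, "n": t.n}
        for t in tables
        for s, c in sorted(t.counts.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["condition", "time_h", "event", "gene", "stage", "count", "n"],
    )
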