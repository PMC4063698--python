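"""Permutation simulation of fully-stained discs and Naive Bayes staging.

A real disc is scored for at most two gene products.  To stage a disc "as
if" it had been stained for a whole marker panel, a population of discs is
simulated by drawing each gene's stage independently from that gene's
empirical marginal at the time point (sampling with replacement — the
permutation step), and each simulated disc is then assigned to a disc
stage with a categorical Naive Bayes classifier trained on the staging
scheme itself: one canonical exemplar per stage, uniform stage priors, and
Laplace smoothing over each gene's modelled stage support.

Ambiguity is resolved conservatively: posterior ties (e.g. stages F and G,
which agree on Ac/Sens/Dac) go to the earliest stage, mirroring the
classifier behaviour the scheme was validated with.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .observations import MarginalTable
from .scheme import StagingScheme

#: Posterior probabilities closer than this are treated as tied.
TIE_TOL = 1e-12

#: Number of simulated discs per time point in the study design.
DEFAULT_N_SIM = 1000

DEFAULT_ALPHA = 0.5


def child_seed(master_seed: int, condition: str, time_h: float, event: str) -> int:
    """Deterministic per-(condition, time point) child seed.

    Mixes the master seed with a CRC of the time-point identity so that
    streams are reproducible and independent of the order in which time
    points are processed.
    """
    tag = zlib.crc32(f"{condition}|{time_h!r}|{event}".encode())
    return int(np.random.SeedSequence([master_seed, tag]).generate_state(1)[0] % (2**31))


@dataclass
class SimulatedDiscSet:
    """A simulated population of fully-stained discs at one time point."""

    condition: str
    time_h: float
    event: str
    n: int
    seed: int
    markers: tuple[str, ...]
    #: shape (n, len(markers)) integer gene stages, column order = markers
    stages: np.ndarray

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=int)
        if self.stages.shape != (self.n, len(self.markers)):
            raise ValueError("stage array shape does not match n x markers")

    def combos(self) -> list[dict[str, int]]:
        return [
            dict(zip(self.markers, row)) for row in self.stages.tolist()
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stages, columns=list(self.markers))
        df.insert(0, "event", self.event)
        df.insert(0, "time_h", self.time_h)
        df.insert(0, "condition", self.condition)
        return df


def simulate_discs(
    marginals: Sequence[MarginalTable],
    n: int = DEFAULT_N_SIM,
    seed: int | np.random.Generator = 0,
) -> SimulatedDiscSet:
    """Simulate *n* fully-stained discs from per-gene marginals.

    Each marginal supplies one gene; each simulated disc draws every
    gene's stage independently from that gene's empirical distribution
    (with replacement).  All marginals must refer to the same condition
    and time point.

    Raises
    ------
    ValueError
        If marginals are empty, duplicated per gene, or refer to
        different time points.
    """
    if not marginals:
        raise ValueError("no marginal tables supplied")
    genes = [m.gene for m in marginals]
    if len(set(genes)) != len(genes):
        raise ValueError(f"duplicate marginals for gene(s) in {genes}")
    keys = {(m.condition, m.time_h, m.event) for m in marginals}
    # NaN time_h (event-keyed rows) compares unequal to itself; key on repr
    keys = {(c, repr(t), e) for c, t, e in keys}
    if len(keys) != 1:
        raise ValueError(f"marginals mix time points: {sorted(keys)}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cols = []
    for m in marginals:
        support = np.array(m.support, dtype=int)
        probs = np.array([m.counts[s] for s in m.support], dtype=float)
        probs /= probs.sum()
        cols.append(rng.choice(support, size=n, p=probs))
    first = marginals[0]
    return SimulatedDiscSet(
        condition=first.condition,
        time_h=first.time_h,
        event=first.event,
        n=n,
        seed=seed if isinstance(seed, int) else -1,
        markers=tuple(genes),
        stages=np.column_stack(cols),
    )


# -- classifier -------------------------------------------------------------


@dataclass
class NBCModel:
    """Categorical Naive Bayes over disc stages, trained on the scheme.

    Attributes
    ----------
    scheme
        The staging scheme the classifier was trained on.
    markers
        Genes entering the likelihood.
    prior
        Stage prior, uniform by default; sums to 1.
    conditionals
        For each gene, an (n_stages, support_size) array of
        P(gene stage value | disc stage); rows sum to 1.  The support of
        gene *g* is ``0 .. max stage of g in the scheme``.
    alpha
        Laplace smoothing weight (0 disables smoothing).
    """

    scheme: StagingScheme
    markers: tuple[str, ...]
    prior: np.ndarray
    conditionals: dict[str, np.ndarray]
    alpha: float
    supports: dict[str, int] = field(default_factory=dict)  # support size per gene

    @property
    def labels(self) -> list[str]:
        return self.scheme.labels


def train_nbc(
    scheme: StagingScheme,
    markers: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
) -> NBCModel:
    """Train the classifier from one canonical exemplar per disc stage.

    For disc stage *s* and gene *g* with support size *K*, the conditional
    probability of value *v* is ``(1[v == canonical] + alpha) / (1 + alpha*K)``.
    The prior is uniform over stages.
    """
    markers = tuple(markers)
    if not markers:
        raise ValueError("empty marker set")
    unknown = set(markers) - set(scheme.genes)
    if unknown:
        raise KeyError(f"unknown marker(s): {sorted(unknown)}")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    n_stages = len(scheme)
    prior = np.full(n_stages, 1.0 / n_stages)
    conditionals: dict[str, np.ndarray] = {}
    supports: dict[str, int] = {}
    for g in markers:
        k = len(scheme.gene_support(g))
        supports[g] = k
        table = np.full((n_stages, k), alpha)
        for i, s in enumerate(scheme.stages):
            table[i, s.combo[g]] += 1.0
        table /= table.sum(axis=1, keepdims=True)
        conditionals[g] = table
    return NBCModel(
        scheme=scheme,
        markers=markers,
        prior=prior,
        conditionals=conditionals,
        alpha=alpha,
        supports=supports,
    )


def posterior(model: NBCModel, combo: Mapping[str, int]) -> pd.Series:
    """Posterior stage probabilities for one gene-stage combination.

    Genes in the combo outside ``model.markers`` are rejected; markers
    absent from the combo are simply omitted from the likelihood product.
    A stage value outside a gene's modelled support contributes zero
    likelihood.  If every stage ends with zero likelihood (possible only
    at ``alpha == 0``) the returned series is all zero — the flagged
    "no stage matches" state, which :func:`classify` resolves by Hamming
    distance.
    """
    extra = set(combo) - set(model.markers)
    if extra:
        raise KeyError(f"combo gene(s) not in model markers: {sorted(extra)}")
    like = model.prior.copy()
    for g, v in combo.items():
        table = model.conditionals[g]
        if 0 <= v < table.shape[1]:
            like = like * table[:, v]
        else:
            like = like * 0.0
    total = like.sum()
    if total == 0.0:
        return pd.Series(like, index=model.labels)
    return pd.Series(like / total, index=model.labels)


def _hamming_fallback(model: NBCModel, combo: Mapping[str, int]) -> str:
    """Earliest stage at minimum Hamming distance to the combo."""
    best_label, best_d = None, None
    for s in model.scheme.stages:
        d = sum(1 for g, v in combo.items() if s.combo[g] != v)
        if best_d is None or d < best_d:
            best_label, best_d = s.label, d
    return best_label  # stages iterated in rank order -> earliest tie wins


def classify(model: NBCModel, combo: Mapping[str, int]) -> str:
    """Assign a combo to a disc stage label.

    The assignment is the posterior argmax; posteriors tied within
    ``TIE_TOL`` resolve to the earliest (lowest-rank) stage.  The all-zero
    posterior state (no stage matches any scored gene at ``alpha == 0``)
    falls back to the earliest stage at minimum Hamming distance between
    the combo and the canonical combos.
    """
    post = posterior(model, combo)
    if post.sum() == 0.0:
        return _hamming_fallback(model, combo)
    best = post.max()
    for label, p in post.items():  # index is in rank order
        if best - p <= TIE_TOL:
            return label
    raise AssertionError("unreachable")


def classify_set(model: NBCModel, simset: SimulatedDiscSet) -> pd.Series:
    """Vectorised classification of a simulated disc population.

    Equivalent to calling :func:`classify` per disc; returns one stage
    label per simulated disc.
    """
    extra = set(simset.markers) - set(model.markers)
    if extra:
        raise KeyError(f"simulated gene(s) not in model markers: {sorted(extra)}")
    n = simset.n
    n_stages = len(model.scheme)
    like = np.tile(model.prior, (n, 1))  # (n, n_stages)
    for j, g in enumerate(simset.markers):
        table = model.conditionals[g]  # (n_stages, K)
        vals = simset.stages[:, j]
        inside = (vals >= 0) & (vals < table.shape[1])
        contrib = np.zeros((n, n_stages))
        contrib[inside] = table[:, vals[inside]].T
        like *= contrib
    totals = like.sum(axis=1)
    labels = np.array(model.labels)
    out = np.empty(n, dtype=object)
    ok = totals > 0.0
    if ok.any():
        post = like[ok] / totals[ok, None]
        best = post.max(axis=1, keepdims=True)
        # earliest stage within TIE_TOL of the max
        idx = (best - post <= TIE_TOL).argmax(axis=1)
        out[ok] = labels[idx]
    if (~ok).any():
        for i in np.nonzero(~ok)[0]:
            out[i] = _hamming_fallback(
                model, dict(zip(simset.markers, simset.stages[i]))
            )
    return pd.Series(out, name="stage")


# -- assignment tables ------------------------------------------------------


@dataclass
class AssignmentTable:
    """Per-time-point proportions of simulated discs per assigned stage.

    ``frame`` is indexed by (time_h, event) rows in time order with one
    column per disc-stage label; each row sums to 1.  This is the data
    behind the stage-assignment bubble plots.
    """

    condition: str
    frame: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        long = (
            self.frame.stack()
            .rename("proportion")
            .reset_index()
        )
        long.insert(0, "condition", self.condition)
        return long


def assignment_table(
    model: NBCModel, simsets: Sequence[SimulatedDiscSet]
) -> AssignmentTable:
    """Classify simulated populations and tabulate stage proportions."""
    if not simsets:
        raise ValueError("no simulated disc sets supplied")
    conditions = {s.condition for s in simsets}
    if len(conditions) != 1:
        raise ValueError(f"simsets mix conditions: {sorted(conditions)}")
    rows = {}
    for s in simsets:
        if s.n == 0:
            raise ValueError("empty simulated disc set")
        assigned = classify_set(model, s)
        props = assigned.value_counts(normalize=True)
        rows[(s.time_h, s.event)] = [
            props.get(label, 0.0) for label in model.labels
        ]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=model.labels)
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["time_h", "event"])
    frame = frame.sort_index(level="time_h")
    return AssignmentTable(condition=conditions.pop(), frame=frame)
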