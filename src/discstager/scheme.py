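"""Wing-disc staging scheme as a combinatorial object.

A staging scheme assigns, to each of an ordered series of disc stages
(``A`` .. ``K`` for the third larval instar of *Drosophila*), one integer
*gene-specific stage* per patterning gene product.  Stage ``0`` means the
gene is not yet expressed, so every gene has a defined value at every disc
stage.  The combination of gene-specific stages across genes is what makes
a disc stage recognisable; restricting attention to a subset of markers may
merge stages that differ only in the unscored genes.

The packaged default scheme (``data/scheme_synthetic.tsv``) is a synthetic
reconstruction of the published wing-disc scheme: its cell values are
chosen to satisfy every structural property stated in the accompanying
text (eleven mutually distinct stages, nine resolvable from Ac+Sens alone,
stages F and G identical on Ac/Sens/Dac, Ac/Sens/Dac unexpressed at the
moult) rather than read off the original figure panels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: The six gene products of the full wing-disc scheme.
SCHEME_GENES: tuple[str, ...] = ("Ac", "Sens", "Dac", "Ct", "N", "Wg")

#: Disc-stage labels in developmental order.
STAGE_LABELS: tuple[str, ...] = tuple("ABCDEFGHIJK")


class SchemeValidationError(ValueError):
    """A staging-scheme file or object violates a structural invariant.

    The message names the offending row (stage label) and/or column (gene)
    so a transcription error can be located in the source table.
    """


@dataclass(frozen=True)
class DiscStage:
    """One row of the scheme: a named disc stage and its gene-stage combo."""

    label: str
    rank: int
    nominal_time_h: float
    combo: Mapping[str, int]

    def restricted(self, markers: Iterable[str]) -> tuple[tuple[str, int], ...]:
        """The combo restricted to *markers*, in canonical gene order."""
        return tuple((g, self.combo[g]) for g in sorted(markers))


@dataclass
class StagingScheme:
    """An ordered staging scheme: disc stages x genes -> integer stage.

    Parameters
    ----------
    stages
        Disc stages in developmental order (rank 0, 1, ...).
    genes
        Gene products covered by the scheme, in column order.
    """

    stages: Sequence[DiscStage]
    genes: Sequence[str] = field(default_factory=lambda: list(SCHEME_GENES))
    #: Set False to hold a known-invalid scheme (e.g. to inspect it with
    #: :func:`validate_scheme`); loaders always validate.
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.validate:
            return
        violations = validate_scheme(self)
        if violations:
            raise SchemeValidationError("; ".join(violations))

    # -- lookups -----------------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.stages]

    def stage(self, label: str) -> DiscStage:
        for s in self.stages:
            if s.label == label:
                return s
        raise KeyError(f"unknown stage label {label!r}")

    def gene_support(self, gene: str) -> range:
        """All integer stage values modelled for *gene*: 0 .. max in scheme."""
        if gene not in self.genes:
            raise KeyError(f"unknown gene {gene!r}")
        return range(0, max(s.combo[gene] for s in self.stages) + 1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage_label": s.label, "nominal_time_h": s.nominal_time_h,
             **{g: s.combo[g] for g in self.genes}}
            for s in self.stages
        ]
        return pd.DataFrame(rows)

    def __len__(self) -> int:
        return len(self.stages)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StagingScheme):
            return NotImplemented
        return list(self.genes) == list(other.genes) and self.to_frame().equals(
            other.to_frame()
        )


# -- validation ------------------------------------------------------------


def _check_rows(df: pd.DataFrame) -> None:
    """Raise SchemeValidationError for malformed scheme tables."""
    required = {"stage_label", "nominal_time_h"}
    missing = required - set(df.columns)
    if missing:
        raise SchemeValidationError(f"missing column(s): {sorted(missing)}")
    genes = [c for c in df.columns if c not in required]
    if not genes:
        raise SchemeValidationError("no gene columns found")
    dup = df["stage_label"][df["stage_label"].duplicated()]
    if not dup.empty:
        raise SchemeValidationError(
            f"duplicate stage label(s): {sorted(dup.unique())}"
        )
    for g in genes:
        for label, value in zip(df["stage_label"], df[g]):
            if pd.isna(value) or float(value) != int(value):
                raise SchemeValidationError(
                    f"non-integer gene stage at row {label!r}, column {g!r}: "
                    f"{value!r}"
                )
            if int(value) < 0:
                raise SchemeValidationError(
                    f"negative gene stage at row {label!r}, column {g!r}"
                )


def validate_scheme(scheme: StagingScheme) -> list[str]:
    """Check the structural invariants of a scheme; return violations.

    An empty list means the scheme is valid.  Each violation names the
    invariant and the offending stage and/or gene.  Nothing is raised.
    """
    out: list[str] = []
    labels = [s.label for s in scheme.stages]
    if len(set(labels)) != len(labels):
        out.append(f"duplicate stage labels: {labels}")
    times = [s.nominal_time_h for s in scheme.stages]
    for a, b in zip(scheme.stages, scheme.stages[1:]):
        if b.nominal_time_h <= a.nominal_time_h:
            out.append(
                f"nominal_time_h not increasing between stages "
                f"{a.label!r} and {b.label!r}"
            )
    for s in scheme.stages:
        for g in scheme.genes:
            if g not in s.combo:
                out.append(f"stage {s.label!r} missing gene {g!r}")
            elif s.combo[g] < 0:
                out.append(f"negative stage for gene {g!r} at {s.label!r}")
    # patterning only advances: per-gene monotone non-decreasing
    for g in scheme.genes:
        for a, b in zip(scheme.stages, scheme.stages[1:]):
            if g in a.combo and g in b.combo and b.combo[g] < a.combo[g]:
                out.append(
                    f"gene {g!r} stage decreases from {a.label!r} "
                    f"({a.combo[g]}) to {b.label!r} ({b.combo[g]})"
                )
    # full combos pairwise distinct
    seen: dict[tuple, str] = {}
    for s in scheme.stages:
        key = tuple(s.combo.get(g) for g in scheme.genes)
        if key in seen:
            out.append(
                f"stages {seen[key]!r} and {s.label!r} share the full "
                f"gene-stage combination {key}"
            )
        else:
            seen[key] = s.label
    _ = times
    return out


# -- I/O --------------------------------------------------------------------


def load_scheme(path: str | Path) -> StagingScheme:
    """Load a staging scheme from a TSV file.

    The file has columns ``stage_label``, ``nominal_time_h`` and one integer
    column per gene.  Rows are disc stages in developmental order.

    Raises
    ------
    SchemeValidationError
        If the table is malformed or violates a scheme invariant.
    FileNotFoundError
        If *path* does not exist.
    """
    df = pd.read_csv(path, sep="\t")
    _check_rows(df)
    genes = [c for c in df.columns if c not in ("stage_label", "nominal_time_h")]
    stages = [
        DiscStage(
            label=str(row["stage_label"]),
            rank=i,
            nominal_time_h=float(row["nominal_time_h"]),
            combo={g: int(row[g]) for g in genes},
        )
        for i, (_, row) in enumerate(df.iterrows())
    ]
    return StagingScheme(stages=stages, genes=genes)


def write_scheme(scheme: StagingScheme, path: str | Path) -> None:
    """Write a scheme to TSV in the format :func:`load_scheme` reads."""
    scheme.to_frame().to_csv(path, sep="\t", index=False)


def load_default_scheme() -> StagingScheme:
    """The packaged 11-stage x 6-gene wing-disc scheme (synthetic cells)."""
    ref = importlib.resources.files("discstager.data") / "scheme_synthetic.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_scheme(p)


# -- marker-subset queries ---------------------------------------------------


def distinguishability(
    scheme: StagingScheme, markers: Iterable[str]
) -> tuple[list[list[str]], int]:
    """Partition disc stages into classes indistinguishable under *markers*.

    Two stages fall into one class when their gene-stage combos agree on
    every scored marker.  With no markers every stage is in one class; with
    all six genes the packaged scheme resolves all eleven stages.

    Returns
    -------
    (classes, count)
        ``classes`` lists each equivalence class as stage labels in stage
        order, classes ordered by their earliest member; ``count`` is
        ``len(classes)``.
    """
    markers = list(markers)
    unknown = set(markers) - set(scheme.genes)
    if unknown:
        raise KeyError(f"unknown marker(s): {sorted(unknown)}")
    classes: dict[tuple, list[str]] = {}
    for s in scheme.stages:
        classes.setdefault(s.restricted(markers), []).append(s.label)
    ordered = sorted(classes.values(), key=lambda c: scheme.stage(c[0]).rank)
    return ordered, len(ordered)


def canonical_combo(
    scheme: StagingScheme, stage_label: str, markers: Iterable[str]
) -> dict[str, int]:
    """The scheme row for *stage_label* restricted to *markers*."""
    markers = list(markers)
    unknown = set(markers) - set(scheme.genes)
    if unknown:
        raise KeyError(f"unknown marker(s): {sorted(unknown)}")
    s = scheme.stage(stage_label)
    return {g: s.combo[g] for g in markers}
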