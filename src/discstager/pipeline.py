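"""End-to-end pipeline runs driven by a single YAML config.

One config describes every condition (a synthetic cohort spec or an
observation CSV plus event times), the marker panel, simulation size and
master seed; ``run_pipeline`` executes synth/load -> marginals ->
simulate -> classify -> profiles -> milestone alignment -> Sens-vs-Ac
tests and writes every artifact plus a machine-readable manifest carrying
the config hash and seed, so a run can be reproduced and audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import timeline
from .model import DEFAULT_MARKERS, DiscStagingModel
from .observations import ObservationSet, read_observations
from .scheme import StagingScheme, load_default_scheme, load_scheme
from .simclassify import DEFAULT_ALPHA, DEFAULT_N_SIM
from .synthetic import CohortParams, generate_cohort
from .timeline import EventTimes, read_event_times

logger = logging.getLogger(__name__)


@dataclass
class ConditionSpec:
    """One condition: either a synthetic cohort or an observation file."""

    name: str
    synth: dict[str, Any] | None = None
    observations: str | None = None
    events: dict[str, float] | None = None  # wandering_h / pupariation_h

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.observations is None):
            raise ValueError(
                f"condition {self.name!r}: give exactly one of "
                "'synth' or 'observations'"
            )


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    conditions: list[ConditionSpec]
    baseline: str
    scheme: str = "default"
    markers: tuple[str, ...] = DEFAULT_MARKERS
    n_sim: int = DEFAULT_N_SIM
    alpha: float = DEFAULT_ALPHA
    significance: float = 0.01
    tv_threshold: float = timeline.DEFAULT_TV_THRESHOLD
    seed: int = 0
    out_dir: str = "discstager_out"
    event_times_file: str | None = None

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate condition names: {names}")
        if self.baseline not in names:
            raise ValueError(
                f"baseline {self.baseline!r} not among conditions {names}"
            )
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        conds = [
            ConditionSpec(name=name, **spec)
            for name, spec in raw.pop("conditions", {}).items()
        ]
        if "markers" in raw:
            raw["markers"] = tuple(raw["markers"])
        return cls(conditions=conds, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def canonical(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _load_condition(
    spec: ConditionSpec, scheme: StagingScheme, config: RunConfig
) -> tuple[ObservationSet, EventTimes]:
    if spec.synth is not None:
        from .simclassify import child_seed

        kwargs = dict(spec.synth)
        kwargs.setdefault(
            "seed", child_seed(config.seed, spec.name, -1.0, "cohort")
        )
        params = CohortParams(condition=spec.name, **kwargs)
        obs, events, _truth = generate_cohort(params, scheme)
        return obs, events
    obs = read_observations(spec.observations)
    if spec.events is not None:
        events = EventTimes(condition=spec.name, **spec.events)
    elif config.event_times_file is not None:
        events = read_event_times(config.event_times_file)[spec.name]
    else:
        raise ValueError(
            f"condition {spec.name!r}: no event times (give 'events' or "
            "'event_times_file')"
        )
    return obs, events


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute a full run; return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = (
        load_default_scheme()
        if config.scheme == "default"
        else load_scheme(config.scheme)
    )
    artifacts: list[str] = []

    def _write(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts.append(name)
        return path

    all_discs, events_map, per_cond_obs = [], {}, {}
    for spec in config.conditions:
        obs, events = _load_condition(spec, scheme, config)
        per_cond_obs[spec.name] = obs
        events_map[spec.name] = events
        all_discs.extend(obs.discs)
    merged = ObservationSet(discs=all_discs, provenance="pipeline run")
    _write("observations.csv", lambda p: merged.to_frame().to_csv(p, index=False))

    model = DiscStagingModel(
        merged, scheme=scheme, markers=config.markers, alpha=config.alpha
    )
    results = model.fit(n_sim=config.n_sim, seed=config.seed)
    _write(
        "assignments.csv",
        lambda p: results.assignment_frame().to_csv(p, index=False),
    )

    profiles = {
        cond: results.profile(cond, events_map[cond])
        for cond in results.conditions
    }
    for cond, prof in profiles.items():
        safe = cond.replace(">", "_").replace("/", "_")
        _write(
            f"profile_{safe}.csv",
            lambda p, fr=prof.frame: fr.to_csv(p, index=False),
        )

    verdicts = []
    base = config.baseline
    for cond in results.conditions:
        if cond == base:
            continue
        for milestone in timeline.MILESTONES:
            try:
                v = timeline.milestone_alignment(
                    profiles[base], profiles[cond], milestone,
                    threshold=config.tv_threshold,
                )
            except KeyError as err:
                logger.warning("alignment skipped: %s", err)
                continue
            verdicts.append(
                {"baseline": base, "condition": cond,
                 **dataclasses.asdict(v)}
            )
    _write(
        "alignment.json",
        lambda p: p.write_text(json.dumps(verdicts, indent=2)),
    )

    sens_rows = []
    for cond in results.conditions:
        if cond == base:
            continue
        try:
            df = timeline.sens_vs_ac_tests(
                per_cond_obs[base], per_cond_obs[cond],
                alpha=config.significance,
            )
        except ValueError as err:
            logger.warning("Sens-vs-Ac skipped for %r: %s", cond, err)
            continue
        df.insert(0, "condition_pair", f"{base} vs {cond}")
        sens_rows.append(df)
    if sens_rows:
        import pandas as pd

        _write(
            "sens_vs_ac.csv",
            lambda p: pd.concat(sens_rows, ignore_index=True).to_csv(
                p, index=False
            ),
        )

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_sim": config.n_sim,
        "markers": list(config.markers),
        "baseline": config.baseline,
        "conditions": [c.name for c in config.conditions],
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
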