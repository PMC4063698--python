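"""Self-validation experiments for the staging pipeline.

Each function runs a property of the pipeline end to end — scheme
resolution counts, the deterministic F-to-G collapse on the Ac/Sens/Dac
panel, goodness of fit of the permutation simulator, and recovery of a
known milestone-alignment structure from synthetic cohorts — and returns
the measured quantities.  ``scripts/acceptance.py`` reports these numbers;
the test suite asserts them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import simclassify, timeline
from .model import DiscStagingModel
from .observations import MarginalTable, ObservationSet
from .scheme import StagingScheme, canonical_combo, distinguishability
from .simclassify import assignment_table, simulate_discs, train_nbc
from .synthetic import CohortParams, generate_cohort

TRIO = ("Ac", "Sens", "Dac")


def resolution_counts(scheme: StagingScheme) -> dict:
    """Stage-resolution of the marker panels used in practice."""
    _, n_full = distinguishability(scheme, scheme.genes)
    _, n_pair = distinguishability(scheme, ["Ac", "Sens"])
    classes, n_trio = distinguishability(scheme, list(TRIO))
    return {
        "full_panel_classes": n_full,
        "ac_sens_classes": n_pair,
        "trio_classes": n_trio,
        "trio_merged_pairs": [c for c in classes if len(c) > 1],
    }


def fg_collapse_percent(
    scheme: StagingScheme, n: int = 1000, seed: int = 0, alpha: float = 0.5
) -> float:
    """Percent of simulated discs carrying stage G's canonical Ac/Sens/Dac
    combo that the classifier assigns to stage F (ties resolve earliest)."""
    combo = canonical_combo(scheme, "G", TRIO)
    marginals = [
        MarginalTable(
            condition="fg", time_h=30.0, event="none", gene=g,
            counts={v: 10}, n=10,
        )
        for g, v in combo.items()
    ]
    simset = simulate_discs(marginals, n=n, seed=seed)
    model = train_nbc(scheme, TRIO, alpha=alpha)
    table = assignment_table(model, [simset])
    return float(table.frame.iloc[0]["F"] * 100.0)


@dataclass
class FidelityReport:
    chi2_passes: int
    n_seeds: int
    alpha: float
    joint_within_3se: int  # seeds whose joint pair frequency is within 3 SE
    joint_max_dev_se: float  # worst joint-frequency deviation, in binomial SEs

    @property
    def pass_rate_percent(self) -> float:
        return 100.0 * self.chi2_passes / self.n_seeds

    @property
    def joint_pass_rate_percent(self) -> float:
        return 100.0 * self.joint_within_3se / self.n_seeds


def simulator_fidelity(
    n: int = 1000,
    n_seeds: int = 100,
    seed: int = 0,
    alpha: float = 0.001,
) -> FidelityReport:
    """Goodness of fit of the permutation simulator.

    For a representative multi-stage marginal, simulate ``n`` discs under
    ``n_seeds`` independent seeds and chi-square-test the simulated
    frequencies against the input marginal; also check that pairwise joint
    frequencies stay within binomial sampling error of the product of the
    marginals (the simulator draws genes independently).
    """
    counts_ac = {4: 5, 5: 3, 6: 8}
    counts_sens = {2: 4, 3: 6}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_seeds) % (2**31)
    passes = 0
    joint_ok = 0
    worst_dev = 0.0
    support = sorted(counts_ac)
    probs = np.array([counts_ac[s] for s in support], dtype=float)
    probs /= probs.sum()
    p_joint = (counts_ac[4] / 16) * (counts_sens[2] / 10)
    se = np.sqrt(p_joint * (1 - p_joint) / n)
    for s in child_seeds:
        marginals = [
            MarginalTable(condition="c", time_h=20.0, event="none",
                          gene="Ac", counts=counts_ac, n=16),
            MarginalTable(condition="c", time_h=20.0, event="none",
                          gene="Sens", counts=counts_sens, n=10),
        ]
        sim = simulate_discs(marginals, n=n, seed=int(s))
        obs = np.array([(sim.stages[:, 0] == v).sum() for v in support])
        p = stats.chisquare(obs, probs * n).pvalue
        if p > alpha:
            passes += 1
        joint = np.mean((sim.stages[:, 0] == 4) & (sim.stages[:, 1] == 2))
        dev = abs(joint - p_joint) / se
        joint_ok += dev <= 3.0
        worst_dev = max(worst_dev, dev)
    return FidelityReport(
        chi2_passes=passes, n_seeds=n_seeds, alpha=alpha,
        joint_within_3se=joint_ok, joint_max_dev_se=float(worst_dev),
    )


@dataclass
class RecoveryReport:
    n_reps: int
    moult_aligned: int
    pupariation_aligned: int
    interior_misaligned: int
    full_recovery: int  # all three verdicts correct in one replicate

    def rate_percent(self, field: str) -> float:
        return 100.0 * getattr(self, field) / self.n_reps


def milestone_recovery(
    scheme: StagingScheme,
    n_reps: int = 50,
    seed: int = 0,
    lag: float = -0.15,
    anchored: bool = True,
    n_sim: int = 1000,
    tv_threshold: float = timeline.DEFAULT_TV_THRESHOLD,
) -> RecoveryReport:
    """Recover the generator's milestone structure from synthetic cohorts.

    Each replicate draws a baseline cohort (lock-step progression) and a
    slow cohort with mid-instar ``lag``, runs the permute-and-classify
    pipeline on both, and asks whether the milestone-alignment verdicts
    match the generator's truth: aligned at the moult and (when anchored)
    at pupariation, not aligned at the maximally lagged interior point.
    """
    ss = np.random.SeedSequence([seed, 1234])
    rep_seeds = ss.generate_state(3 * n_reps) % (2**31)
    moult = wpp = interior = full = 0
    for r in range(n_reps):
        s_base, s_alt, s_fit = (int(x) for x in rep_seeds[3 * r: 3 * r + 3])
        base = CohortParams(condition="base", seed=s_base)
        alt = CohortParams(
            condition="alt", pupariation_h=60.0, wandering_h=55.0,
            timepoints=(0, 10, 20, 30, 40, 50),
            progression_lag=lag, anchor_milestones=anchored, seed=s_alt,
        )
        obs_b, ev_b, _ = generate_cohort(base, scheme)
        obs_a, ev_a, _ = generate_cohort(alt, scheme)
        merged = ObservationSet(discs=obs_b.discs + obs_a.discs)
        res = DiscStagingModel(merged, scheme=scheme).fit(
            n_sim=n_sim, seed=s_fit
        )
        pb = res.profile("base", ev_b)
        pa = res.profile("alt", ev_a)
        v_m = timeline.milestone_alignment(pb, pa, "moult", tv_threshold)
        v_p = timeline.milestone_alignment(pb, pa, "pupariation", tv_threshold)
        v_i = timeline.milestone_alignment(pb, pa, 0.5, tv_threshold)
        moult += v_m.aligned
        wpp += v_p.aligned
        interior += not v_i.aligned
        full += v_m.aligned and v_p.aligned and not v_i.aligned
    return RecoveryReport(
        n_reps=n_reps, moult_aligned=moult, pupariation_aligned=wpp,
        interior_misaligned=interior, full_recovery=full,
    )
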