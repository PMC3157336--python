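"""Benchmarking utilities: recall, AUROC, randomization null, and power.

These mirror how a target-set activity method is validated: the
transfecting (primary) miRNA of each experiment should be re-detected as
active; secondary miRNAs serve as negatives for a ranking AUROC;
shuffling the gene-label <-> value assignment must silence every call;
and simulation across shift sizes quantifies each test's sensitivity.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .activity_calling import call_activity
from .datamodel import (
    MIRNA,
    ActivityCall,
    ActivityTable,
    ExpressionProfile,
    RegulatorCatalog,
    RunConfig,
)
from .synthetic import SIGN_ABSOLUTE, SyntheticSpec, generate_catalog, generate_profile

logger = logging.getLogger("mirtfnet")

VALID_TESTS = ("wr", "ks", "hg", "consensus")


def _significant(call: ActivityCall, test: str) -> bool:
    if test == "consensus":
        return call.consensus_active
    if test in ("wr", "ks", "hg"):
        return getattr(call, f"q_{test}") < call.alpha
    raise ValueError(f"unknown test {test!r}; expected one of {VALID_TESTS}")


def primary_recall(
    tables: Sequence[ActivityTable],
    primaries: Mapping[str, str],
    test: str = "wr",
) -> float:
    """Fraction of experiments whose transfecting miRNA is significant.

    An experiment whose primary miRNA was untested (too few measured
    targets, or absent from the catalog) counts as a miss.
    """
    if not tables:
        raise ValueError("no activity tables given")
    detected = 0
    for table in tables:
        primary = primaries[table.experiment_id]
        call = table.call_for(primary)
        if call is None:
            logger.warning(
                "%s: primary miRNA %s was not tested; counted as missed",
                table.experiment_id, primary,
            )
            continue
        detected += _significant(call, test)
    return detected / len(tables)


def auroc(
    scores: Mapping[str, float],
    positives: set[str],
    negatives: set[str],
) -> float:
    """Probability a random positive outranks a random negative.

    Scores are BH-adjusted p-values, so *lower is better*; tied scores
    contribute half a pair (the Mann-Whitney formulation).
    """
    positives, negatives = set(positives), set(negatives)
    if not positives or not negatives:
        raise ValueError("positives and negatives must both be non-empty")
    if positives & negatives:
        raise ValueError("positives and negatives must be disjoint")
    missing = (positives | negatives) - set(scores)
    if missing:
        raise ValueError(f"no score for {sorted(missing)[:5]}")
    labels = sorted(positives) + sorted(negatives)
    vals = np.array([scores[r] for r in labels])
    ranks = rankdata(vals)  # ascending: rank 1 = best (smallest q)
    n_pos, n_neg = len(positives), len(negatives)
    # pairs in which the positive scores worse than the negative (+ 0.5 ties)
    u_worse = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return 1.0 - u_worse / (n_pos * n_neg)


def combined_scores(table: ActivityTable, kind: str = MIRNA) -> dict[str, float]:
    """Worst-of-both ranking score max(q_wr, q_ks) per regulator.

    A regulator ranks highly only when both rank tests support it, the
    ranking analogue of the two-test consensus rule.
    """
    return {
        c.regulator: max(c.q_wr, c.q_ks)
        for c in table.calls
        if c.kind == kind
    }


def permutation_null(
    profile: ExpressionProfile,
    catalog: RegulatorCatalog,
    config: RunConfig | None = None,
    n_shuffles: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Active-call counts after shuffling the gene-label <-> value assignment.

    Each shuffle permutes the expression values over the gene labels,
    re-runs the full calling pipeline, and records how many regulators come
    out consensus-active (both rank tests BH-significant).  Per-shuffle
    RNG substreams spawn from the master seed, so results are reproducible
    and independent of evaluation order.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    config = config or RunConfig()
    genes = sorted(profile.values)
    values = np.array([profile.values[g] for g in genes])
    counts = np.zeros(n_shuffles, dtype=int)
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_shuffles)):
        rng = np.random.default_rng(child)
        shuffled = values[rng.permutation(values.size)]
        perm_profile = ExpressionProfile(
            experiment_id=f"{profile.experiment_id}-shuffle{i}",
            transfecting_mirna=profile.transfecting_mirna,
            values=dict(zip(genes, map(float, shuffled))),
            cell_line=profile.cell_line,
            time_point_h=profile.time_point_h,
        )
        table = call_activity(perm_profile, catalog, config)
        counts[i] = sum(c.consensus_active for c in table.calls)
    return counts


def power_table(
    spec: SyntheticSpec | None = None,
    deltas: Sequence[float] = (0.0, 0.25, 0.5, 1.0),
    n_targets_list: Sequence[int] = (50,),
    n_reps: int = 200,
    seed: int = 0,
    n_null_regulators: int = 19,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Detection rate of a planted regulator per (test, delta, n_targets).

    Each replicate plants one miRNA with ``n_targets`` targets shifted by
    delta (symmetric |l2fc| inflation) among ``n_null_regulators`` null
    regulators of the same kind, runs the calling pipeline, and checks
    whether the planted regulator is BH-significant under each test.
    Returns a tidy frame with columns test, delta, n_targets, rate.
    """
    spec = spec or SyntheticSpec()
    config = config or RunConfig()
    base = spec.with_(n_mirnas=1 + n_null_regulators, n_tfs=0)
    master = np.random.SeedSequence(seed)
    rows = []
    for delta in deltas:
        for n_targets in n_targets_list:
            cond = base.with_(
                target_set_size_range=(n_targets, n_targets),
            )
            hits = {"wr": 0, "ks": 0, "hg": 0}
            child_seeds = master.spawn(n_reps)
            for child in child_seeds:
                rep_seed = int(child.generate_state(1)[0] % 2**31)
                rep_spec = cond.with_(
                    seed=rep_seed,
                    planted=(("MIR001", float(delta), SIGN_ABSOLUTE),),
                )
                catalog = generate_catalog(rep_spec)
                profile = generate_profile(rep_spec, catalog)
                table = call_activity(profile, catalog, config)
                call = table.call_for("MIR001")
                for test in hits:
                    hits[test] += _significant(call, test)
            for test, n_hit in hits.items():
                rows.append(
                    {
                        "test": test,
                        "delta": float(delta),
                        "n_targets": int(n_targets),
                        "rate": n_hit / n_reps,
                    }
                )
    return pd.DataFrame(rows)
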