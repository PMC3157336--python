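"""Per-experiment orchestration: test every cataloged regulator and call activity.

For each regulator with enough measured targets, the target l2fc values are
compared against all other measured genes with the rank-sum, KS and
hypergeometric tests; p-values are Benjamini-Hochberg adjusted per test
(by default separately within the miRNA and TF families of one
experiment); and the consensus verdict requires both rank tests to be
significant, or — for TFs measured on the array — a fold change beyond the
threshold.  The hypergeometric q-value is reported for comparison only.
"""

from __future__ import annotations

import logging

import numpy as np

from .activity_tests import bh_adjust, hypergeom_p, ks_p, rank_sum_p
from .datamodel import (
    MIRNA,
    TF,
    ActivityCall,
    ActivityTable,
    ExpressionProfile,
    RegulatorCatalog,
    RunConfig,
)

logger = logging.getLogger("mirtfnet")


def call_activity(
    profile: ExpressionProfile,
    catalog: RegulatorCatalog,
    config: RunConfig | None = None,
) -> ActivityTable:
    """Test all cataloged regulators against one expression profile.

    Targets absent from the profile are restricted away before testing, so
    both the target and background groups contain only measured genes.
    Regulators with fewer than ``config.min_targets`` measured targets are
    reported as untested.  Raises if no regulator is testable.
    """
    config = config or RunConfig()
    genes = sorted(profile.values)
    index = {g: i for i, g in enumerate(genes)}
    values = np.array([profile.values[g] for g in genes])
    de_mask = np.abs(values) >= config.l2fc_threshold
    de_set = {g for g, m in zip(genes, de_mask) if m}
    universe = set(genes)

    if (
        profile.transfecting_mirna
        and profile.transfecting_mirna not in catalog.target_sets
    ):
        logger.warning(
            "transfecting miRNA %s has no target set in the catalog; "
            "it cannot be tested", profile.transfecting_mirna,
        )

    calls: list[ActivityCall] = []
    untested: list[str] = []
    for regulator in sorted(catalog.target_sets):
        ts = catalog.target_sets[regulator]
        target_idx = [index[g] for g in ts.targets if g in index]
        if len(target_idx) < config.min_targets:
            untested.append(regulator)
            continue
        mask = np.zeros(values.size, dtype=bool)
        mask[target_idx] = True
        target_vals = values[mask]
        background_vals = values[~mask]
        wr = rank_sum_p(target_vals, background_vals, config.ranking_mode)
        ks = ks_p(target_vals, background_vals, config.ranking_mode)
        hg = hypergeom_p(ts.targets & universe, de_set, universe)
        fc_active = False
        if ts.kind == TF and regulator in index:
            fc_active = bool(abs(values[index[regulator]]) >= config.l2fc_threshold)
        calls.append(
            ActivityCall(
                regulator=regulator,
                kind=ts.kind,
                n_targets_measured=len(target_idx),
                p_wr=wr.p_value,
                p_ks=ks.p_value,
                p_hg=hg.p_value,
                fc_active=fc_active,
                direction=wr.direction,
                alpha=config.alpha,
            )
        )
    if untested:
        logger.info(
            "%s: %d regulator(s) with < %d measured targets left untested",
            profile.experiment_id, len(untested), config.min_targets,
        )
    if not calls:
        raise ValueError(
            f"{profile.experiment_id}: no regulator has >= "
            f"{config.min_targets} measured targets"
        )

    _apply_bh(calls, config)
    table = ActivityTable(
        experiment_id=profile.experiment_id,
        calls=calls,
        untested=untested,
        config=config,
    )
    table.counts = summarize_counts(table)
    return table


def _apply_bh(calls: list[ActivityCall], config: RunConfig) -> None:
    """BH-adjust each test's p-values in place, within the configured scope."""
    if config.bh_scope == "per-kind":
        families = [
            [c for c in calls if c.kind == MIRNA],
            [c for c in calls if c.kind == TF],
        ]
    else:
        families = [list(calls)]
    for family in families:
        if not family:
            continue
        for attr in ("wr", "ks", "hg"):
            q = bh_adjust([getattr(c, f"p_{attr}") for c in family])
            for c, qv in zip(family, q):
                setattr(c, f"q_{attr}", float(qv))


def summarize_counts(table: ActivityTable) -> dict:
    """Per-kind counts of significant regulators by test, plus union counts.

    'shared' counts regulators significant under both rank tests (the
    consensus criterion); 'fc_only' counts TFs active solely through their
    own fold change; 'active' is the union verdict.
    """
    alpha = table.config.alpha
    out: dict = {}
    for kind in (MIRNA, TF, "all"):
        group = [c for c in table.calls if kind == "all" or c.kind == kind]
        out[kind] = {
            "tested": len(group),
            "wr": sum(c.q_wr < alpha for c in group),
            "ks": sum(c.q_ks < alpha for c in group),
            "shared": sum(c.consensus_active for c in group),
            "hg": sum(c.q_hg < alpha for c in group),
            "fc": sum(c.fc_active for c in group),
            "fc_only": sum(c.fc_active and not c.consensus_active for c in group),
            "active": sum(c.active for c in group),
        }
    return out
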