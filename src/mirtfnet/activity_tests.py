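"""Statistical tests comparing target-gene l2fc against the non-target background.

A regulator (miRNA or TF) is considered active when the fold changes of its
annotated targets cannot be a sample from the background distribution of
the remaining measured genes.  Three tests quantify this: the Wilcoxon
rank-sum test on the gene ranking, the two-sample Kolmogorov-Smirnov test
on the l2fc ECDFs, and the hypergeometric test for over-representation of
targets among differentially expressed genes.  The rank-based tests are
threshold-free; the hypergeometric test needs the fold-change cutoff that
defines the DE set.

For small samples (where the number of target/background label assignments
is enumerable) the rank tests use their exact permutation distribution with
mid-rank tie handling; larger samples use the tie-corrected normal / asymptotic
Kolmogorov approximations from scipy.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import TestResult

#: enumerate the exact permutation null when C(n_t + n_b, n_t) is below this
_EXACT_LIMIT = 25_000

_EPS = 1e-12


def _transform(values: np.ndarray, ranking_mode: str) -> np.ndarray:
    if ranking_mode == "absolute":
        return np.abs(values)
    if ranking_mode == "signed":
        return np.asarray(values, dtype=float)
    raise ValueError(f"unknown ranking_mode {ranking_mode!r}")


def _direction(target_values: np.ndarray, background_values: np.ndarray) -> str:
    """Sign of the signed median difference between targets and background."""
    diff = float(np.median(target_values) - np.median(background_values))
    if diff > 0:
        return "up"
    if diff < 0:
        return "down"
    return "mixed"


def _check_groups(target_values, background_values):
    t = np.asarray(target_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    if t.size == 0 or b.size == 0:
        raise ValueError("both target and background groups must be non-empty")
    return t, b


def _exact_feasible(n_t: int, n_b: int) -> bool:
    return math.comb(n_t + n_b, n_t) <= _EXACT_LIMIT


def _exact_rank_sum_p(t: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumerating all label assignments."""
    combined = np.concatenate([t, b])
    ranks = stats.rankdata(combined)
    n_t, n = t.size, combined.size
    obs = float(ranks[:n_t].sum())
    mean = n_t * (n + 1) / 2.0
    dev = abs(obs - mean)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_t):
        total += 1
        if abs(sum(ranks[i] for i in combo) - mean) >= dev - _EPS:
            hits += 1
    return obs, hits / total


def _ks_statistic(sorted_all: np.ndarray, is_target: np.ndarray) -> float:
    """D = sup |ECDF_t - ECDF_b| over a pre-sorted combined sample."""
    n_t = int(is_target.sum())
    n_b = is_target.size - n_t
    cum_t = np.cumsum(is_target) / n_t
    cum_b = np.cumsum(~is_target) / n_b
    # evaluate only at the right edge of tied blocks
    edge = np.ones(is_target.size, dtype=bool)
    edge[:-1] = np.diff(sorted_all) > 0
    return float(np.max(np.abs(cum_t[edge] - cum_b[edge])))


def _exact_ks_p(t: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    combined = np.concatenate([t, b])
    order = np.argsort(combined, kind="stable")
    sorted_all = combined[order]
    n_t, n = t.size, combined.size
    labels = np.zeros(n, dtype=bool)
    labels[:n_t] = True
    obs = _ks_statistic(sorted_all, labels[order])
    hits = total = 0
    for combo in itertools.combinations(range(n), n_t):
        total += 1
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        if _ks_statistic(sorted_all, mask) >= obs - _EPS:
            hits += 1
    return obs, hits / total


def rank_sum_p(
    target_values: Sequence[float],
    background_values: Sequence[float],
    ranking_mode: str = "absolute",
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of targets vs background.

    Genes are ranked on |l2fc| (``ranking_mode='absolute'``, the default,
    sensitive to both induction and repression) or on raw l2fc
    (``'signed'``).  Ties take mid-ranks; the large-sample path applies the
    tie-corrected normal approximation with continuity correction.
    """
    t_raw, b_raw = _check_groups(target_values, background_values)
    t = _transform(t_raw, ranking_mode)
    b = _transform(b_raw, ranking_mode)
    direction = _direction(t_raw, b_raw)
    if np.ptp(np.concatenate([t, b])) == 0:
        return TestResult(0.0, 1.0, t.size, b.size, direction, degenerate=True)
    if _exact_feasible(t.size, b.size):
        statistic, p = _exact_rank_sum_p(t, b)
    else:
        res = stats.mannwhitneyu(t, b, alternative="two-sided", method="asymptotic")
        statistic, p = float(res.statistic), float(res.pvalue)
    return TestResult(statistic, min(max(p, np.nextafter(0, 1)), 1.0), t.size, b.size, direction)


def ks_p(
    target_values: Sequence[float],
    background_values: Sequence[float],
    ranking_mode: str = "absolute",
) -> TestResult:
    """Two-sided two-sample Kolmogorov-Smirnov test of targets vs background.

    The statistic is D = sup |ECDF_targets - ECDF_background| on the
    (possibly absolute-value transformed) l2fc scale.
    """
    t_raw, b_raw = _check_groups(target_values, background_values)
    t = _transform(t_raw, ranking_mode)
    b = _transform(b_raw, ranking_mode)
    direction = _direction(t_raw, b_raw)
    if np.ptp(np.concatenate([t, b])) == 0:
        return TestResult(0.0, 1.0, t.size, b.size, direction, degenerate=True)
    if _exact_feasible(t.size, b.size):
        statistic, p = _exact_ks_p(t, b)
    else:
        res = stats.ks_2samp(t, b, alternative="two-sided", method="asymp")
        statistic, p = float(res.statistic), float(res.pvalue)
    return TestResult(statistic, min(max(p, np.nextafter(0, 1)), 1.0), t.size, b.size, direction)


def hypergeom_p(
    target_set: Iterable[str],
    de_set: Iterable[str],
    universe: Iterable[str],
) -> TestResult:
    """Upper-tail hypergeometric test for target over-representation in the DE set.

    With N measured genes, K of them differentially expressed and n targets,
    returns P(X >= k) for the observed overlap k, i.e. the probability of at
    least as many DE targets by chance.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    targets = set(target_set) & universe
    de = set(de_set) & universe
    n_genes = len(universe)
    k = len(targets & de)
    p = float(stats.hypergeom.sf(k - 1, n_genes, len(de), len(targets)))
    return TestResult(
        statistic=float(k),
        p_value=min(max(p, np.nextafter(0, 1)), 1.0),
        n_targets=len(targets),
        n_background=n_genes - len(targets),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Input p-values must lie in (0, 1]; the adjusted value for each entry is
    min over j >= rank of p_(j) * m / j, capped at 1, so adjusted >= raw.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
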