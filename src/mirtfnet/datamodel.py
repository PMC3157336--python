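"""Core domain types for regulator-activity inference.

The objects here describe one miRNA-transfection experiment (a gene -> log2
fold-change map with metadata), the regulator annotation catalog (miRNA and
TF target sets plus kinase-TF interaction edges), the per-regulator activity
calls, and the regulatory network models rooted at the transfecting miRNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

MIRNA = "miRNA"
TF = "TF"
KINDS = (MIRNA, TF)

#: tests computed per regulator: Wilcoxon rank-sum, Kolmogorov-Smirnov,
#: hypergeometric over-representation.
TESTS = ("wr", "ks", "hg")


def normalize_gene(symbol: str) -> str:
    """Map a gene symbol into the package's case-insensitive namespace."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of a full analysis run.

    alpha
        BH-corrected significance threshold for calling a regulator active.
    fc_threshold
        Fold-change cutoff, applied symmetrically (>= fc or <= 1/fc), used
        both for the TF own-expression activity criterion and for the
        differentially-expressed gene set of the hypergeometric test.
    min_targets
        Minimum number of measured targets required to test a regulator;
        regulators below it are reported as untested.
    ranking_mode
        'absolute' ranks genes by |l2fc| (detects activation and repression
        symmetrically); 'signed' ranks by raw l2fc.
    max_cascade_steps
        Maximum number of edge layers beyond the transfecting miRNA when
        building the regulatory model.
    bh_scope
        'per-kind' adjusts miRNAs and TFs as separate families (per test,
        per experiment); 'pooled' adjusts them jointly.
    """

    alpha: float = 0.05
    fc_threshold: float = 2.0
    min_targets: int = 5
    ranking_mode: str = "absolute"
    max_cascade_steps: int = 3
    bh_scope: str = "per-kind"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not self.fc_threshold > 1.0:
            raise ValueError(f"fc_threshold must be > 1, got {self.fc_threshold}")
        if self.min_targets < 2:
            raise ValueError(f"min_targets must be >= 2, got {self.min_targets}")
        if self.ranking_mode not in ("absolute", "signed"):
            raise ValueError(f"unknown ranking_mode {self.ranking_mode!r}")
        if self.bh_scope not in ("per-kind", "pooled"):
            raise ValueError(f"unknown bh_scope {self.bh_scope!r}")

    @property
    def l2fc_threshold(self) -> float:
        """The fold-change cutoff on the log2 scale."""
        return math.log2(self.fc_threshold)

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


@dataclass
class ExpressionProfile:
    """Gene -> l2fc map for one transfection-vs-control comparison.

    The transfecting miRNA itself is generally absent from ``values``:
    miRNAs are not measured on mRNA arrays, which is the reason activity
    must be inferred from their targets in the first place.
    """

    experiment_id: str
    transfecting_mirna: str | None
    values: dict[str, float]
    cell_line: str = ""
    time_point_h: float = 0.0

    def __post_init__(self) -> None:
        for gene, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite l2fc for gene {gene!r}")
        if self.time_point_h < 0:
            raise ValueError("time_point_h must be non-negative")

    @property
    def genes(self) -> set[str]:
        return set(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TargetSet:
    """One regulator's annotated target genes, tagged with its kind."""

    regulator: str
    kind: str
    targets: set[str]
    sources: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not self.targets:
            raise ValueError(f"empty target set for {self.regulator!r}")


@dataclass
class RegulatorCatalog:
    """Target sets per regulator plus kinase-TF interaction edges.

    ``kinase_tf_edges`` are protein-interaction pairs stored as ordered
    (kinase, tf) tuples; they are traversed miRNA-side -> TF when building
    regulatory models.
    """

    target_sets: dict[str, TargetSet] = field(default_factory=dict)
    kinase_tf_edges: set[tuple[str, str]] = field(default_factory=set)

    @property
    def kinases(self) -> set[str]:
        return {k for k, _ in self.kinase_tf_edges}

    @property
    def mirnas(self) -> set[str]:
        return {r for r, ts in self.target_sets.items() if ts.kind == MIRNA}

    @property
    def tfs(self) -> set[str]:
        return {r for r, ts in self.target_sets.items() if ts.kind == TF}

    def kind_of(self, regulator: str) -> str:
        return self.target_sets[regulator].kind

    def targets_of(self, regulator: str) -> set[str]:
        return self.target_sets[regulator].targets

    def mirna_kinase_edges(self) -> set[tuple[str, str]]:
        """miRNA -> kinase pairs implied by miRNA target sets."""
        kin = self.kinases
        return {
            (r, g)
            for r, ts in self.target_sets.items()
            if ts.kind == MIRNA
            for g in ts.targets & kin
        }

    def add(self, regulator: str, kind: str, targets: Iterable[str], source: str = "") -> None:
        """Union ``targets`` into the regulator's set; kinds must agree."""
        targets = set(targets)
        existing = self.target_sets.get(regulator)
        if existing is None:
            self.target_sets[regulator] = TargetSet(
                regulator, kind, targets, {source} if source else set()
            )
            return
        if existing.kind != kind:
            raise ValueError(
                f"regulator {regulator!r} listed as both "
                f"{existing.kind} and {kind}"
            )
        existing.targets |= targets
        if source:
            existing.sources.add(source)

    def merge(self, other: "RegulatorCatalog") -> "RegulatorCatalog":
        """Return a new catalog with unioned target sets and edges."""
        out = RegulatorCatalog()
        for cat in (self, other):
            for ts in cat.target_sets.values():
                for src in ts.sources or {""}:
                    out.add(ts.regulator, ts.kind, ts.targets, src)
        out.kinase_tf_edges = set(self.kinase_tf_edges) | set(other.kinase_tf_edges)
        return out

    def n_pairs(self) -> int:
        return sum(len(ts.targets) for ts in self.target_sets.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulatorCatalog):
            return NotImplemented
        return (
            {r: (ts.kind, frozenset(ts.targets)) for r, ts in self.target_sets.items()}
            == {r: (ts.kind, frozenset(ts.targets)) for r, ts in other.target_sets.items()}
            and self.kinase_tf_edges == other.kinase_tf_edges
        )


@dataclass
class TestResult:
    """Outcome of one target-vs-background comparison.

    ``direction`` reports the sign of (median target l2fc - median
    background l2fc) on signed values: 'up', 'down', or 'mixed' when the
    medians are equal.  ``degenerate`` flags comparisons where every value
    was tied, in which case p is 1 by convention.
    """

    statistic: float
    p_value: float
    n_targets: int
    n_background: int
    direction: str = "mixed"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside (0,1]")


@dataclass
class ActivityCall:
    """Consensus activity verdict for one regulator in one experiment.

    ``active`` is True iff both rank tests are BH-significant, or the
    fold-change criterion holds (TFs only).  The hypergeometric q-value is
    reported for comparison but never gates the verdict.
    """

    regulator: str
    kind: str
    n_targets_measured: int
    p_wr: float
    p_ks: float
    p_hg: float
    q_wr: float = 1.0
    q_ks: float = 1.0
    q_hg: float = 1.0
    fc_active: bool = False
    direction: str = "mixed"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.kind == MIRNA and self.fc_active:
            raise ValueError("fc_active must be False for miRNAs (not on the array)")

    @property
    def consensus_active(self) -> bool:
        return self.q_wr < self.alpha and self.q_ks < self.alpha

    @property
    def active(self) -> bool:
        return self.consensus_active or self.fc_active


@dataclass
class ActivityTable:
    """All activity calls for one experiment, plus summary counts."""

    experiment_id: str
    calls: list[ActivityCall]
    untested: list[str] = field(default_factory=list)
    config: RunConfig = field(default_factory=RunConfig)
    counts: dict = field(default_factory=dict)

    def call_for(self, regulator: str) -> ActivityCall | None:
        for c in self.calls:
            if c.regulator == regulator:
                return c
        return None

    def active_set(self, kind: str | None = None) -> set[str]:
        return {
            c.regulator
            for c in self.calls
            if c.active and (kind is None or c.kind == kind)
        }


#: node/edge types of the regulatory model graph
NODE_MIRNA = "miRNA"
NODE_KINASE = "kinase"
NODE_TF = "TF"

EDGE_MIRNA_KINASE = "miRNA-kinase"
EDGE_MIRNA_TF = "miRNA-TF"
EDGE_KINASE_TF = "kinase-TF"
EDGE_TF_TF = "TF-TF"


@dataclass
class RegulatoryModel:
    """Typed graph rooted at the transfecting miRNA.

    Nodes map id -> type (miRNA/kinase/TF); edges are (u, v, type, source)
    tuples.  Active TFs that no path could reach from the root are kept in
    ``unconnected_active_tfs`` so that nothing is dropped silently.
    """

    root: str
    nodes: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str, str, str]] = field(default_factory=set)
    connected_tfs: set[str] = field(default_factory=set)
    unconnected_active_tfs: set[str] = field(default_factory=set)
    explained_genes: set[str] = field(default_factory=set)
    explained_fraction: float = 0.0

    def node_set(self) -> set[str]:
        return set(self.nodes)

    def edge_keys(self) -> set[tuple[str, str, str]]:
        """Edges without the source label, for comparisons across models."""
        return {(u, v, t) for u, v, t, _ in self.edges}


@dataclass
class IntersectionModel:
    """Nodes/edges shared by at least k of n per-experiment models."""

    k: int
    n_models: int
    node_support: dict[str, int] = field(default_factory=dict)
    edge_support: dict[tuple[str, str, str], int] = field(default_factory=dict)
    node_types: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.node_support)

    @property
    def edges(self) -> set[tuple[str, str, str]]:
        return set(self.edge_support)


def profile_from_mapping(
    experiment_id: str,
    values: Mapping[str, float],
    transfecting_mirna: str | None = None,
    **meta,
) -> ExpressionProfile:
    """Build a profile from any mapping, normalizing gene symbols."""
    return ExpressionProfile(
        experiment_id=experiment_id,
        transfecting_mirna=transfecting_mirna,
        values={normalize_gene(g): float(v) for g, v in values.items()},
        **meta,
    )
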