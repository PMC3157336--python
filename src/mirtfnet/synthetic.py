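"""Synthetic regulator catalogs and expression profiles with planted signals.

The generator emulates the statistical structure the activity tests assume:
a background of null genes whose l2fc is pure noise, and regulators whose
target sets were drawn at random from that gene universe.  "Planting" a
regulator shifts its targets' l2fc away from the background — downward
(miRNA-like repression), upward, or symmetrically away from zero (an
|l2fc| inflation, the generic signature of an active regulator whose
targets move in both directions).  TF and kinase symbols are part of the
measured gene universe, so TFs can also trip the own-fold-change criterion
and cascades through kinases are constructible.

Everything is a pure function of the spec: the same ``SyntheticSpec``
always yields bit-identical catalogs and profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datamodel import (
    MIRNA,
    TF,
    ExpressionProfile,
    RegulatorCatalog,
)

#: planted-shift sign conventions
SIGN_DOWN = "down"
SIGN_UP = "up"
SIGN_ABSOLUTE = "absolute"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-signal generator.

    Defaults describe the standard study condition used throughout the
    test-bed: 5,000 measured genes, 200 regulators (half miRNA, half TF)
    with target sets of 20-200 genes, and unit-variance Normal background
    noise on the l2fc scale.

    ``planted`` lists (regulator, delta, sign) triples; delta is the shift
    in l2fc units applied to every measured target of that regulator.
    ``noise`` selects the background distribution: 'normal' or 't' (a
    heavy-tailed Student-t with ``t_df`` degrees of freedom, scaled to the
    requested standard deviation) to probe robustness of the rank tests.
    """

    n_genes: int = 5000
    n_mirnas: int = 100
    n_tfs: int = 100
    n_kinases: int = 25
    target_set_size_range: tuple[int, int] = (20, 200)
    background_sd: float = 1.0
    planted: tuple[tuple[str, float, str], ...] = ()
    kinase_tf_density: float = 0.05
    tf_tf_density: float = 0.0
    mirna_kinase_p: float = 0.0
    mirna_tf_p: float = 0.0
    noise: str = "normal"
    t_df: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.target_set_size_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad target_set_size_range {self.target_set_size_range}")
        if hi > self.n_genes:
            raise ValueError(
                f"target set size {hi} exceeds gene universe of {self.n_genes}"
            )
        for d in (self.kinase_tf_density, self.tf_tf_density,
                  self.mirna_kinase_p, self.mirna_tf_p):
            if not 0.0 <= d <= 1.0:
                raise ValueError("densities/probabilities must lie in [0,1]")
        for reg, delta, sign in self.planted:
            if delta < 0:
                raise ValueError(f"planted shift for {reg} must be >= 0")
            if sign not in (SIGN_DOWN, SIGN_UP, SIGN_ABSOLUTE):
                raise ValueError(f"unknown planted sign {sign!r}")
        if self.noise not in ("normal", "t"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.n_tfs + self.n_kinases > self.n_genes:
            raise ValueError("TF and kinase symbols must fit into the gene universe")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


def mirna_names(spec: SyntheticSpec) -> list[str]:
    return [f"MIR{i + 1:03d}" for i in range(spec.n_mirnas)]


def tf_names(spec: SyntheticSpec) -> list[str]:
    return [f"TF{i + 1:03d}" for i in range(spec.n_tfs)]


def kinase_names(spec: SyntheticSpec) -> list[str]:
    return [f"KIN{i + 1:03d}" for i in range(spec.n_kinases)]


def gene_universe(spec: SyntheticSpec) -> list[str]:
    """Measured gene symbols; TFs and kinases occupy the first slots."""
    n_plain = spec.n_genes - spec.n_tfs - spec.n_kinases
    return tf_names(spec) + kinase_names(spec) + [
        f"G{i + 1:05d}" for i in range(n_plain)
    ]


def _streams(spec: SyntheticSpec) -> tuple[np.random.Generator, np.random.Generator]:
    catalog_ss, profile_ss = np.random.SeedSequence(spec.seed).spawn(2)
    return np.random.default_rng(catalog_ss), np.random.default_rng(profile_ss)


def generate_catalog(spec: SyntheticSpec) -> RegulatorCatalog:
    """Random bipartite regulator->target catalog plus kinase-TF edges."""
    rng, _ = _streams(spec)
    universe = np.array(gene_universe(spec))
    lo, hi = spec.target_set_size_range
    catalog = RegulatorCatalog()

    tfs = tf_names(spec)
    kinases = kinase_names(spec)
    for mir in mirna_names(spec):
        size = int(rng.integers(lo, hi + 1))
        targets = set(rng.choice(universe, size=size, replace=False))
        if spec.mirna_kinase_p > 0:
            targets |= {k for k in kinases if rng.random() < spec.mirna_kinase_p}
        if spec.mirna_tf_p > 0:
            targets |= {t for t in tfs if rng.random() < spec.mirna_tf_p}
        catalog.add(mir, MIRNA, targets, "synthetic")
    for tf in tfs:
        size = int(rng.integers(lo, hi + 1))
        targets = set(rng.choice(universe, size=size, replace=False)) - {tf}
        if spec.tf_tf_density > 0:
            targets |= {t for t in tfs if t != tf and rng.random() < spec.tf_tf_density}
        if not targets:
            targets = {str(universe[int(rng.integers(len(universe)))])}
        catalog.add(tf, TF, targets, "synthetic")
    if spec.kinase_tf_density > 0:
        draws = rng.random((len(kinases), len(tfs)))
        for i, k in enumerate(kinases):
            for j, t in enumerate(tfs):
                if draws[i, j] < spec.kinase_tf_density:
                    catalog.kinase_tf_edges.add((k, t))
    return catalog


def generate_profile(
    spec: SyntheticSpec,
    catalog: RegulatorCatalog | None = None,
    experiment_id: str | None = None,
) -> ExpressionProfile:
    """Draw a background noise profile and apply the planted shifts.

    For 'absolute' planting the shift carries the sign of the gene's base
    noise value, inflating |l2fc| symmetrically; overlapping planted target
    sets accumulate their shifts additively.
    """
    catalog = catalog if catalog is not None else generate_catalog(spec)
    _, rng = _streams(spec)
    universe = gene_universe(spec)
    index = {g: i for i, g in enumerate(universe)}
    if spec.noise == "normal":
        base = rng.normal(0.0, spec.background_sd, len(universe))
    else:
        scale = spec.background_sd / np.sqrt(spec.t_df / (spec.t_df - 2))
        base = rng.standard_t(spec.t_df, len(universe)) * scale
    shift = np.zeros(len(universe))
    transfecting = None
    for reg, delta, sign in spec.planted:
        if reg not in catalog.target_sets:
            raise ValueError(f"planted regulator {reg!r} not in catalog")
        if transfecting is None and catalog.kind_of(reg) == MIRNA:
            transfecting = reg
        idx = [index[g] for g in catalog.targets_of(reg) if g in index]
        if sign == SIGN_DOWN:
            shift[idx] -= delta
        elif sign == SIGN_UP:
            shift[idx] += delta
        else:
            s = np.sign(base[idx])
            s[s == 0] = 1.0
            shift[idx] += delta * s
    values = base + shift
    return ExpressionProfile(
        experiment_id=experiment_id or f"synthetic-seed{spec.seed}",
        transfecting_mirna=transfecting,
        values={g: float(values[i]) for g, i in index.items()},
        cell_line="synthetic",
    )


@dataclass
class BenchmarkTruth:
    """Ground-truth labels of a cascade benchmark instance."""

    primary_mirna: str
    cascade_kinases: list[str]
    active_tfs: list[str]
    planted: list[tuple[str, float, str]] = field(default_factory=list)


def make_benchmark(
    spec: SyntheticSpec | None = None,
    n_cascade_kinases: int = 2,
    n_cascade_tfs: int = 3,
    delta_mirna: float = 1.0,
    delta_tf: float = 0.8,
    sign: str = SIGN_ABSOLUTE,
    direct_tf_fraction: float = 0.0,
) -> tuple[ExpressionProfile, RegulatorCatalog, BenchmarkTruth]:
    """End-to-end fixture: a planted miRNA -> kinase -> TF cascade.

    The first miRNA is wired to ``n_cascade_kinases`` kinases, which are
    connected round-robin to ``n_cascade_tfs`` TFs; the miRNA's own targets
    and each cascade TF's targets are planted as shifted.  Activity calling
    should recover the planted TFs and model building should connect them
    to the root.
    """
    spec = spec or SyntheticSpec()
    if n_cascade_kinases > spec.n_kinases or n_cascade_tfs > spec.n_tfs:
        raise ValueError("cascade larger than the catalog's kinase/TF pools")
    catalog = generate_catalog(spec)
    primary = mirna_names(spec)[0]
    kinases = kinase_names(spec)[:n_cascade_kinases]
    tfs = tf_names(spec)[:n_cascade_tfs]

    catalog.add(primary, MIRNA, set(kinases), "cascade")
    n_direct = int(round(direct_tf_fraction * n_cascade_tfs))
    catalog.add(primary, MIRNA, set(tfs[:n_direct]), "cascade")
    for j, tf in enumerate(tfs):
        catalog.kinase_tf_edges.add((kinases[j % n_cascade_kinases], tf))

    planted = [(primary, delta_mirna, sign)] + [(tf, delta_tf, sign) for tf in tfs]
    planted_spec = spec.with_(planted=tuple(planted))
    profile = generate_profile(planted_spec, catalog, experiment_id=f"cascade-seed{spec.seed}")
    truth = BenchmarkTruth(
        primary_mirna=primary,
        cascade_kinases=list(kinases),
        active_tfs=list(tfs),
        planted=planted,
    )
    return profile, catalog, truth
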