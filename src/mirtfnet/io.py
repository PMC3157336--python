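"""Readers and writers for expression tables, target sets, edge lists and config.

Formats are deliberately plain: tab-separated tables for expression values
and interaction edges, GMT-style lines or 3-column edge tables for target
sets, YAML (or flat key=value) for run configuration, JSON for manifests.
Gene and regulator symbols are folded into a case-insensitive namespace on
input (stored upper-case), so catalogs from mixed-case sources line up.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable

import yaml

from .datamodel import (
    KINDS,
    ActivityTable,
    ExpressionProfile,
    RegulatorCatalog,
    RunConfig,
    normalize_gene,
)

logger = logging.getLogger("mirtfnet")


class FormatError(ValueError):
    """A parse failure, carrying file and line context in its message."""


def _lines(path: str | Path):
    text = Path(path).read_text()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line


def read_expression(
    path: str | Path,
    experiment_id: str | None = None,
    transfecting_mirna: str | None = None,
    cell_line: str = "",
    time_point_h: float = 0.0,
) -> ExpressionProfile:
    """Read a 2-column (gene, l2fc) table into an ExpressionProfile.

    An optional single header row is tolerated.  Duplicate gene rows are
    collapsed by their mean l2fc, with a warning naming the genes.
    """
    path = Path(path)
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    n_rows = 0
    for lineno, line in _lines(path):
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        gene = normalize_gene(parts[0])
        try:
            value = float(parts[1])
        except ValueError:
            if n_rows == 0:
                continue  # header row
            raise FormatError(
                f"{path}:{lineno}: unparsable l2fc {parts[1]!r} for gene {parts[0]!r}"
            ) from None
        n_rows += 1
        sums[gene] = sums.get(gene, 0.0) + value
        counts[gene] = counts.get(gene, 0) + 1
    if n_rows == 0:
        raise FormatError(f"{path}: no expression rows found")
    dupes = sorted(g for g, c in counts.items() if c > 1)
    if dupes:
        logger.warning(
            "%s: %d duplicated gene(s) collapsed by mean l2fc (e.g. %s)",
            path, len(dupes), ", ".join(dupes[:5]),
        )
    values = {g: sums[g] / counts[g] for g in sums}
    return ExpressionProfile(
        experiment_id=experiment_id or path.stem,
        transfecting_mirna=transfecting_mirna,
        values=values,
        cell_line=cell_line,
        time_point_h=time_point_h,
    )


def write_expression(profile: ExpressionProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tl2fc\n")
        for gene in sorted(profile.values):
            fh.write(f"{gene}\t{profile.values[gene]:.10g}\n")


def read_target_sets(
    path: str | Path,
    kind: str | None = None,
    source: str = "",
) -> RegulatorCatalog:
    """Read regulator target sets from a GMT-style or 3-column edge file.

    GMT lines are ``regulator<TAB>description<TAB>gene...`` and require the
    ``kind`` argument; edge rows are ``regulator<TAB>kind<TAB>target``.  The
    two formats are distinguished per line by whether the second column is a
    recognised regulator kind.  Empty sets are dropped with a warning; a
    regulator appearing under two kinds is an error.
    """
    path = Path(path)
    source = source or path.stem
    catalog = RegulatorCatalog()
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) == 3 and parts[1].strip() in KINDS:
            reg = normalize_gene(parts[0])
            try:
                catalog.add(reg, parts[1].strip(), {normalize_gene(parts[2])}, source)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            continue
        if kind is None:
            raise FormatError(
                f"{path}:{lineno}: gene-set line found but no regulator kind given"
            )
        if len(parts) < 3:
            raise FormatError(
                f"{path}:{lineno}: gene-set lines need name, description and members"
            )
        reg = normalize_gene(parts[0])
        members = {normalize_gene(g) for g in parts[2:] if g.strip()}
        if not members:
            logger.warning("%s:%d: empty target set for %s dropped", path, lineno, reg)
            continue
        try:
            catalog.add(reg, kind, members, source)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
    n_reg = len(catalog.target_sets)
    logger.info(
        "%s: %d regulators, %d regulator-target pairs (%d distinct targets)",
        path, n_reg, catalog.n_pairs(),
        len(set().union(*(ts.targets for ts in catalog.target_sets.values()))) if n_reg else 0,
    )
    return catalog


def write_target_sets(catalog: RegulatorCatalog, path: str | Path) -> None:
    """Write a catalog's target sets as GMT-tagged 3-column edge rows."""
    with open(path, "w") as fh:
        for reg in sorted(catalog.target_sets):
            ts = catalog.target_sets[reg]
            for gene in sorted(ts.targets):
                fh.write(f"{reg}\t{ts.kind}\t{gene}\n")


def read_interactions(path: str | Path) -> set[tuple[str, str]]:
    """Read a 2-column (kinase, TF) edge table into a de-duplicated pair set."""
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    for lineno, line in _lines(path):
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        pairs.add((normalize_gene(parts[0]), normalize_gene(parts[1])))
    return pairs


def write_interactions(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, t in sorted(pairs):
            fh.write(f"{k}\t{t}\n")


def read_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML mapping (flat key: value)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {f: getattr(config, f) for f in RunConfig.__dataclass_fields__},
            fh, sort_keys=True,
        )


def write_activity_table(table: ActivityTable, path: str | Path) -> None:
    """One TSV row per regulator: kind, n, p/q per test, flags, direction."""
    cols = (
        "regulator\tkind\tn_targets\tp_wr\tp_ks\tp_hg\t"
        "q_wr\tq_ks\tq_hg\tfc_active\tactive\tdirection\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for c in sorted(table.calls, key=lambda c: (c.kind, c.q_wr, c.regulator)):
            fh.write(
                f"{c.regulator}\t{c.kind}\t{c.n_targets_measured}\t"
                f"{c.p_wr:.6g}\t{c.p_ks:.6g}\t{c.p_hg:.6g}\t"
                f"{c.q_wr:.6g}\t{c.q_ks:.6g}\t{c.q_hg:.6g}\t"
                f"{int(c.fc_active)}\t{int(c.active)}\t{c.direction}\n"
            )
        for reg in sorted(table.untested):
            fh.write(f"{reg}\tuntested\t-\t-\t-\t-\t-\t-\t-\t-\t-\t-\n")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config: RunConfig,
    inputs: Iterable[str | Path],
    outputs: Iterable[str | Path],
    seed: int | None = None,
) -> None:
    """Emit a JSON run manifest recording inputs (with digests) and outputs."""
    from datetime import datetime, timezone

    from . import __version__

    manifest = {
        "command": command,
        "version": __version__,
        "seed": seed if seed is not None else config.seed,
        "config": {f: getattr(config, f) for f in RunConfig.__dataclass_fields__},
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
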