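"""Readers and writers for the pipeline's plain-text formats.

Peak calls travel as BED-like TSV (0-based half-open; ``bed6+1`` puts the
read count in a seventh column, ``narrowPeak`` maps the signalValue
column to the count), matrices and results as TSV with row identifiers,
gene sets as one-gene-per-line text, and configuration as YAML.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .atac import CALL_COLUMNS, ConsensusPeak, PeakCall
from .enrichment import GeneSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_matrix",
    "write_matrix",
    "read_gene_set",
    "write_gene_set",
    "write_consensus_bed",
    "load_config",
]


class ParseError(ValueError):
    pass


def read_bed(path, dialect: str = "bed6+1", clone: str = "") -> list[PeakCall]:
    """Read per-clone peak calls from a BED-like file.

    ``bed6+1``: chrom, start, end, name, score, strand, count.
    ``narrowPeak``: chrom, start, end, name, score, strand, signalValue,
    pValue, qValue, summit — the signalValue is rounded into the count.
    """
    if dialect not in ("bed6+1", "narrowPeak"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end, name, score = (
                    parts[0], int(parts[1]), int(parts[2]), parts[3], float(parts[4])
                )
                count = int(round(float(parts[6])))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED line: {line!r}") from exc
            calls.append(PeakCall(chrom, start, end, name, score, count, clone))
    return calls


def write_bed(calls: list[PeakCall] | pd.DataFrame, path) -> None:
    """Write peak calls as bed6+1 (strand written as '.')."""
    if isinstance(calls, pd.DataFrame):
        tab = calls[CALL_COLUMNS]
        rows = list(tab.itertuples(index=False))
    else:
        rows = [(c.chrom, c.start, c.end, c.name, c.score, c.count) for c in calls]
    with open(path, "w") as fh:
        for chrom, start, end, name, score, count in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t.\t{count}\n")


def write_consensus_bed(consensus: list[ConsensusPeak], path) -> None:
    with open(path, "w") as fh:
        for p in consensus:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t"
                f"{p.source_score_per_million:g}\t.\n"
            )


def read_matrix(path) -> pd.DataFrame:
    """Read a TSV matrix (first column = row ids) as floats."""
    try:
        tab = pd.read_csv(path, sep="\t", index_col=0)
        return tab.astype(float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: malformed matrix: {exc}") from exc


def write_matrix(matrix: pd.DataFrame, path, index_label: str = "id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """One gene per line; a first line starting with '#' names the set."""
    path = Path(path)
    genes = []
    note = ""
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                note = line.lstrip("# ")
                continue
            genes.append(line)
    return GeneSet(name or path.stem, frozenset(genes), note)


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        if gene_set.note:
            fh.write(f"# {gene_set.note}\n")
        for g in sorted(gene_set.members):
            fh.write(g + "\n")


def load_config(path, known_keys: set[str] | None = None) -> dict:
    """Load a YAML config, rejecting unknown top-level keys when given."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    if known_keys is not None:
        unknown = set(cfg) - known_keys
        if unknown:
            raise ParseError(f"{path}: unknown config keys: {sorted(unknown)}")
    return cfg
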