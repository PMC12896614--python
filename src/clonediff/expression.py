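"""Two-pass transcript detectability filtering and expression normalization.

The transcriptome reference is decomposed into features: exonic sequence
fragments (defined by transcript membership) and exon–exon junctions.  A
feature is *detected* when it has at least one mapped read in at least half
of the clones; a transcript survives the first pass only when every one of
its constituent features is detected.  Quantifying the reduced reference
then yields TPM, on which a second detection rule operates (TPM > 0 in at
least half the clones), with genes called expressed when any member
transcript is detected.  Gene-level TPM is the sum of member-transcript
TPM.  Normalization is upper-quartile scaling followed by a log transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FeatureCatalog",
    "CoverageMatrix",
    "ExpressionMatrix",
    "compute_apn",
    "flag_detected_features",
    "reduce_transcriptome",
    "flag_detected_transcripts",
    "gene_expressed",
    "second_pass",
    "SecondPassResult",
    "upper_quartile_log",
]

FEATURE_KINDS = ("exonic_fragment", "junction")


class InvalidFeatureError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


class MappingError(KeyError):
    pass


class DegenerateLibraryError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureCatalog:
    """Transcript models decomposed into exonic fragments and junctions.

    Parameters
    ----------
    features
        DataFrame indexed by feature id with columns ``kind``
        (``exonic_fragment`` or ``junction``), ``length`` (nt, > 0) and
        ``transcripts`` (tuple of member transcript ids).
    transcript_to_gene
        Series mapping transcript id -> gene id (each transcript maps to
        exactly one gene).
    """

    features: pd.DataFrame = field(repr=False)
    transcript_to_gene: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        required = {"kind", "length", "transcripts"}
        if not required.issubset(self.features.columns):
            raise InvalidFeatureError(f"feature table needs columns {sorted(required)}")
        if (self.features["length"] <= 0).any():
            raise InvalidFeatureError("feature lengths must be positive")
        bad_kind = set(self.features["kind"]) - set(FEATURE_KINDS)
        if bad_kind:
            raise InvalidFeatureError(f"unknown feature kinds: {sorted(bad_kind)}")
        member = {t for ts in self.features["transcripts"] for t in ts}
        orphans = member - set(self.transcript_to_gene.index)
        if orphans:
            raise MappingError(f"transcripts without a gene mapping: {sorted(orphans)[:5]}")
        # every transcript must have >= 1 feature
        featureless = set(self.transcript_to_gene.index) - member
        if featureless:
            raise InvalidFeatureError(
                f"transcripts with no constituent features: {sorted(featureless)[:5]}"
            )

    @property
    def transcripts(self) -> list[str]:
        return list(self.transcript_to_gene.index)

    @property
    def genes(self) -> list[str]:
        return sorted(self.transcript_to_gene.unique())

    def features_of(self) -> dict[str, list[str]]:
        """Map transcript id -> list of constituent feature ids."""
        out: dict[str, list[str]] = {t: [] for t in self.transcript_to_gene.index}
        for fid, ts in self.features["transcripts"].items():
            for t in ts:
                out[t].append(fid)
        return out

    def to_tsv(self, features_path, transcripts_path) -> None:
        tab = self.features.copy()
        tab["transcripts"] = [",".join(ts) for ts in tab["transcripts"]]
        tab.to_csv(features_path, sep="\t", index_label="feature")
        self.transcript_to_gene.rename("gene").to_csv(
            transcripts_path, sep="\t", index_label="transcript"
        )

    @classmethod
    def from_tsv(cls, features_path, transcripts_path) -> "FeatureCatalog":
        tab = pd.read_csv(features_path, sep="\t", index_col="feature")
        tab["transcripts"] = [
            tuple(s.split(",")) if isinstance(s, str) and s else ()
            for s in tab["transcripts"]
        ]
        t2g = pd.read_csv(transcripts_path, sep="\t", index_col="transcript")["gene"]
        return cls(tab, t2g)


@dataclass(frozen=True)
class CoverageMatrix:
    """Per-feature coverage across clones.

    ``apn`` is average depth per nucleotide (total mapped depth over the
    feature divided by its length); ``read_support`` is the mapped read
    count used by the detection rule.
    """

    apn: pd.DataFrame = field(repr=False)
    read_support: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.apn.shape != self.read_support.shape:
            raise InvalidFeatureError("apn and read_support shapes differ")
        if (self.apn.to_numpy() < 0).any() or (self.read_support.to_numpy() < 0).any():
            raise InvalidFeatureError("coverage values must be non-negative")


@dataclass(frozen=True)
class ExpressionMatrix:
    """TPM per transcript (or gene) per clone, with detection flags.

    ``tpm`` rows are transcripts or genes, columns are clones; each column
    sums to at most 10^6 (equality when the full transcriptome is
    represented).  ``detected`` and ``normalized_log`` are filled in by
    :func:`flag_detected_transcripts` / :func:`upper_quartile_log`.
    """

    tpm: pd.DataFrame = field(repr=False)
    level: str = "transcript"
    detected: pd.Series | None = field(default=None, repr=False)
    normalized_log: pd.DataFrame | None = field(default=None, repr=False)
    scale_factors: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise InvalidFeatureError("TPM values must be non-negative")

    @property
    def clones(self) -> list[str]:
        return list(self.tpm.columns)


def compute_apn(depth_sum: float, length: int) -> float:
    """Average depth per nucleotide: total read depth divided by length."""
    if length <= 0:
        raise InvalidFeatureError(f"feature length must be positive, got {length}")
    if depth_sum < 0:
        raise InvalidFeatureError("depth sum must be non-negative")
    return depth_sum / length


def flag_detected_features(
    cov: CoverageMatrix, min_reads: int = 1, clone_fraction: float = 0.5
) -> pd.Series:
    """Flag features with >= ``min_reads`` in at least ``clone_fraction`` of clones.

    The boundary counts: support in exactly half the clones is detected.
    """
    if not 0 < clone_fraction <= 1:
        raise ValueError("clone_fraction must be in (0, 1]")
    if cov.read_support.size == 0:
        raise EmptyInputError("empty coverage matrix")
    n = cov.read_support.shape[1]
    frac = (cov.read_support >= min_reads).sum(axis=1) / n
    return frac >= clone_fraction


def reduce_transcriptome(catalog: FeatureCatalog, detected_features: pd.Series) -> FeatureCatalog:
    """First-pass reduction: keep transcripts whose features are all detected.

    Genes left with no retained transcript are dropped with them.
    """
    detected_features = detected_features.reindex(catalog.features.index, fill_value=False)
    by_transcript = catalog.features_of()
    keep_t = [
        t for t, feats in by_transcript.items() if all(detected_features[f] for f in feats)
    ]
    keep_set = set(keep_t)
    t2g = catalog.transcript_to_gene.loc[
        [t for t in catalog.transcript_to_gene.index if t in keep_set]
    ]
    feats = catalog.features.copy()
    feats["transcripts"] = [
        tuple(t for t in ts if t in keep_set) for ts in feats["transcripts"]
    ]
    feats = feats[[len(ts) > 0 for ts in feats["transcripts"]]]
    return FeatureCatalog(feats, t2g)


def flag_detected_transcripts(expr: ExpressionMatrix, clone_fraction: float = 0.5) -> pd.Series:
    """Flag rows with TPM strictly positive in at least ``clone_fraction`` of clones."""
    if not 0 < clone_fraction <= 1:
        raise ValueError("clone_fraction must be in (0, 1]")
    n = expr.tpm.shape[1]
    return (expr.tpm > 0).sum(axis=1) / n >= clone_fraction


def gene_expressed(transcript_flags: pd.Series, transcript_to_gene: pd.Series) -> pd.Series:
    """A gene is expressed when at least one member transcript is detected."""
    orphans = set(transcript_flags.index) - set(transcript_to_gene.index)
    if orphans:
        raise MappingError(f"transcripts missing from gene map: {sorted(orphans)[:5]}")
    genes = transcript_to_gene.loc[transcript_flags.index]
    return transcript_flags.groupby(genes).any()


@dataclass(frozen=True)
class SecondPassResult:
    transcripts: ExpressionMatrix
    genes: ExpressionMatrix


def second_pass(
    expr: ExpressionMatrix, catalog: FeatureCatalog, clone_fraction: float = 0.5
) -> SecondPassResult:
    """Restrict expression to pass-1 survivors and re-derive detection and gene TPM.

    Transcript rows not present in ``catalog`` are removed; detection flags
    are recomputed under the TPM rule; gene TPM is the exact sum of member
    transcript TPM, and genes whose transcripts were all removed vanish.
    """
    keep = [t for t in expr.tpm.index if t in set(catalog.transcript_to_gene.index)]
    t_tpm = expr.tpm.loc[keep]
    t_expr = ExpressionMatrix(t_tpm, level="transcript")
    t_flags = flag_detected_transcripts(t_expr, clone_fraction)
    t_expr = replace(t_expr, detected=t_flags)

    genes = catalog.transcript_to_gene.loc[keep]
    g_tpm = t_tpm.groupby(genes).sum()
    g_tpm.index.name = expr.tpm.index.name
    g_expr = ExpressionMatrix(g_tpm, level="gene")
    g_flags = gene_expressed(t_flags, catalog.transcript_to_gene)
    g_expr = replace(g_expr, detected=g_flags.reindex(g_tpm.index, fill_value=False))
    return SecondPassResult(transcripts=t_expr, genes=g_expr)


def upper_quartile_log(
    expr: ExpressionMatrix, pseudo: float = 1.0, log_base: float = 2.0
) -> ExpressionMatrix:
    """Upper-quartile normalize each clone and log-transform.

    Per clone the raw quartile is the 75th percentile of that clone's
    strictly positive values (linear interpolation between order
    statistics).  Scale factors are the raw quartiles divided by their
    geometric mean across clones, so the output stays on a TPM-like scale;
    a single-clone matrix gets factor 1.  The transform is
    ``log(tpm / scale + pseudo)`` in ``log_base``.
    """
    tpm = expr.tpm
    uq = {}
    for clone in tpm.columns:
        pos = tpm[clone][tpm[clone] > 0]
        if pos.empty:
            raise DegenerateLibraryError(f"clone {clone!r} has no positive values")
        uq[clone] = float(np.percentile(pos, 75))
    uq = pd.Series(uq)
    factors = uq / np.exp(np.log(uq).mean())
    norm = np.log(tpm.div(factors, axis=1) + pseudo) / np.log(log_base)
    return replace(expr, normalized_log=norm, scale_factors=factors)
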