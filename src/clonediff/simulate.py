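"""Synthetic clone panels with planted differential structure.

The generator emulates the study design the analysis assumes: a panel of
isogenic clones in five groups (wild type, exon-4-targeted split into
high/low protein expressors, exon-6-targeted, double-targeted), a
transcript-level TPM matrix with log-normal noise and group-mean shifts for
planted differentially expressed genes, feature-level coverage in which a
configurable fraction of transcripts carries one undetected constituent
feature (to exercise the two-pass reduction), and per-clone ATAC peak
calls with negative-binomial counts, linear accessibility gradients across
0/1/2 targeted exons, planted single-clone outliers, and interval jitter
so consensus merging is nontrivial.  A truth table records everything
planted so recovery tests need not re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ClonePanel, InvalidConfigError

__all__ = [
    "PanelConfig",
    "TruthTable",
    "DEEffect",
    "GradientPeak",
    "ExpressionSim",
    "generate_panel",
    "simulate_expression",
    "simulate_atac",
    "default_truth",
]

READ_LENGTH = 100  # nt, used to convert read support to coverage depth


class TruthMismatchError(ValueError):
    """A truth entry references an id absent from the generated data."""


@dataclass(frozen=True)
class PanelConfig:
    """Group sizes for a synthetic clone panel.

    Defaults mirror the study panel: 4 wild-type clones, 7 exon-4-targeted
    clones (3 with near-normal protein, 4 with little or none), 5
    exon-6-targeted clones, and 8 double-targeted clones (24 total).
    """

    n_wt: int = 4
    n_exon4_high: int = 3
    n_exon4_low: int = 4
    n_exon6: int = 5
    n_double: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_wt, self.n_exon4_high, self.n_exon4_low, self.n_exon6, self.n_double)
        if any(c < 0 for c in counts):
            raise InvalidConfigError("group sizes must be non-negative")
        if sum(counts) < 2:
            raise InvalidConfigError("a panel needs at least 2 clones in total")

    @property
    def n_clones(self) -> int:
        return self.n_wt + self.n_exon4_high + self.n_exon4_low + self.n_exon6 + self.n_double


@dataclass(frozen=True)
class DEEffect:
    """A planted expression effect: shift `effect` log2 units on the clones of
    the first-named group of `contrast` (syntax ``"H4:2-vs-0"``)."""

    gene: str
    contrast: str
    effect: float

    def parse(self) -> tuple[str, str, str]:
        hyp, pair = self.contrast.split(":")
        a, b = pair.split("-vs-")
        return hyp, a, b


@dataclass(frozen=True)
class GradientPeak:
    peak: str
    slope: float  # expected extra counts per targeted exon


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of planted structure, for recovery tests."""

    de_genes: tuple[DEEffect, ...] = ()
    gradient_peaks: tuple[GradientPeak, ...] = ()
    outlier_observations: tuple[tuple[str, str], ...] = ()
    enriched_set_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if any(e.effect == 0 for e in self.de_genes):
            raise TruthMismatchError("planted effect sizes must be nonzero")
        if any(g.slope == 0 for g in self.gradient_peaks):
            raise TruthMismatchError("planted gradient slopes must be nonzero")

    def to_tsv(self, path) -> None:
        rows = []
        for e in self.de_genes:
            rows.append(("de_gene", e.gene, e.contrast, e.effect))
        for g in self.gradient_peaks:
            rows.append(("gradient_peak", g.peak, "", g.slope))
        for peak, clone in self.outlier_observations:
            rows.append(("outlier", peak, clone, ""))
        for gene in self.enriched_set_genes:
            rows.append(("enriched_set_gene", gene, "", ""))
        pd.DataFrame(rows, columns=["kind", "id", "detail", "value"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        tab = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
        de, grad, outl, enr = [], [], [], []
        for row in tab.itertuples(index=False):
            if row.kind == "de_gene":
                de.append(DEEffect(row.id, row.detail, float(row.value)))
            elif row.kind == "gradient_peak":
                grad.append(GradientPeak(row.id, float(row.value)))
            elif row.kind == "outlier":
                outl.append((row.id, row.detail))
            elif row.kind == "enriched_set_gene":
                enr.append(row.id)
        return cls(tuple(de), tuple(grad), tuple(outl), tuple(enr))


def generate_panel(config: PanelConfig) -> ClonePanel:
    """Build a clone panel with labels under all four grouping hypotheses."""
    rows = []
    spec = [
        ("WT", config.n_wt),
        ("exon4-high", config.n_exon4_high),
        ("exon4-low", config.n_exon4_low),
        ("exon6", config.n_exon6),
        ("double", config.n_double),
    ]
    h2_of = {
        "WT": "WT",
        "exon4-high": "exon4",
        "exon4-low": "exon4",
        "exon6": "exon6",
        "double": "exon4and6",
    }
    h4_of = {"WT": "0", "exon4-high": "1", "exon4-low": "1", "exon6": "1", "double": "2"}
    i = 0
    for h3, n in spec:
        for _ in range(n):
            i += 1
            clone = f"C{i:02d}"
            h1 = "WT" if h3 == "WT" else "targeted"
            rows.append((clone, h1, h2_of[h3], h3, h4_of[h3]))
    labels = pd.DataFrame(
        rows, columns=["clone", "H1", "H2", "H3", "H4"]
    ).set_index("clone")
    return ClonePanel(labels)


def _targeted_exon_count(panel: ClonePanel) -> pd.Series:
    return panel.groups("H4").astype(int)


@dataclass(frozen=True)
class ExpressionSim:
    """Output bundle of :func:`simulate_expression`."""

    catalog: "FeatureCatalog" = field(repr=False)
    coverage: "CoverageMatrix" = field(repr=False)
    expression: "ExpressionMatrix" = field(repr=False)
    dropped_features: dict = field(default_factory=dict, repr=False)

    def __iter__(self):
        return iter((self.catalog, self.coverage, self.expression))


def simulate_expression(
    panel: ClonePanel,
    n_genes: int,
    transcripts_per_gene: int,
    truth: TruthTable,
    dispersion: float = 0.4,
    seed: int = 0,
    dropped_fraction: float = 0.1,
) -> ExpressionSim:
    """Simulate transcript TPM, feature coverage, and the feature catalog.

    Transcript TPM is log-normal: a gene baseline (log2 scale) plus the
    planted group shift for truth-listed DE genes plus N(0, dispersion)
    clone noise, renormalized so every TPM column sums to 10^6.  Each
    transcript is decomposed into two exonic fragments and one junction;
    ``dropped_fraction`` of transcripts have their junction's read support
    zeroed in a majority of clones so the first-pass reduction removes
    them.
    """
    from .expression import CoverageMatrix, ExpressionMatrix, FeatureCatalog

    if n_genes < 10:
        raise InvalidConfigError("n_genes must be >= 10")
    if dispersion <= 0:
        raise InvalidConfigError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    clones = panel.clones
    n = len(clones)

    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    gene_set = set(genes)
    for eff in truth.de_genes:
        if eff.gene not in gene_set:
            raise TruthMismatchError(f"truth DE gene {eff.gene!r} not in generated genes")

    transcripts, t2g = [], {}
    for g in genes:
        for k in range(1, transcripts_per_gene + 1):
            t = f"{g}.T{k}"
            transcripts.append(t)
            t2g[t] = g

    # gene baselines and per-transcript share of the gene's expression
    gene_base = pd.Series(rng.normal(4.0, 2.0, n_genes), index=genes)
    share = rng.dirichlet(np.full(transcripts_per_gene, 5.0), size=n_genes)
    t_base = np.array(
        [
            gene_base[t2g[t]] + np.log2(share[genes.index(t2g[t]), int(t.split(".T")[1]) - 1])
            for t in transcripts
        ]
    )

    # planted group shifts, per gene, per clone
    shift = pd.DataFrame(0.0, index=genes, columns=clones)
    for eff in truth.de_genes:
        hyp, group_a, _ = eff.parse()
        in_a = panel.groups(hyp) == group_a
        shift.loc[eff.gene, in_a.index[in_a]] += eff.effect

    log2_tpm = (
        t_base[:, None]
        + shift.loc[[t2g[t] for t in transcripts]].to_numpy()
        + rng.normal(0.0, dispersion, (len(transcripts), n))
    )
    raw = 2.0 ** log2_tpm
    tpm = raw / raw.sum(axis=0, keepdims=True) * 1e6
    tpm = pd.DataFrame(tpm, index=transcripts, columns=clones)

    # feature catalog: 2 exonic fragments + 1 junction per transcript
    feat_rows, feat_of_t = [], {}
    for t in transcripts:
        feats = [(f"{t}.EF1", "exonic_fragment"), (f"{t}.EF2", "exonic_fragment"),
                 (f"{t}.J1", "junction")]
        feat_of_t[t] = [f for f, _ in feats]
        for fid, kind in feats:
            feat_rows.append((fid, kind, int(rng.integers(50, 301)), (t,)))
    features = pd.DataFrame(
        feat_rows, columns=["feature", "kind", "length", "transcripts"]
    ).set_index("feature")
    catalog = FeatureCatalog(features, pd.Series(t2g, name="gene"))

    # read support follows transcript abundance
    mean_reads = np.repeat(tpm.to_numpy() / 10.0, 3, axis=0) + 0.5
    support = rng.poisson(mean_reads).astype(int)
    support = pd.DataFrame(support, index=features.index, columns=clones)

    n_drop = int(round(dropped_fraction * len(transcripts)))
    dropped = {}
    if n_drop > 0:
        drop_ts = rng.choice(transcripts, size=n_drop, replace=False)
        n_keep = max(0, int(np.ceil(0.5 * n)) - 1)  # support in < 50% of clones
        for t in drop_ts:
            junction = f"{t}.J1"
            keep = rng.choice(n, size=n_keep, replace=False)
            row = np.zeros(n, dtype=int)
            row[keep] = np.maximum(support.loc[junction].to_numpy()[keep], 1)
            support.loc[junction] = row
            dropped[t] = junction

    depth = support * READ_LENGTH
    apn = depth.div(features["length"], axis=0)
    coverage = CoverageMatrix(apn=apn, read_support=support)
    expr = ExpressionMatrix(tpm, level="transcript")
    return ExpressionSim(catalog, coverage, expr, dropped)


def simulate_atac(
    panel: ClonePanel,
    n_peaks: int,
    truth: TruthTable,
    seed: int = 0,
    peak_width: int = 500,
    jitter: int = 50,
    dispersion: float = 0.1,
    chrom: str = "chr1",
    spacing: int = 10_000,
) -> dict[str, pd.DataFrame]:
    """Simulate per-clone peak-call tables (BED-like, 0-based half-open).

    Counts are negative-binomial around a per-peak baseline; truth
    gradient peaks add ``slope x (number of targeted exons)`` to the
    expectation; truth outlier observations are raised far above the rest
    of the panel (at least 10x the peak's median).  Peak intervals jitter
    by up to ``jitter`` nt per clone around the shared location.
    """
    if n_peaks < 10:
        raise InvalidConfigError("n_peaks must be >= 10")
    if dispersion <= 0:
        raise InvalidConfigError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    clones = panel.clones
    exon_count = _targeted_exon_count(panel)

    peaks = [f"P{i:04d}" for i in range(1, n_peaks + 1)]
    peak_set = set(peaks)
    slope_of = {g.peak: g.slope for g in truth.gradient_peaks}
    for pid in slope_of:
        if pid not in peak_set:
            raise TruthMismatchError(f"truth gradient peak {pid!r} not in generated peaks")
    for pid, clone in truth.outlier_observations:
        if pid not in peak_set or clone not in set(clones):
            raise TruthMismatchError(f"truth outlier ({pid!r}, {clone!r}) unknown")

    base_start = {p: 1000 + i * spacing for i, p in enumerate(peaks)}
    base_mean = rng.uniform(100.0, 400.0, n_peaks)

    r = 1.0 / dispersion
    counts = np.empty((n_peaks, len(clones)), dtype=float)
    for i, pid in enumerate(peaks):
        mu = base_mean[i] + slope_of.get(pid, 0.0) * exon_count.to_numpy()
        mu = np.maximum(mu, 1.0)
        counts[i] = rng.negative_binomial(r, r / (r + mu))
    counts = np.maximum(counts, 1)

    count_df = pd.DataFrame(counts, index=peaks, columns=clones)
    for pid, clone in truth.outlier_observations:
        others = count_df.loc[pid].drop(clone)
        target = max(10.0 * count_df.loc[pid].median(), 6.0 * others.max())
        count_df.loc[pid, clone] = float(np.ceil(target * 1.2))

    calls = {}
    for j, clone in enumerate(clones):
        offs = (
            rng.integers(-jitter, jitter + 1, n_peaks)
            if jitter > 0
            else np.zeros(n_peaks, dtype=int)
        )
        starts = np.array([base_start[p] for p in peaks]) + offs
        cc = count_df[clone].to_numpy().astype(int)
        calls[clone] = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + peak_width,
                "name": [f"{p}:{clone}" for p in peaks],
                "score": cc.astype(float),
                "count": cc,
            }
        )
    return calls


def synthetic_gene_models(
    n_genes: int,
    chrom: str = "chr1",
    spacing: int = 10_000,
    body: int = 2_000,
) -> pd.DataFrame:
    """Gene bodies laid out on the same grid as the simulated peaks.

    Gene ``G000k`` occupies the locus of peak ``P000k``, so a peak is
    proximal to exactly its own gene — which makes the mapping between
    planted accessibility effects and annotated DA genes exact.
    """
    rows = [
        (f"G{i:04d}", chrom, 1000 + (i - 1) * spacing, 1000 + (i - 1) * spacing + body, "+")
        for i in range(1, n_genes + 1)
    ]
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])


def default_truth(
    n_genes: int,
    n_peaks: int,
    seed: int = 0,
    n_de: int = 30,
    de_effect: float = 2.0,
    de_contrast: str = "H4:2-vs-0",
    n_gradient: int = 20,
    gradient_slope: float = 150.0,
    n_outliers: int = 5,
    enriched_set_size: int = 40,
    enriched_de_fraction: float = 0.6,
    clones: list[str] | None = None,
) -> TruthTable:
    """A standard planted-structure table for pipeline runs and recovery tests.

    The enriched gene set mixes planted DE genes
    (``enriched_de_fraction``) with background genes, giving a strong
    odds ratio for the enrichment stage to recover.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    peaks = [f"P{i:04d}" for i in range(1, n_peaks + 1)]
    de = list(rng.choice(genes, size=min(n_de, n_genes), replace=False))
    grad = list(rng.choice(peaks, size=min(n_gradient, n_peaks), replace=False))
    out_peaks = [p for p in peaks if p not in set(grad)]
    outl = list(rng.choice(out_peaks, size=min(n_outliers, len(out_peaks)), replace=False))
    clone_pool = clones if clones is not None else [f"C{i:02d}" for i in range(1, 25)]
    outlier_obs = tuple(
        (p, clone_pool[int(rng.integers(len(clone_pool)))]) for p in outl
    )
    n_de_in_set = min(int(round(enriched_set_size * enriched_de_fraction)), len(de))
    non_de = [g for g in genes if g not in set(de)]
    in_set = list(rng.choice(de, size=n_de_in_set, replace=False)) + list(
        rng.choice(non_de, size=enriched_set_size - n_de_in_set, replace=False)
    )
    return TruthTable(
        de_genes=tuple(DEEffect(g, de_contrast, de_effect) for g in de),
        gradient_peaks=tuple(GradientPeak(p, gradient_slope) for p in grad),
        outlier_observations=outlier_obs,
        enriched_set_genes=tuple(sorted(in_set)),
    )
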