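"""Consensus ATAC peaks: merging, weighted counts, TMM, voom-style weights.

Per-clone peak calls are merged into consensus peaks: calls from different
clones that overlap by at least 1 bp (transitively) form one cluster, and
the member call with the highest depth-normalized score supplies the
consensus coordinate.  Clusters present in at least ``min_clones`` clones
with a consensus score of at least 1 per million are retained.  Counts are
assigned to consensus peaks by weighting each overlapping sample peak's
count by the fraction of the sample peak covered by the consensus interval.

Downstream: peaks with fewer than 10 reads in at least half the samples
are excluded; library scaling uses trimmed-mean-of-M-values (TMM) factors;
log counts-per-million are paired with precision weights from a fitted
mean–variance trend (voom-style); per-peak two-means clustering of sample
counts screens for single-sample outliers; peaks are annotated genic when
within 2 kb of a gene body.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "PeakCall",
    "ConsensusPeak",
    "build_consensus",
    "weighted_counts",
    "filter_low_counts",
    "tmm_factors",
    "voom_transform",
    "detect_outlier_peaks",
    "annotate_peaks",
]

CALL_COLUMNS = ["chrom", "start", "end", "name", "score", "count"]


class DegenerateLibraryError(ValueError):
    pass


class InsufficientReplicationError(ValueError):
    pass


@dataclass(frozen=True)
class PeakCall:
    """A single per-clone peak call (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    name: str
    score: float
    count: int
    clone: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")
        if self.score < 0 or self.count < 0:
            raise ValueError("score and count must be non-negative")


@dataclass(frozen=True)
class ConsensusPeak:
    """Consensus interval chosen from an overlap cluster of per-clone calls."""

    name: str
    chrom: str
    start: int
    end: int
    source_clone: str
    source_score_per_million: float
    supporting_clones: frozenset[str]


def calls_to_frame(calls: list[PeakCall]) -> dict[str, pd.DataFrame]:
    """Group a flat list of calls into per-clone tables."""
    df = pd.DataFrame([c.__dict__ for c in calls])
    return {
        clone: sub[CALL_COLUMNS].reset_index(drop=True)
        for clone, sub in df.groupby("clone")
    }


def _merge_within_clone(table: pd.DataFrame, clone: str) -> pd.DataFrame:
    """Merge overlapping calls within one clone (precondition violation)."""
    out_rows = []
    merged_any = False
    for chrom, sub in table.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"])
        cur = None
        for row in sub.itertuples(index=False):
            if cur is not None and row.start < cur["end"]:
                cur["end"] = max(cur["end"], row.end)
                cur["score"] = max(cur["score"], row.score)
                cur["count"] += row.count
                merged_any = True
            else:
                if cur is not None:
                    out_rows.append(cur)
                cur = dict(zip(CALL_COLUMNS, (chrom, row.start, row.end, row.name,
                                              row.score, row.count)))
        if cur is not None:
            out_rows.append(cur)
    if merged_any:
        warnings.warn(f"clone {clone!r}: overlapping calls within the clone were merged")
    return pd.DataFrame(out_rows, columns=CALL_COLUMNS)


def build_consensus(
    calls: dict[str, pd.DataFrame],
    min_clones: int = 2,
    min_score_per_million: float = 1.0,
) -> list[ConsensusPeak]:
    """Cluster per-clone calls by >=1 bp transitive overlap and pick consensus peaks.

    The consensus coordinate is the member call with the highest
    score-per-million (score x 10^6 / the clone's total score); ties go to
    the longer interval, then the lexicographically smaller clone id.  A
    cluster is retained when it has calls from at least ``min_clones``
    distinct clones and its consensus score-per-million is at least
    ``min_score_per_million``.
    """
    frames = []
    for clone in sorted(calls):
        tab = calls[clone]
        if tab.empty:
            continue
        tab = _merge_within_clone(tab, clone)
        total = tab["score"].sum()
        if total <= 0:
            raise DegenerateLibraryError(f"clone {clone!r} has zero total peak score")
        tab = tab.assign(clone=clone, spm=tab["score"] * 1e6 / total)
        frames.append(tab)
    if not frames:
        return []
    pool = pd.concat(frames, ignore_index=True)

    consensus: list[ConsensusPeak] = []
    idx = 0
    for chrom, sub in pool.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"]).reset_index(drop=True)
        # transitive closure of 1-bp overlap on sorted intervals = sweep
        cluster_rows: list = []
        cluster_end = -1
        for row in sub.itertuples(index=False):
            if cluster_rows and row.start < cluster_end:
                cluster_rows.append(row)
                cluster_end = max(cluster_end, row.end)
            else:
                if cluster_rows:
                    peak = _finalize_cluster(cluster_rows, chrom, idx,
                                             min_clones, min_score_per_million)
                    if peak is not None:
                        consensus.append(peak)
                        idx += 1
                cluster_rows = [row]
                cluster_end = row.end
        if cluster_rows:
            peak = _finalize_cluster(cluster_rows, chrom, idx,
                                     min_clones, min_score_per_million)
            if peak is not None:
                consensus.append(peak)
                idx += 1
    return consensus


def _finalize_cluster(rows, chrom, idx, min_clones, min_spm) -> ConsensusPeak | None:
    clones = {r.clone for r in rows}
    if len(clones) < min_clones:
        return None
    best = max(rows, key=lambda r: (r.spm, r.end - r.start, _neg_str(r.clone)))
    if best.spm < min_spm:
        return None
    return ConsensusPeak(
        name=f"consensus_{idx}",
        chrom=chrom,
        start=int(best.start),
        end=int(best.end),
        source_clone=best.clone,
        source_score_per_million=float(best.spm),
        supporting_clones=frozenset(clones),
    )


class _neg_str(str):
    """Reverses string comparison so max() prefers the lexicographically smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def weighted_counts(
    consensus: list[ConsensusPeak], calls: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Overlap-weighted count matrix (consensus peaks x clones).

    Entry (p, c) sums, over clone-c calls overlapping peak p's interval,
    the call's count times the fraction of the call covered by p.
    """
    clones = sorted(calls)
    mat = np.zeros((len(consensus), len(clones)))
    for j, clone in enumerate(clones):
        tab = calls[clone]
        by_chrom = {chrom: sub.sort_values("start") for chrom, sub in tab.groupby("chrom")}
        for i, peak in enumerate(consensus):
            sub = by_chrom.get(peak.chrom)
            if sub is None:
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            counts = sub["count"].to_numpy(dtype=float)
            ov = np.minimum(ends, peak.end) - np.maximum(starts, peak.start)
            hit = ov > 0
            if hit.any():
                frac = ov[hit] / (ends[hit] - starts[hit])
                mat[i, j] = float(np.sum(counts[hit] * frac))
    return pd.DataFrame(mat, index=[p.name for p in consensus], columns=clones)


def filter_low_counts(
    matrix: pd.DataFrame,
    min_reads: int = 10,
    sample_fraction: float = 0.5,
    round_counts: bool = True,
) -> pd.DataFrame:
    """Drop peaks with fewer than ``min_reads`` in >= ``sample_fraction`` of samples.

    The boundary triggers exclusion: exactly half the samples below the
    threshold drops the peak.  By default weighted counts are rounded to
    integers before applying the read threshold.
    """
    vals = matrix.round() if round_counts else matrix
    low_frac = (vals < min_reads).sum(axis=1) / matrix.shape[1]
    return matrix.loc[low_frac < sample_fraction]


def tmm_factors(
    matrix: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the column whose upper quartile of
    count/library-size is closest to the across-sample mean of those
    quartiles.  For each sample, M (log2 ratio of relative proportions
    against the reference) and A (average log2 proportion) are computed on
    rows positive in both samples, doubly trimmed by ``trim_m`` and
    ``trim_a``, and averaged with inverse-asymptotic-variance weights; the
    factor is 2 to that mean.
    """
    counts = matrix.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(matrix.columns[lib <= 0])
        raise DegenerateLibraryError(f"samples with zero total counts: {bad}")
    f75 = np.array([
        np.percentile(counts[:, j] / lib[j], 75) for j in range(counts.shape[1])
    ])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(counts[:, j], counts[:, ref], lib[j], lib[ref],
                                   trim_m, trim_a)
    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.columns)


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or np.sum(1.0 / v[keep]) == 0:
        return 0.0
    w = 1.0 / v[keep]
    val = float(np.sum(w * m[keep]) / np.sum(w))
    return 0.0 if not np.isfinite(val) else val


def voom_transform(
    matrix: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series | None = None,
    span: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log counts-per-million with mean–variance precision weights.

    log-CPM uses a half-count offset:
    ``log2((count + 0.5) / (library x factor + 1) x 10^6)``.  The residual
    standard deviation of each peak (about group means when ``groups`` is
    supplied, else about the peak mean) is square-rooted and smoothed
    against the peak's average log-count by locally weighted regression
    (``span``); the precision weight of every observation is the predicted
    sqrt-standard-deviation at its own log-CPM, raised to the power -4,
    with predictions clamped to the fitted curve's range at the extremes.
    """
    if matrix.shape[1] < 2:
        raise InsufficientReplicationError("need at least 2 samples")
    if groups is not None:
        groups = groups.reindex(matrix.columns)
        if (groups.value_counts() < 2).any():
            raise InsufficientReplicationError("each group needs at least 2 samples")
    counts = matrix.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    eff = lib * factors.reindex(matrix.columns).to_numpy()
    log_cpm = np.log2((counts + 0.5) / (eff + 1.0) * 1e6)

    if groups is None:
        fitted = log_cpm.mean(axis=1, keepdims=True)
    else:
        fitted = np.empty_like(log_cpm)
        for g in groups.unique():
            cols = (groups == g).to_numpy()
            fitted[:, cols] = log_cpm[:, cols].mean(axis=1, keepdims=True)
    resid = log_cpm - fitted
    df_resid = log_cpm.shape[1] - (1 if groups is None else groups.nunique())
    sd = np.sqrt(np.sum(resid**2, axis=1) / max(df_resid, 1))
    sqrt_sd = np.sqrt(sd)
    mean_log = log_cpm.mean(axis=1)

    if np.allclose(sqrt_sd, sqrt_sd[0]):
        weights = np.full_like(log_cpm, max(sqrt_sd[0], 1e-4) ** -4.0)
    else:
        curve = lowess(sqrt_sd, mean_log, frac=span, return_sorted=True)
        cx, cy = curve[:, 0], np.maximum(curve[:, 1], 1e-4)
        pred = np.interp(np.clip(log_cpm, cx[0], cx[-1]), cx, cy)
        weights = pred**-4.0

    idx, cols = matrix.index, matrix.columns
    return (
        pd.DataFrame(log_cpm, index=idx, columns=cols),
        pd.DataFrame(weights, index=idx, columns=cols),
    )


def detect_outlier_peaks(
    matrix: pd.DataFrame, max_iter: int = 100, tol: float = 1e-8
) -> tuple[pd.DataFrame, list[str]]:
    """Per-peak two-means screening for single-sample outliers.

    For every peak the sample counts are clustered with k = 2 (centers
    initialized at the row minimum and maximum, Lloyd iterations).  If one
    cluster is a single sample, that (peak, sample) observation is flagged
    and the peak is excluded from downstream testing; peaks whose two
    clusters both have at least 2 members are retained.
    """
    if matrix.shape[1] < 3:
        raise InsufficientReplicationError("outlier screening needs >= 3 samples")
    x = matrix.to_numpy(dtype=float)
    c0 = x.min(axis=1)
    c1 = x.max(axis=1)
    nondeg = c1 > c0
    assign = np.zeros(x.shape, dtype=bool)  # True -> high cluster
    for _ in range(max_iter):
        assign = np.abs(x - c1[:, None]) < np.abs(x - c0[:, None])
        n1 = assign.sum(axis=1)
        n0 = x.shape[1] - n1
        new_c1 = np.where(n1 > 0, np.sum(x * assign, axis=1) / np.maximum(n1, 1), c1)
        new_c0 = np.where(n0 > 0, np.sum(x * ~assign, axis=1) / np.maximum(n0, 1), c0)
        if np.max(np.abs(new_c1 - c1)) < tol and np.max(np.abs(new_c0 - c0)) < tol:
            c0, c1 = new_c0, new_c1
            break
        c0, c1 = new_c0, new_c1
    n_high = assign.sum(axis=1)
    n_low = x.shape[1] - n_high
    singleton_high = nondeg & (n_high == 1)
    singleton_low = nondeg & (n_low == 1)
    flags = np.zeros(x.shape, dtype=bool)
    flags[singleton_high] = assign[singleton_high]
    flags[singleton_low] = ~assign[singleton_low]
    flag_df = pd.DataFrame(flags, index=matrix.index, columns=matrix.columns)
    excluded = list(matrix.index[flags.any(axis=1)])
    return flag_df, excluded


def annotate_peaks(
    consensus: list[ConsensusPeak],
    gene_models: pd.DataFrame,
    window: int = 2000,
) -> pd.DataFrame:
    """Categorize peaks as genic (<= ``window`` nt from a gene body) or intergenic.

    ``gene_models`` needs columns gene, chrom, start, end (0-based
    half-open gene bodies).  Returns one row per peak with its category,
    the comma-joined proximal genes, and the distance to the nearest gene
    body (0 for overlap).  Peaks on chromosomes absent from the models are
    annotated intergenic with a warning.
    """
    by_chrom = {c: sub for c, sub in gene_models.groupby("chrom")}
    missing_chroms = set()
    rows = []
    for peak in consensus:
        sub = by_chrom.get(peak.chrom)
        if sub is None:
            missing_chroms.add(peak.chrom)
            rows.append((peak.name, "intergenic", "", np.nan))
            continue
        gstart = sub["start"].to_numpy()
        gend = sub["end"].to_numpy()
        # gap between [start,end) intervals; 0 if they overlap
        dist = np.maximum(0, np.maximum(gstart - peak.end, peak.start - gend))
        prox = dist <= window
        nearest = float(dist.min()) if dist.size else np.nan
        if prox.any():
            genes = ",".join(sub["gene"].to_numpy()[prox])
            rows.append((peak.name, "genic", genes, nearest))
        else:
            rows.append((peak.name, "intergenic", "", nearest))
    if missing_chroms:
        warnings.warn(
            f"chromosomes absent from gene models: {sorted(missing_chroms)}"
        )
    return pd.DataFrame(rows, columns=["peak", "category", "genes", "distance"])
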