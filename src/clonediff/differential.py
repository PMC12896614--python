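"""Group-mean linear models, pairwise contrasts, FDR, and DE/DA classification.

Each feature (gene expression value or peak accessibility value, on the
normalized log scale) is modeled as ``Y_ij = mu + g_i + e_ij`` where ``g_i``
is the clone group under one of the grouping hypotheses and the residual is
Gaussian.  Contrasts between group pairs are tested with two-sided t
statistics using the pooled residual variance from the single group-means
fit; optional observation weights (precision weights from the
mean–variance trend) turn the fit into weighted least squares.  Multiple
testing is corrected per comparison with the Benjamini–Hochberg step-up.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupModelSpec",
    "fit_group_model",
    "pairwise_log2fc",
    "bh_fdr",
    "run_differential",
    "classify_genes",
]


@dataclass(frozen=True)
class GroupModelSpec:
    """Grouping hypothesis: a label per clone plus the contrasts to test."""

    hypothesis: str
    labels: pd.Series = field(repr=False)
    contrasts: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.labels.isna().any():
            raise ValueError("every clone must carry a group label")
        groups = set(self.labels.unique())
        if not self.contrasts:
            pairs = tuple(
                (b, a) for a, b in itertools.combinations(sorted(groups), 2)
            )
            object.__setattr__(self, "contrasts", pairs)
        for a, b in self.contrasts:
            if a not in groups or b not in groups:
                raise ValueError(f"contrast ({a}, {b}) references an unknown group")

    @property
    def groups(self) -> list[str]:
        return sorted(self.labels.unique())


def fit_group_model(
    values: pd.DataFrame,
    spec: GroupModelSpec,
    weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit the group-means model per feature and test each contrast.

    ``values`` is features x clones on the analysis (log) scale; optional
    ``weights`` of the same shape gives weighted least squares.  Returns a
    long table with one row per (feature, contrast): the group means, the
    contrast estimate, the two-sided t statistic and its p-value on the
    pooled-residual-variance degrees of freedom.

    A contrast whose groups have zero clones is skipped with a warning
    column; zero residual variance with a nonzero estimate yields p = 0
    and a ``zero_variance`` flag.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame().T
    labels = spec.labels.reindex(values.columns)
    if labels.isna().any():
        raise ValueError("values contain clones missing from the group labels")
    y = values.to_numpy(dtype=float)
    w = (
        np.ones_like(y)
        if weights is None
        else weights.reindex(index=values.index, columns=values.columns).to_numpy(dtype=float)
    )
    groups = spec.groups
    k = len(groups)
    n = y.shape[1]
    if n - k < 1:
        raise ValueError("residual degrees of freedom < 1")

    means = {}
    wsums = {}
    for g in groups:
        cols = (labels == g).to_numpy()
        wg = w[:, cols]
        means[g] = np.sum(wg * y[:, cols], axis=1) / np.sum(wg, axis=1)
        wsums[g] = np.sum(wg, axis=1)
    fitted = np.empty_like(y)
    for g in groups:
        cols = (labels == g).to_numpy()
        fitted[:, cols] = means[g][:, None]
    rss = np.sum(w * (y - fitted) ** 2, axis=1)
    df = n - k
    s2 = rss / df

    rows = []
    for a, b in spec.contrasts:
        est = means[a] - means[b]
        var = s2 * (1.0 / wsums[a] + 1.0 / wsums[b])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / np.sqrt(var)
        zero_var = (s2 <= 0) | ~np.isfinite(t)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(zero_var & (est != 0), 0.0, p)
        p = np.where(zero_var & (est == 0), 1.0, p)
        with np.errstate(invalid="ignore"):
            edge_t = np.where(est != 0, np.sign(est) * np.inf, 0.0)
        t = np.where(zero_var, edge_t, t)
        rows.append(
            pd.DataFrame(
                {
                    "feature": values.index,
                    "comparison": f"{a}-vs-{b}",
                    "group_a": a,
                    "group_b": b,
                    "mean_a": means[a],
                    "mean_b": means[b],
                    "estimate": est,
                    "statistic": t,
                    "df": df,
                    "p": p,
                    "zero_variance": zero_var,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def pairwise_log2fc(mean_a: float, mean_b: float, delta: float = 0.001):
    """log2 fold change between two group means on the linear scale.

    A small offset ``delta`` guards zero means; both means zero gives 0 by
    convention.  Accepts scalars or arrays.
    """
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    out = np.log2((a + delta) / (b + delta))
    out = np.where((a == 0) & (b == 0), 0.0, out)
    return float(out) if out.ndim == 0 else out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_differential(
    log_values: pd.DataFrame,
    spec: GroupModelSpec,
    weights: pd.DataFrame | None = None,
    linear_values: pd.DataFrame | None = None,
    alpha: float = 0.05,
    fc_delta: float = 0.001,
) -> pd.DataFrame:
    """Fit, test, compute fold changes and BH FDR for one grouping hypothesis.

    Fold changes come from group means of ``linear_values`` (the
    normalized, unlogged scale) when supplied; otherwise the contrast
    estimate on the log scale serves directly as log2FC.  FDR is adjusted
    within each comparison (one family per contrast).
    """
    res = fit_group_model(log_values, spec, weights)
    if linear_values is not None:
        labels = spec.labels.reindex(linear_values.columns)
        lin_means = {
            g: linear_values.loc[:, (labels == g).to_numpy()].mean(axis=1)
            for g in spec.groups
        }
        fc = np.empty(len(res))
        for comp, sub in res.groupby("comparison"):
            a, b = sub["group_a"].iloc[0], sub["group_b"].iloc[0]
            fc[sub.index] = pairwise_log2fc(
                lin_means[a].loc[sub["feature"]].to_numpy(),
                lin_means[b].loc[sub["feature"]].to_numpy(),
                fc_delta,
            )
        res["log2_fc"] = fc
    else:
        res["log2_fc"] = res["estimate"]
    res["fdr"] = np.nan
    for comp in res["comparison"].unique():
        mask = res["comparison"] == comp
        res.loc[mask, "fdr"] = bh_fdr(res.loc[mask, "p"].to_numpy())
    res["significant"] = res["fdr"] < alpha
    return res


def classify_genes(
    de: pd.DataFrame,
    da_peaks: pd.DataFrame,
    annotations: pd.DataFrame,
    alpha: float = 0.05,
    detect_log_tpm: float = 1.0,
) -> pd.DataFrame:
    """Join expression and accessibility results into per-gene categories.

    A gene is DE in a comparison when its expression FDR is below
    ``alpha``; it is DA when at least one significant proximal peak
    (per ``annotations``, mapping peak -> comma-joined proximal genes)
    exists in that comparison.  Detected-in-comparate flags use a mean
    log-TPM threshold.  The joint category is one of ``DE-only``,
    ``DA-only``, ``DE-and-DA``, ``neither``.
    """
    known_peaks = set(da_peaks["feature"])
    unknown = set(annotations["peak"]) - known_peaks
    if unknown and not known_peaks:
        raise ValueError("annotations reference peaks absent from the accessibility results")

    peak_genes = {
        row.peak: tuple(g for g in str(row.genes).split(",") if g)
        for row in annotations.itertuples(index=False)
        if row.category == "genic"
    }
    rows = []
    comparisons = sorted(set(de["comparison"]) | set(da_peaks["comparison"]))
    for comp in comparisons:
        de_sub = de[de["comparison"] == comp].set_index("feature")
        da_sub = da_peaks[da_peaks["comparison"] == comp]
        da_genes: set[str] = set()
        for row in da_sub[da_sub["fdr"] < alpha].itertuples(index=False):
            da_genes.update(peak_genes.get(row.feature, ()))
        genes = sorted(set(de_sub.index) | da_genes)
        for gene in genes:
            if gene in de_sub.index:
                rec = de_sub.loc[gene]
                is_de = bool(rec["fdr"] < alpha)
                det_a = bool(rec["mean_a"] >= detect_log_tpm)
                det_b = bool(rec["mean_b"] >= detect_log_tpm)
            else:
                is_de, det_a, det_b = False, False, False
            is_da = gene in da_genes
            category = {
                (True, True): "DE-and-DA",
                (True, False): "DE-only",
                (False, True): "DA-only",
                (False, False): "neither",
            }[(is_de, is_da)]
            rows.append((gene, comp, det_a, det_b, is_de, is_da, category))
    return pd.DataFrame(
        rows,
        columns=["gene", "comparison", "detected_a", "detected_b", "de", "da", "category"],
    )
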