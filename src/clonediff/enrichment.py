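"""Risk-gene-set enrichment via two-sided chi-square tests on 2x2 tables.

Membership in a curated gene set (e.g. autoimmune-disease risk genes) is
crossed with per-gene significance (differentially expressed and/or
carrying a proximal differentially accessible peak) into a 2x2 contingency
table, tested with Pearson's chi-square on 1 degree of freedom.  No
continuity correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "ContingencyTable",
    "EnrichmentResult",
    "build_table",
    "chisq_test",
    "run_enrichment_suite",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    note: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (in-set, out-set) x (significant, not significant)."""

    a: int  # in set, significant
    b: int  # in set, not significant
    c: int  # out of set, significant
    d: int  # out of set, not significant

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class EnrichmentResult:
    chi2: float
    df: int
    p: float
    table: ContingencyTable
    direction: str  # "enriched" or "depleted"
    degenerate: bool = False


def build_table(universe, significant, gene_set: GeneSet) -> ContingencyTable:
    """Cross set membership with significance over a gene universe.

    ``significant`` may be a set of gene ids or a boolean Series over the
    universe.  Set membership is intersected with the universe first.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty gene universe")
    uni = set(universe)
    if isinstance(significant, pd.Series):
        sig = set(significant.index[significant.astype(bool)])
    else:
        sig = set(significant)
    sig &= uni
    members = gene_set.members & uni
    if not members:
        warnings.warn(f"gene set {gene_set.name!r} is disjoint from the universe")
    a = len(members & sig)
    b = len(members - sig)
    c = len(sig - members)
    d = len(uni) - a - b - c
    return ContingencyTable(a, b, c, d)


def chisq_test(table: ContingencyTable, continuity: bool = False) -> EnrichmentResult:
    """Two-sided Pearson chi-square on a 2x2 table (df = 1).

    By default no Yates continuity correction is applied.  Degenerate
    tables (a zero margin) return chi2 = 0, p = 1, flagged.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins) or n == 0:
        return EnrichmentResult(0.0, 1, 1.0, table, "enriched", degenerate=True)
    if continuity:
        num = n * (abs(a * d - b * c) - n / 2.0) ** 2
        num = max(num, 0.0)
    else:
        num = n * (a * d - b * c) ** 2
    chi2 = num / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(chi2, 1))
    direction = "enriched" if a / (a + b) >= c / (c + d) else "depleted"
    return EnrichmentResult(float(chi2), 1, p, table, direction)


MODES = ("DE", "DA-proximal", "DE-or-DA")
_MODE_ALIASES = {"DA": "DA-proximal", "any": "DE-or-DA"}


def run_enrichment_suite(
    classifications: pd.DataFrame,
    sets: list[GeneSet],
    modes: list[str] = list(MODES),
    universe=None,
    include_union: bool = True,
    continuity: bool = False,
) -> pd.DataFrame:
    """One chi-square test per (gene set, comparison-or-union, mode).

    ``classifications`` is the per-gene table from
    :func:`clonediff.differential.classify_genes` (columns gene,
    comparison, de, da).  ``universe`` defaults to all genes appearing in
    the classifications.  With ``include_union`` the significance flags
    are also pooled across comparisons by logical OR (comparison label
    ``any``).
    """
    modes = [_MODE_ALIASES.get(m, m) for m in modes]
    for mode in modes:
        if mode not in MODES:
            raise ValueError(f"unknown enrichment mode {mode!r}; expected one of {MODES}")
    if universe is None:
        universe = sorted(classifications["gene"].unique())

    jobs: list[tuple[str, pd.DataFrame]] = [
        (comp, sub) for comp, sub in classifications.groupby("comparison")
    ]
    if include_union and classifications["comparison"].nunique() > 1:
        pooled = classifications.groupby("gene")[["de", "da"]].any().reset_index()
        pooled["comparison"] = "any"
        jobs.append(("any", pooled))

    rows = []
    for comp, sub in jobs:
        flag_by_mode = {
            "DE": sub.groupby("gene")["de"].any(),
            "DA-proximal": sub.groupby("gene")["da"].any(),
            "DE-or-DA": sub.groupby("gene")[["de", "da"]].any().any(axis=1),
        }
        for mode in modes:
            flags = flag_by_mode[mode]
            sig = set(flags.index[flags])
            for gs in sets:
                table = build_table(universe, sig, gs)
                res = chisq_test(table, continuity=continuity)
                rows.append(
                    (
                        gs.name,
                        comp,
                        mode,
                        table.a,
                        table.b,
                        table.c,
                        table.d,
                        res.chi2,
                        res.df,
                        res.p,
                        res.direction,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "set", "comparison", "mode",
            "a", "b", "c", "d",
            "chi2", "df", "p", "direction",
        ],
    )
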