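"""Independent straight-line oracles shared by the test suite."""

import numpy as np
import pandas as pd


def brute_force_consensus(calls, min_clones=2, min_spm=1.0):
    """Independent oracle: explicit pairwise-overlap graph + transitive closure.

    Returns (clusters, retained) where clusters are frozensets of member
    names and retained maps a consensus name-defining member to its cluster.
    """
    pool = []
    for clone in sorted(calls):
        tab = calls[clone]
        total = tab["score"].sum()
        for row in tab.itertuples(index=False):
            pool.append(
                dict(chrom=row.chrom, start=row.start, end=row.end, name=row.name,
                     score=row.score, count=row.count, clone=clone,
                     spm=row.score * 1e6 / total)
            )
    n = len(pool)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = pool[i], pool[j]
            if a["chrom"] == b["chrom"] and a["start"] < b["end"] and b["start"] < a["end"]:
                parent[find(i)] = find(j)
    clusters: dict[int, list[dict]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(pool[i])
    retained = []
    for members in clusters.values():
        clones = {m["clone"] for m in members}
        if len(clones) < min_clones:
            continue
        best = sorted(
            members,
            key=lambda m: (-m["spm"], -(m["end"] - m["start"]), m["clone"]),
        )[0]
        if best["spm"] < min_spm:
            continue
        retained.append((best, frozenset(m["name"] for m in members), frozenset(clones)))
    return retained


def brute_force_tmm(counts: np.ndarray, trim_m=0.3, trim_a=0.05) -> np.ndarray:
    """Straight-line TMM oracle following the published formula step by step."""
    lib = counts.sum(axis=0)
    f75 = np.array([np.percentile(counts[:, j] / lib[j], 75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for j in range(counts.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        ms, as_, vs = [], [], []
        for i in range(counts.shape[0]):
            xo, xr = counts[i, j], counts[i, ref]
            if xo > 0 and xr > 0:
                po, pr = xo / lib[j], xr / lib[ref]
                ms.append(np.log2(po / pr))
                as_.append(0.5 * np.log2(po * pr))
                vs.append((lib[j] - xo) / (lib[j] * xo) + (lib[ref] - xr) / (lib[ref] * xr))
        ms, as_, vs = np.array(ms), np.array(as_), np.array(vs)
        n = len(ms)
        rm = pd.Series(ms).rank().to_numpy()
        ra = pd.Series(as_).rank().to_numpy()
        keep = (
            (rm >= np.floor(n * trim_m) + 1) & (rm <= n - np.floor(n * trim_m))
            & (ra >= np.floor(n * trim_a) + 1) & (ra <= n - np.floor(n * trim_a))
        )
        w = 1.0 / vs[keep]
        factors.append(2.0 ** (np.sum(w * ms[keep]) / np.sum(w)))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))
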