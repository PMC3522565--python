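"""Chi-square information-content tests and binary hierarchical clustering.

The cis-regulatory information content of two or three orthologous
promoters is compared by a Pearson goodness-of-fit test of the detected
TFBS-class counts against an equal ratio (1:1 or 1:1:1), without
continuity correction:

    X^2 = sum (o_i - e_i)^2 / e_i,   e_i = total * r_i / sum(r)

with ``cells - 1`` degrees of freedom.  Binary occurrence matrices are
clustered agglomeratively on Jaccard (default) or Hamming distances; the
merge order is fully deterministic, ties being broken by the
lexicographically smallest leaf label, and dendrograms export to Newick.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

from .errors import InputError
from .motif_scan import OccurrenceMatrix


def significance_stars(p_value: float) -> str:
    """Conventional significance marks: * p<0.05, ** p<0.01, *** p<0.001."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class ChiSquareResult:
    counts: tuple[int, ...]
    ratio: tuple[float, ...]
    statistic: float
    df: int
    p_value: float
    stars: str


def chisq_equal_ratio(
    counts: Sequence[float], ratio: Sequence[float] | None = None
) -> ChiSquareResult:
    """Pearson goodness-of-fit of counts against an expected ratio.

    ``ratio`` defaults to equality (1:1:...).  No continuity correction is
    applied; the p-value comes from the chi-square distribution with
    ``len(counts) - 1`` degrees of freedom.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise InputError("counts must be a 1-D vector of length >= 2")
    if np.any(obs < 0):
        raise InputError("counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise InputError("counts must have a positive total")
    r = np.ones_like(obs) if ratio is None else np.asarray(ratio, dtype=float)
    if r.shape != obs.shape:
        raise InputError("ratio must have the same length as counts")
    if np.any(r <= 0):
        raise InputError("expected ratio shares must be positive (zero expected cell)")
    expected = total * r / r.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(chi2.sf(stat, df))
    return ChiSquareResult(
        counts=tuple(int(c) if float(c).is_integer() else float(c) for c in obs),
        ratio=tuple(r),
        statistic=stat,
        df=df,
        p_value=p,
        stars=significance_stars(p),
    )


def information_content_tests(
    unique_counts: pd.DataFrame, bonferroni: bool = False
) -> pd.DataFrame:
    """Equal-ratio tests of per-species unique TFBS counts for each COG.

    ``unique_counts`` has species as rows and COGs as columns.  Returns a
    tidy table with one row per (COG, comparison): the all-species 1:1:...
    test plus every pairwise 1:1 test.  ``bonferroni`` adds a
    family-wise-adjusted p-value column (factor = number of tests) and
    derives the stars from it; by default no correction is applied.
    """
    species = list(unique_counts.index)
    rows = []
    for cog in unique_counts.columns:
        col = unique_counts[cog]
        comparisons = [tuple(species)] if len(species) > 2 else []
        comparisons += [
            (a, b) for i, a in enumerate(species) for b in species[i + 1 :]
        ]
        for comp in comparisons:
            res = chisq_equal_ratio([col[sp] for sp in comp])
            rows.append(
                {
                    "cog_id": cog,
                    "comparison": ":".join(comp),
                    "ratio": ":".join(["1"] * len(comp)),
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "stars": res.stars,
                }
            )
    table = pd.DataFrame(rows)
    if bonferroni and len(table):
        table["p_adjusted"] = (table["p_value"] * len(table)).clip(upper=1.0)
        table["stars"] = table["p_adjusted"].map(significance_stars)
    return table


def binary_distance_matrix(
    occ: OccurrenceMatrix | pd.DataFrame,
    metric: str = "jaccard",
    axis: str = "genes",
) -> pd.DataFrame:
    """Pairwise distances between genes (columns) or classes (rows).

    Jaccard distance is 1 - |intersection| / |union| with 0/0 := 0;
    Hamming distance is the fraction of mismatching positions.
    """
    if metric not in ("jaccard", "hamming"):
        raise InputError(f"unsupported metric {metric!r}")
    if axis not in ("genes", "classes"):
        raise InputError(f"axis must be 'genes' or 'classes', got {axis!r}")
    data = occ.data if isinstance(occ, OccurrenceMatrix) else occ
    if data.size == 0:
        raise InputError("occurrence matrix is empty")
    mat = data.values.astype(bool)
    labels = list(data.columns) if axis == "genes" else list(data.index)
    if axis == "genes":
        mat = mat.T
    d = squareform(pdist(mat, metric=metric))
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Deterministic agglomerative clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Merge:
    left: tuple[str, ...]
    right: tuple[str, ...]
    height: float


@dataclass(eq=False)
class Dendrogram:
    """Merge tree over leaves with merge heights (= merge distances)."""

    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]
    linkage: str
    metric: str = ""

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(m.height for m in self.merges)

    @property
    def first_merge(self) -> frozenset:
        """Leaf labels united by the earliest merge."""
        m = self.merges[0]
        return frozenset(m.left) | frozenset(m.right)

    def to_newick(self) -> str:
        """Ultrametric Newick: leaf-to-root path length = root height / 2."""
        node_str: dict[tuple[str, ...], str] = {(l,): l for l in self.leaves}
        node_h: dict[tuple[str, ...], float] = {(l,): 0.0 for l in self.leaves}
        merged: tuple[str, ...] = ()
        for m in self.merges:
            lk, rk = m.left, m.right
            bl_l = (m.height - node_h[lk]) / 2.0
            bl_r = (m.height - node_h[rk]) / 2.0
            key = tuple(sorted(lk + rk))
            node_str[key] = (
                f"({node_str[lk]}:{bl_l:.6g},{node_str[rk]}:{bl_r:.6g})"
            )
            node_h[key] = m.height
            merged = key
        return node_str[merged] + ";" if self.merges else f"{self.leaves[0]};"


_LINKAGE_FUNCS = {
    "average": np.mean,
    "complete": np.max,
    "single": np.min,
}


def agglomerative_cluster(
    dist: pd.DataFrame, linkage: str = "average", metric: str = ""
) -> Dendrogram:
    """Agglomerative clustering with a deterministic tie rule.

    ``dist`` must be square and symmetric with a zero diagonal.  At each
    step the pair of clusters at minimal linkage distance merges; exact
    ties are broken in favour of the pair whose (smallest-leaf-label,
    smallest-leaf-label) pair sorts first, which makes the topology a pure
    function of the labelled distances.
    """
    if linkage not in _LINKAGE_FUNCS:
        raise InputError(f"unsupported linkage {linkage!r}")
    d = np.asarray(dist.values, dtype=float)
    labels = [str(l) for l in dist.index]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise InputError("distance matrix must be square")
    if list(dist.columns.astype(str)) != labels:
        raise InputError("distance matrix rows and columns must agree")
    if not np.allclose(d, d.T, atol=1e-12):
        raise InputError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise InputError("distance matrix must have a zero diagonal")
    if len(labels) != len(set(labels)):
        raise InputError("leaf labels must be unique")
    if len(labels) < 2:
        return Dendrogram(tuple(labels), (), linkage, metric)

    agg = _LINKAGE_FUNCS[linkage]
    clusters: list[tuple[str, ...]] = [(l,) for l in labels]
    index_of = {l: i for i, l in enumerate(labels)}
    merges: list[Merge] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                ia = [index_of[x] for x in a]
                ib = [index_of[x] for x in b]
                dd = float(agg(d[np.ix_(ia, ib)]))
                tie = tuple(sorted((min(a), min(b))))
                cand = (dd, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dd, _, i, j = best
        a, b = clusters[i], clusters[j]
        left, right = sorted((a, b), key=min)
        merges.append(Merge(left=left, right=right, height=dd))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(tuple(sorted(a + b)))
    return Dendrogram(tuple(labels), tuple(merges), linkage, metric)


def cluster_occurrence(
    occ: OccurrenceMatrix | pd.DataFrame,
    axis: str = "genes",
    metric: str = "jaccard",
    linkage: str = "average",
) -> Dendrogram:
    """Distance computation and clustering in one step."""
    dist = binary_distance_matrix(occ, metric=metric, axis=axis)
    return agglomerative_cluster(dist, linkage=linkage, metric=metric)
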