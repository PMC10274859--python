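"""RNA-target co-occurrence of RBP pairs via the Jaccard index.

Binding-site sets are collections of genomic windows (identity-matched by
default). For every interacting pair with eCLIP-style data, J = |A ∩ B| /
|A ∪ B| is computed and grouped by RNA-dependency class; each class is
compared against random non-interacting RBP pairs with a one-sided
rank-sum test. The all-pairs Jaccard matrix can be ordered by hierarchical
clustering (average linkage, distance 1 - J).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial.distance import squareform

from .network import canonical_pair


@dataclass(frozen=True)
class BindingSiteSet:
    """An RBP's set of binding windows in one cell context."""

    rbp: str
    sites: frozenset = field(default_factory=frozenset)
    cell_context: str = ""

    def __post_init__(self) -> None:
        for w in self.sites:
            if isinstance(w, tuple) and len(w) >= 3 and not w[1] < w[2]:
                raise ValueError(f"malformed window {w!r} (start must be < end)")


def jaccard_index(a: BindingSiteSet | set, b: BindingSiteSet | set) -> float:
    """|A ∩ B| / |A ∪ B|; NaN when both sets are empty."""
    if isinstance(a, BindingSiteSet) and isinstance(b, BindingSiteSet):
        if a.cell_context != b.cell_context:
            raise ValueError(
                f"cell context mismatch: {a.cell_context!r} vs {b.cell_context!r}"
            )
        sa, sb = set(a.sites), set(b.sites)
    else:
        sa, sb = set(a), set(b)
    union = sa | sb
    if not union:
        return float("nan")
    return len(sa & sb) / len(union)


def pairwise_jaccard_matrix(sites: dict[str, set]) -> pd.DataFrame:
    rbps = sorted(sites)
    mat = pd.DataFrame(np.nan, index=rbps, columns=rbps)
    for i, a in enumerate(rbps):
        for b in rbps[i:]:
            j = jaccard_index(sites[a], sites[b])
            mat.loc[a, b] = j
            mat.loc[b, a] = j
    return mat


def typewise_jaccard_comparison(
    typed_edges: pd.DataFrame,
    sites: dict[str, set],
    n_random: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[float]], list[float]]:
    """Jaccard of interacting pairs per RNA-dependency class vs random pairs.

    Random pairs are drawn among RBPs with binding data, excluding
    interacting pairs. Returns (summary frame, per-type value lists, random
    values). One-sided (greater) rank-sum per type.
    """
    rng = np.random.default_rng(seed)
    with_sites = sorted(p for p in sites if sites[p])
    interacting = set()
    per_type: dict[str, list[float]] = {}
    for _, row in typed_edges.iterrows():
        a, b = row["bait"] if "bait" in row else row["protein_a"], (
            row["prey"] if "prey" in row else row["protein_b"]
        )
        interacting.add(canonical_pair(a, b))
        if a in sites and b in sites and sites[a] and sites[b]:
            per_type.setdefault(row["ip_type"], []).append(
                jaccard_index(sites[a], sites[b])
            )
    eligible = [
        (a, b)
        for i, a in enumerate(with_sites)
        for b in with_sites[i + 1:]
        if (a, b) not in interacting
    ]
    if not eligible:
        raise ValueError("no eligible random pairs")
    idx = rng.integers(0, len(eligible), size=n_random)
    random_vals = [jaccard_index(sites[eligible[i][0]], sites[eligible[i][1]]) for i in idx]
    rows = []
    for t in sorted(per_type):
        vals = per_type[t]
        if len(vals) >= 1:
            res = stats.mannwhitneyu(vals, random_vals, alternative="greater")
            p = float(res.pvalue)
        else:
            p = np.nan
        rows.append(
            {"ip_type": t, "n_pairs": len(vals), "median_jaccard": float(np.median(vals)),
             "median_random": float(np.median(random_vals)), "p_value": p}
        )
    return pd.DataFrame(rows), per_type, random_vals


def cluster_jaccard_matrix(matrix: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, pd.Series]:
    """Order a symmetric Jaccard matrix by clustering on distance 1 - J.

    Returns the reordered matrix and per-RBP cluster labels. A singleton
    matrix forms a single cluster.
    """
    if len(matrix) == 1:
        return matrix.copy(), pd.Series([1], index=matrix.index, name="cluster")
    dist = 1.0 - matrix.fillna(0.0).to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = average(squareform(dist, checks=False))
    labels = fcluster(link, t=min(k, len(matrix)), criterion="maxclust")
    order = [matrix.index[i] for i in leaves_list(link)]
    ordered = matrix.loc[order, order]
    return ordered, pd.Series(labels, index=matrix.index, name="cluster")
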