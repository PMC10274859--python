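"""Prey-centric analyses: life-cycle profiles, cluster-based step
assignment, and the prey-prey interaction correlation map.

A prey's life-cycle profile is the fraction of its interacting baits in
each step (all interaction types included, baits without a literature step
accumulate in "unknown"). Profiles are grouped by agglomerative clustering
(average linkage, Euclidean distance) and each cluster is labeled with the
argmax of its mean profile. The prey-prey map is the Pearson correlation of
binary prey x bait incidence vectors.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, leaves_list
from scipy.spatial.distance import pdist, squareform


def prey_step_profiles(
    typed_edges: pd.DataFrame, bait_steps: Mapping[str, str]
) -> pd.DataFrame:
    """Per-prey step fractions plus n_baits and n_steps columns.

    Fractions over steps sum to 1 for every prey.
    """
    steps = sorted(set(bait_steps.values()) | {"unknown"})
    counts: dict[str, dict[str, int]] = {}
    for _, row in typed_edges.iterrows():
        step = bait_steps.get(row["bait"], "unknown") or "unknown"
        prey_counts = counts.setdefault(row["prey"], {s: 0 for s in steps})
        prey_counts[step] += 1
    rows = []
    for prey in sorted(counts):
        c = counts[prey]
        total = sum(c.values())
        frac = {s: c[s] / total for s in steps}
        rows.append(
            {"prey": prey, **frac, "n_baits": total,
             "n_steps": int(sum(v > 0 for v in frac.values()))}
        )
    out = pd.DataFrame(rows).set_index("prey")
    return out[steps + ["n_baits", "n_steps"]]


def assign_prey_steps(
    profiles: pd.DataFrame,
    k: int | None = None,
    height: float | None = None,
) -> pd.DataFrame:
    """Cluster step-fraction profiles and label clusters by dominant step.

    Exactly one of ``k`` (cluster count) or ``height`` (dendrogram cut) is
    used; default is k = number of steps present. Also flags preys touching
    >= 2 steps.
    """
    step_cols = [c for c in profiles.columns if c not in ("n_baits", "n_steps")]
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles to cluster")
    if k is not None and k > len(profiles):
        raise ValueError("k exceeds number of profiles")
    x = profiles[step_cols].to_numpy(dtype=float)
    link = average(pdist(x, metric="euclidean"))
    if height is not None:
        labels = fcluster(link, t=height, criterion="distance")
    else:
        if k is None:
            k = min(len(profiles), int((profiles[step_cols] > 0).any(axis=0).sum()))
        labels = fcluster(link, t=k, criterion="maxclust")
    out = profiles.copy()
    out["cluster"] = labels
    dominant = {}
    for cl, sub in out.groupby("cluster"):
        dominant[cl] = sub[step_cols].mean(axis=0).idxmax()
    out["assigned_step"] = out["cluster"].map(dominant)
    out["multi_step"] = out["n_steps"] >= 2
    return out


def prey_incidence(typed_edges: pd.DataFrame) -> pd.DataFrame:
    """Binary prey x bait matrix: 1 iff any interaction type links them."""
    preys = sorted(typed_edges["prey"].unique())
    baits = sorted(typed_edges["bait"].unique())
    mat = pd.DataFrame(0, index=preys, columns=baits, dtype=int)
    for _, row in typed_edges.iterrows():
        mat.loc[row["prey"], row["bait"]] = 1
    return mat


def prey_correlation_matrix(
    incidence: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Pearson correlation of prey incidence vectors across baits.

    Returns (correlation, defined-mask, display order). Constant rows (zero
    variance) yield masked, undefined entries. The display order comes from
    average-linkage clustering on distance 1 - r over defined preys.
    """
    if incidence.shape[1] < 2:
        raise ValueError("need >= 2 baits")
    x = incidence.to_numpy(dtype=float)
    sd = x.std(axis=1)
    defined = sd > 0
    corr = np.full((len(x), len(x)), np.nan)
    if defined.sum() >= 1:
        sub = np.corrcoef(x[defined])
        sub = np.atleast_2d(sub)
        idx = np.flatnonzero(defined)
        corr[np.ix_(idx, idx)] = sub
    corr_df = pd.DataFrame(corr, index=incidence.index, columns=incidence.index)
    mask = pd.DataFrame(
        np.outer(defined, defined), index=incidence.index, columns=incidence.index
    )
    order = list(incidence.index)
    if defined.sum() >= 3:
        idx = np.flatnonzero(defined)
        dist = 1.0 - corr[np.ix_(idx, idx)]
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, 2.0)
        link = average(squareform(dist, checks=False))
        leaf_order = [incidence.index[idx[i]] for i in leaves_list(link)]
        rest = [p for p, d in zip(incidence.index, defined) if not d]
        order = leaf_order + rest
    return corr_df, mask, order
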