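"""Resampling test for literature support of a PPI network.

F_exp is the fraction of network pairs found in a reference pair set. The
null distribution {F_i} is built by redrawing the network's pairs at random:
in bait-degree-preserving mode each bait keeps its prey count but draws
random preys from a protein universe; in all-pairs mode the same number of
uniform random pairs is drawn. The one-sided empirical p-value uses the
add-one estimator p = (1 + #{F_i >= F_exp}) / (1 + n), which can never be
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import canonical_pair


@dataclass(frozen=True)
class ResamplingResult:
    f_exp: float
    f_samples: tuple[float, ...]
    n_resamples: int
    p_value: float
    fold: float
    universe: str
    mode: str

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.f_samples)) if self.f_samples else np.nan


def support_fraction(
    edges: set[tuple[str, str]] | list[tuple[str, str]],
    reference: set[tuple[str, str]] | list[tuple[str, str]],
) -> float:
    """|edges ∩ reference| / |edges| on unordered pairs."""
    canon_edges = {canonical_pair(a, b) for a, b in edges}
    if not canon_edges:
        raise ValueError("empty edge set")
    canon_ref = {canonical_pair(a, b) for a, b in reference}
    return len(canon_edges & canon_ref) / len(canon_edges)


def resampling_test(
    edges: list[tuple[str, str]],
    reference: set[tuple[str, str]] | list[tuple[str, str]],
    universe: list[str],
    mode: str = "bait_degree_preserving",
    n: int = 1000,
    seed: int = 0,
    universe_name: str = "preys",
) -> ResamplingResult:
    """Compare observed reference support with a degree-matched random null.

    In ``bait_degree_preserving`` mode, ``edges`` are (bait, prey) pairs;
    each bait draws its observed prey count uniformly without replacement
    from ``universe`` (a protein may serve several baits). In ``all_pairs``
    mode |edges| uniform random pairs are drawn from the universe.
    """
    if mode not in ("bait_degree_preserving", "all_pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    canon_ref = {canonical_pair(a, b) for a, b in reference}
    f_exp = support_fraction(edges, canon_ref)
    uni = np.asarray(universe, dtype=object)
    n_edges = len({canonical_pair(a, b) for a, b in edges})

    degrees: dict[str, int] = {}
    if mode == "bait_degree_preserving":
        for a, _ in edges:
            degrees[a] = degrees.get(a, 0) + 1
        max_deg = max(degrees.values())
        if len(uni) < max_deg + 1:
            raise ValueError("universe smaller than the largest bait degree")

    f_samples = np.empty(n)
    for i in range(n):
        pairs: set[tuple[str, str]] = set()
        if mode == "bait_degree_preserving":
            for bait, deg in degrees.items():
                candidates = uni[uni != bait]
                draws = rng.choice(candidates, size=deg, replace=False)
                pairs.update(canonical_pair(bait, p) for p in draws)
        else:
            while len(pairs) < n_edges:
                a, b = rng.choice(uni, size=2, replace=False)
                pairs.add(canonical_pair(a, b))
        f_samples[i] = len(pairs & canon_ref) / len(pairs)

    p = (1.0 + float(np.sum(f_samples >= f_exp))) / (1.0 + n)
    mean_f = float(np.mean(f_samples))
    fold = float("inf") if mean_f == 0 and f_exp > 0 else (
        0.0 if f_exp == 0 and mean_f == 0 else f_exp / mean_f
    )
    return ResamplingResult(
        f_exp=f_exp,
        f_samples=tuple(float(x) for x in f_samples),
        n_resamples=n,
        p_value=p,
        fold=fold,
        universe=universe_name,
        mode=mode,
    )


def resampling_summary(results: dict[str, ResamplingResult]) -> pd.DataFrame:
    """One row per stratum: F_exp, mean F_i, fold enrichment, p."""
    rows = []
    for stratum, res in results.items():
        rows.append(
            {
                "stratum": stratum,
                "f_exp": res.f_exp,
                "mean_f_random": res.mean_f,
                "fold": res.fold,
                "p_value": res.p_value,
                "n_resamples": res.n_resamples,
                "mode": res.mode,
                "universe": res.universe,
            }
        )
    return pd.DataFrame(rows)
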