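"""SEC-MS co-elution calling with a decoy-based empirical FDR.

A deliberately compact co-elution caller for candidate protein pairs:
replicate fraction profiles are averaged (NA-aware), peaks are picked from
moving-average-smoothed profiles, and a pair is scored by the Pearson
correlation over a +/-5-fraction window around a shared apex (apexes within
2 fractions of each other). Significance is empirical: candidate scores are
compared against scores of random co-measured decoy pairs, p = (1 + #{decoy
>= target}) / (1 + n_decoys), with Benjamini-Hochberg q-values and a call
at q < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class CoelutionParams:
    apex_delta: int = 2          # max apex distance for a shared peak
    window: int = 5              # half-width of the correlation window
    smooth_window: int = 3       # moving-average width for peak picking
    min_peak_distance: int = 3   # merge closer peaks, keeping the higher
    min_intensity: float = 0.0
    noise_k: float = 2.0         # noise floor = max(min_intensity, k * median)
    q_threshold: float = 0.1


def average_sec_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Cell-wise mean over observed replicate values (NA removed from mean)."""
    first = replicates[0]
    for rep in replicates[1:]:
        if not (rep.index.equals(first.index) and rep.columns.equals(first.columns)):
            raise ValueError("replicate matrices must share protein and fraction axes")
    stack = np.stack([rep.to_numpy(dtype=float) for rep in replicates])
    counts = np.sum(~np.isnan(stack), axis=0)
    sums = np.nansum(stack, axis=0)
    mean = np.divide(sums, counts, out=np.full(counts.shape, np.nan), where=counts > 0)
    return pd.DataFrame(mean, index=first.index, columns=first.columns)


def detect_peaks(profile: pd.Series, params: CoelutionParams = CoelutionParams()) -> list[int]:
    """Apex fractions of a single elution profile.

    The profile is smoothed with a centered moving average, local maxima
    above the noise floor are kept, and maxima closer than
    ``min_peak_distance`` fractions are merged in favor of the higher one.
    A flat profile yields no peaks.
    """
    obs = profile.dropna()
    if len(obs) < 5:
        raise ValueError("need >= 5 observed fractions")
    y = obs.to_numpy(dtype=float)
    fr = np.asarray(obs.index, dtype=int)
    if np.ptp(y) == 0.0:
        return []
    smooth = (
        pd.Series(y).rolling(params.smooth_window, center=True, min_periods=1).mean().to_numpy()
    )
    floor = max(params.min_intensity, params.noise_k * float(np.median(smooth)))
    apexes = [
        i
        for i in range(len(smooth))
        if smooth[i] > floor
        and (i == 0 or smooth[i] >= smooth[i - 1])
        and (i == len(smooth) - 1 or smooth[i] > smooth[i + 1])
    ]
    apexes.sort(key=lambda i: -smooth[i])
    kept: list[int] = []
    for i in apexes:
        if all(abs(fr[i] - fr[j]) >= params.min_peak_distance for j in kept):
            kept.append(i)
    return sorted(int(fr[i]) for i in kept)


def coelution_score(
    a: str,
    b: str,
    matrix: pd.DataFrame,
    params: CoelutionParams = CoelutionParams(),
    peak_cache: dict[str, list[int]] | None = None,
) -> tuple[float, int | None]:
    """Best windowed Pearson correlation at a shared apex of two profiles.

    Returns (score, apex fraction); (nan, None) when the peak lists share no
    apex within ``apex_delta`` fractions or too few fractions are mutually
    observed in the window.
    """
    if a not in matrix.index or b not in matrix.index:
        raise KeyError(f"protein missing from elution matrix: {a!r} or {b!r}")

    def peaks(p: str) -> list[int]:
        if peak_cache is not None:
            if p not in peak_cache:
                peak_cache[p] = detect_peaks(matrix.loc[p], params)
            return peak_cache[p]
        return detect_peaks(matrix.loc[p], params)

    pa, pb = peaks(a), peaks(b)
    fractions = np.asarray(matrix.columns, dtype=int)
    best: tuple[float, int | None] = (np.nan, None)
    for fa in pa:
        for fb in pb:
            if abs(fa - fb) > params.apex_delta:
                continue
            center = int(round((fa + fb) / 2))
            sel = (fractions >= center - params.window) & (fractions <= center + params.window)
            xa = matrix.loc[a].to_numpy(dtype=float)[sel]
            xb = matrix.loc[b].to_numpy(dtype=float)[sel]
            ok = ~(np.isnan(xa) | np.isnan(xb))
            if ok.sum() < 3:
                continue
            va, vb = xa[ok], xb[ok]
            if np.std(va) == 0.0 or np.std(vb) == 0.0:
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            if not np.isfinite(best[0]) or r > best[0]:
                best = (r, center)
    return best


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def decoy_qvalues(
    candidate_pairs: list[tuple[str, str]],
    matrix: pd.DataFrame,
    n_decoys: int = 1000,
    seed: int = 0,
    params: CoelutionParams = CoelutionParams(),
) -> pd.DataFrame:
    """Score candidate pairs against a random decoy pair distribution.

    Decoys are drawn uniformly from co-measured protein pairs outside the
    candidate set; decoy pairs without a shared peak rank below every real
    score. Candidates without a shared peak are never called.
    """
    if n_decoys < 100:
        raise ValueError("insufficient decoys (need >= 100)")
    rng = np.random.default_rng(seed)
    proteins = [p for p in matrix.index if matrix.loc[p].notna().sum() >= 5]
    candset = {frozenset(p) for p in candidate_pairs}
    cache: dict[str, list[int]] = {}

    decoy_scores = np.full(n_decoys, -np.inf)
    n_prot = len(proteins)
    drawn = 0
    while drawn < n_decoys:
        i, j = rng.integers(0, n_prot, size=2)
        if i == j:
            continue
        a, b = proteins[i], proteins[j]
        if frozenset((a, b)) in candset:
            continue
        score, _ = coelution_score(a, b, matrix, params, cache)
        if np.isfinite(score):
            decoy_scores[drawn] = score
        drawn += 1
    decoy_sorted = np.sort(decoy_scores)

    rows = []
    for a, b in candidate_pairs:
        score, apex = coelution_score(a, b, matrix, params, cache)
        if np.isfinite(score):
            n_ge = int(len(decoy_sorted) - np.searchsorted(decoy_sorted, score, side="left"))
            p = (1.0 + n_ge) / (1.0 + n_decoys)
        else:
            p = np.nan
        rows.append(
            {"protein_a": min(a, b), "protein_b": max(a, b), "score": score,
             "apex_fraction": apex, "p_value": p}
        )
    out = pd.DataFrame(
        rows,
        columns=["protein_a", "protein_b", "score", "apex_fraction", "p_value"],
    )
    out["q_value"] = np.nan
    has_peak = out["p_value"].notna()
    if has_peak.any():
        out.loc[has_peak, "q_value"] = _benjamini_hochberg(
            out.loc[has_peak, "p_value"].to_numpy()
        )
    out["called"] = has_peak & (out["q_value"] < params.q_threshold)
    return out


def call_coelution(
    replicates: list[pd.DataFrame],
    candidate_pairs: list[tuple[str, str]],
    n_decoys: int = 1000,
    seed: int = 0,
    params: CoelutionParams = CoelutionParams(),
) -> pd.DataFrame:
    """Average replicates then run the decoy-calibrated co-elution caller."""
    matrix = average_sec_replicates(replicates)
    return decoy_qvalues(candidate_pairs, matrix, n_decoys=n_decoys, seed=seed, params=params)
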