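"""High-confidence interacting protein (HCIP) calling and RNA-dependency
classification.

A prey is an HCIP of a bait in one RNase condition when all three hold:

* normalized intensity z > 1.645 (top 5% of the sample) in >= 2 replicates,
* log2 ratio of median IP signal over median background signal > 1, and
* one-sided Wilcoxon rank-sum p < alpha (0.05, or 0.01 for strong baits)
  against the pooled background of IgG controls and failed IPs of the same
  RNase condition.

RNA dependency of a bait-prey pair follows from which conditions called it:
both -> direct; only -RNase -> RNA-mediated; only +RNase -> RNA-shielded;
and when the bait's IP failed QC in one condition, every prey called in the
surviving condition is "undetermined".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tmt import FailedIPReport, NormalizedTable

CONDITIONS = ("rnase_plus", "rnase_minus")


class InsufficientDataError(ValueError):
    pass


def replicate_enrichment_flags(
    norm: NormalizedTable,
    bait: str,
    condition: str,
    *,
    samples: list[str] | None = None,
    z_threshold: float = 1.645,
) -> pd.Series:
    """Per-protein count of replicates with z strictly above the threshold.

    Missing values count as not enriched.
    """
    if samples is None:
        samples = norm.sample_ids(bait=bait, condition=condition, role="bait_ip")
    if len(samples) < 2:
        raise InsufficientDataError(
            f"insufficient replicates for {bait}/{condition}: {len(samples)}"
        )
    block = norm.values[samples]
    return (block > z_threshold).sum(axis=1).astype(int)


def background_pool(
    norm: NormalizedTable,
    condition: str,
    failed: FailedIPReport | None = None,
) -> pd.DataFrame:
    """Background columns for a condition: all IgG plus failed-IP samples."""
    cols = norm.sample_ids(role="igg", condition=condition)
    if failed is not None:
        cols = cols + failed.failed_samples(condition)
    if len(cols) < 4:
        raise InsufficientDataError(
            f"background pool for {condition} has {len(cols)} samples (need >= 4)"
        )
    return norm.values[cols]


def rank_sum_enrichment(prey: np.ndarray, background: np.ndarray) -> tuple[float, float]:
    """(log2 ratio of medians, one-sided rank-sum p for prey > background).

    Exact null distribution when both groups have <= 25 observations and no
    cross-group ties; normal approximation with continuity correction
    otherwise. Degenerate all-tied input returns p = 1.
    """
    prey = np.asarray(prey, dtype=float)
    background = np.asarray(background, dtype=float)
    prey = prey[~np.isnan(prey)]
    background = background[~np.isnan(background)]
    if len(prey) < 2 or len(background) < 4:
        raise InsufficientDataError("need >= 2 prey and >= 4 background values")
    ratio = float(np.median(prey) - np.median(background))
    if np.ptp(np.concatenate([prey, background])) == 0.0:
        return ratio, 1.0
    cross_ties = bool(np.intersect1d(prey, background).size)
    method = "exact" if (len(prey) <= 25 and len(background) <= 25 and not cross_ties) else "asymptotic"
    res = stats.mannwhitneyu(prey, background, alternative="greater", method=method)
    return ratio, float(res.pvalue)


@dataclass(frozen=True)
class HCIPParams:
    z_threshold: float = 1.645
    min_enriched_reps: int = 2
    ratio_threshold: float = 1.0
    alpha: float = 0.05


def call_hcips(
    norm: NormalizedTable,
    bait: str,
    condition: str,
    failed: FailedIPReport,
    params: HCIPParams = HCIPParams(),
) -> pd.DataFrame:
    """Score every prey of one bait x condition IP set.

    Returns a frame with columns bait, prey, condition, n_enriched_reps,
    log2_ratio, p_value, alpha_used, passed; the bait's own row is excluded.
    A prey passes iff n_enriched_reps >= 2, log2_ratio > 1 and p < alpha
    (all inequalities strict, matching the published thresholds).
    """
    if not failed.passed(bait, condition):
        raise InsufficientDataError(f"IP set {bait}/{condition} failed QC")
    samples = list(failed.statuses[(bait, condition)].samples)
    flags = replicate_enrichment_flags(
        norm, bait, condition, samples=samples, z_threshold=params.z_threshold
    )
    bg = background_pool(norm, condition, failed)
    rows = []
    for prey in norm.values.index:
        if prey == bait:
            continue
        n_enr = int(flags[prey])
        vals = norm.values.loc[prey, samples].to_numpy(dtype=float)
        bg_vals = bg.loc[prey].to_numpy(dtype=float)
        n_obs = int(np.sum(~np.isnan(vals)))
        n_bg = int(np.sum(~np.isnan(bg_vals)))
        if n_enr >= params.min_enriched_reps and n_obs >= 2 and n_bg >= 4:
            ratio, p = rank_sum_enrichment(vals, bg_vals)
        else:
            ratio, p = np.nan, np.nan
        passed = (
            n_enr >= params.min_enriched_reps
            and np.isfinite(ratio)
            and ratio > params.ratio_threshold
            and np.isfinite(p)
            and p < params.alpha
        )
        rows.append(
            {
                "bait": bait,
                "prey": prey,
                "condition": condition,
                "n_enriched_reps": n_enr,
                "log2_ratio": ratio,
                "p_value": p,
                "alpha_used": params.alpha,
                "passed": bool(passed),
            }
        )
    return pd.DataFrame(rows)


def classify_rna_dependency(
    calls_plus: pd.DataFrame | None,
    calls_minus: pd.DataFrame | None,
    bait_passed_plus: bool,
    bait_passed_minus: bool,
) -> pd.DataFrame:
    """Assign one RNA-dependency class per bait-prey pair.

    Both conditions QC-passed: direct / mediated / shielded by which
    condition(s) called the prey. Exactly one condition passed: every prey
    called there is undetermined. Neither passed: the bait is dropped and an
    empty frame returned.
    """
    def passing(calls: pd.DataFrame | None) -> pd.DataFrame:
        if calls is None or calls.empty:
            return pd.DataFrame(columns=["bait", "prey"])
        return calls.loc[calls["passed"], ["bait", "prey"]]

    plus = passing(calls_plus) if bait_passed_plus else pd.DataFrame(columns=["bait", "prey"])
    minus = passing(calls_minus) if bait_passed_minus else pd.DataFrame(columns=["bait", "prey"])

    if not bait_passed_plus and not bait_passed_minus:
        return pd.DataFrame(columns=["bait", "prey", "ip_type"])
    if bait_passed_plus != bait_passed_minus:  # exactly one condition survived
        surviving = plus if bait_passed_plus else minus
        out = surviving.copy()
        out["ip_type"] = "undetermined"
        return out.reset_index(drop=True)

    plus_set = set(plus["prey"])
    minus_set = set(minus["prey"])
    bait = None
    for frame in (calls_plus, calls_minus):
        if frame is not None and not frame.empty:
            bait = frame["bait"].iloc[0]
            break
    rows = []
    for prey in sorted(plus_set | minus_set):
        if prey in plus_set and prey in minus_set:
            t = "direct"
        elif prey in minus_set:
            t = "mediated"
        else:
            t = "shielded"
        rows.append({"bait": bait, "prey": prey, "ip_type": t})
    return pd.DataFrame(rows, columns=["bait", "prey", "ip_type"])


def call_all_baits(
    norm: NormalizedTable,
    failed: FailedIPReport,
    params: HCIPParams = HCIPParams(),
    alpha_overrides: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run HCIP calling + classification for every bait in the sheet.

    ``alpha_overrides`` maps bait -> alpha (e.g. 0.01 for high-signal baits).
    Returns (typed edge frame, full per-call frame).
    """
    alpha_overrides = alpha_overrides or {}
    baits = sorted({b for b, _ in failed.statuses})
    all_calls = []
    typed = []
    for bait in baits:
        p = params
        if bait in alpha_overrides:
            p = HCIPParams(
                z_threshold=params.z_threshold,
                min_enriched_reps=params.min_enriched_reps,
                ratio_threshold=params.ratio_threshold,
                alpha=alpha_overrides[bait],
            )
        per_cond: dict[str, pd.DataFrame | None] = {}
        for condition in CONDITIONS:
            if failed.passed(bait, condition):
                calls = call_hcips(norm, bait, condition, failed, p)
                per_cond[condition] = calls
                all_calls.append(calls)
            else:
                per_cond[condition] = None
        typed.append(
            classify_rna_dependency(
                per_cond["rnase_plus"],
                per_cond["rnase_minus"],
                failed.passed(bait, "rnase_plus"),
                failed.passed(bait, "rnase_minus"),
            )
        )
    calls_frame = (
        pd.concat(all_calls, ignore_index=True) if all_calls else pd.DataFrame()
    )
    edges = pd.concat(typed, ignore_index=True) if typed else pd.DataFrame(
        columns=["bait", "prey", "ip_type"]
    )
    return edges, calls_frame
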