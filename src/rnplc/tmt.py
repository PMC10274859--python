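"""TMT reporter-intensity normalization for multiplexed IP-MS.

The normalization chain, applied strictly in order and tracked by stage
flags so no stage can be applied twice:

1. ``apportion_ms1`` — within each TMT mix, redistribute the per-protein
   Top3-MS1 quantity over the reporter channels proportionally to the
   reporter intensities (iBAQ-style correction).
2. ``log2_ppm`` — rescale each sample column to parts per million over its
   observed proteins, add a pseudocount of 1, log2 transform.
3. ``batch_correct`` — per mix and protein, subtract from each non-spike
   sample the mean of the other non-spike samples; the spike-in channel is
   corrected by the mean of all other samples of the mix.
4. ``zscore_samples`` — z-score each sample column across proteins
   (sample standard deviation, n-1).

Missing values propagate: they are excluded from sums and means and are
never imputed. Failed-IP detection (``flag_failed_ips``) requires the bait
itself to be in the top 5% of the sample's distribution (z > 1.645) in at
least 2 replicates, and enough quantified proteins per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STAGES = ("ms1_apportioned", "log2_ppm", "batch_corrected", "zscored")

SAMPLE_COLUMNS = ("mix", "channel", "bait", "condition", "replicate", "role")


class StageError(RuntimeError):
    """Raised when normalization stages are applied out of order or twice."""


@dataclass
class IntensityTable:
    """Protein x sample reporter intensities plus the sample sheet.

    ``values`` columns match ``samples.index`` 1:1. ``top3`` holds the
    per-protein Top3-MS1 quantity per mix (needed for MS1 apportioning).
    ``stages`` records which normalization stages were applied.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    top3: pd.DataFrame | None = None
    stages: tuple[str, ...] = ()
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample sheet rows must match matrix columns 1:1")
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        for mix, sub in self.samples.groupby("mix"):
            if sub["channel"].duplicated().any():
                raise ValueError(f"duplicate channel labels in mix {mix!r}")
            if (sub["role"] == "spike_in").sum() > 1:
                raise ValueError(f"more than one spike-in in mix {mix!r}")

    def _require(self, done: Iterable[str], absent: str) -> None:
        if absent in self.stages:
            raise StageError(f"stage {absent!r} already applied")
        for stage in done:
            if stage not in self.stages:
                raise StageError(f"stage {stage!r} must be applied before {absent!r}")

    def sample_ids(self, **criteria) -> list[str]:
        """Sample ids matching sheet-column equality criteria."""
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        return list(self.samples.index[mask])


@dataclass
class NormalizedTable:
    """z-scores of batch-corrected log2 ppm, with provenance flags."""

    values: pd.DataFrame
    samples: pd.DataFrame
    stages: tuple[str, ...]
    constant_samples: tuple[str, ...] = ()
    flags: dict = field(default_factory=dict)

    def sample_ids(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        for key, val in criteria.items():
            mask &= self.samples[key] == val
        return list(self.samples.index[mask])


def remove_excluded(table: IntensityTable, exclude: Iterable[str]) -> IntensityTable:
    """Drop contaminant/immunoglobulin proteins before normalization."""
    keep = [p for p in table.values.index if p not in set(exclude)]
    top3 = table.top3.loc[keep] if table.top3 is not None else None
    return replace(table, values=table.values.loc[keep], top3=top3)


def apportion_ms1(raw: IntensityTable) -> IntensityTable:
    """Redistribute Top3-MS1 quantities over reporter channels, per mix.

    For protein p in mix m: value(p, channel) = Top3(p, m) x reporter
    fraction of that channel within the mix, so the channel sum recovers
    Top3 exactly. All-zero reporter rows become missing.
    """
    raw._require((), "ms1_apportioned")
    if raw.top3 is None:
        raise ValueError("Top3-MS1 quantities required for apportioning")
    out = raw.values.copy()
    for mix, sub in raw.samples.groupby("mix"):
        cols = list(sub.index)
        block = raw.values[cols]
        rowsum = block.sum(axis=1, skipna=True)
        observed = block.notna().any(axis=1)
        denom = rowsum.where(rowsum > 0)
        frac = block.div(denom, axis=0)
        out[cols] = frac.mul(raw.top3[mix], axis=0).where(observed)
    return replace(raw, values=out, stages=raw.stages + ("ms1_apportioned",))


def log2_ppm(table: IntensityTable) -> IntensityTable:
    """Per-sample ppm rescaling followed by log2(x + 1)."""
    table._require(("ms1_apportioned",), "log2_ppm")
    values = table.values
    if (values < 0).any().any():
        raise ValueError("negative intensities")
    colsum = values.sum(axis=0, skipna=True)
    empty = colsum <= 0
    flags = dict(table.flags)
    if empty.any():
        flags["all_missing_samples"] = tuple(colsum.index[empty])
    ppm = values.div(colsum.where(~empty), axis=1) * 1e6
    out = np.log2(ppm + 1.0)
    return replace(table, values=out, stages=table.stages + ("log2_ppm",), flags=flags)


def batch_correct(table: IntensityTable) -> IntensityTable:
    """Mix-wise batch correction by subtraction of matched-sample means.

    Non-spike sample: subtract the protein-wise mean of the *other*
    non-spike samples of its mix. Spike-in: subtract the mean of all other
    samples of the mix. Missing values are excluded from the means.
    """
    table._require(("log2_ppm",), "batch_corrected")
    out = table.values.copy()
    for mix, sub in table.samples.groupby("mix"):
        cols = list(sub.index)
        if len(cols) < 2:
            raise ValueError(f"mix {mix!r} has a single sample; cannot batch correct")
        block = table.values[cols]
        nonspike = [s for s in cols if sub.loc[s, "role"] != "spike_in"]
        ns = block[nonspike]
        ns_sum = ns.sum(axis=1, skipna=True)
        ns_n = ns.notna().sum(axis=1)
        for s in cols:
            if sub.loc[s, "role"] == "spike_in":
                others = [c for c in cols if c != s]
                mean = block[others].mean(axis=1, skipna=True)
            else:
                v = ns[s]
                obs = v.notna()
                n_other = ns_n - obs.astype(int)
                sum_other = ns_sum - v.fillna(0.0)
                mean = sum_other / n_other.where(n_other > 0)
            out[s] = block[s] - mean
    return replace(table, values=out, stages=table.stages + ("batch_corrected",))


def zscore_samples(table: IntensityTable) -> NormalizedTable:
    """z-score each sample column across observed proteins (ddof=1)."""
    table._require(("batch_corrected",), "zscored")
    values = table.values
    mean = values.mean(axis=0, skipna=True)
    sd = values.std(axis=0, ddof=1, skipna=True)
    constant = sd.index[(sd == 0) | sd.isna()]
    z = values.sub(mean, axis=1).div(sd.replace(0.0, np.nan), axis=1)
    for s in constant:
        z[s] = values[s].notna().map({True: 0.0, False: np.nan})
    return NormalizedTable(
        values=z,
        samples=table.samples,
        stages=table.stages + ("zscored",),
        constant_samples=tuple(constant),
        flags=dict(table.flags),
    )


def normalize(raw: IntensityTable, exclude: Iterable[str] = ()) -> NormalizedTable:
    """Full chain: exclusion -> MS1 apportioning -> log2 ppm -> batch -> z."""
    table = remove_excluded(raw, exclude)
    return zscore_samples(batch_correct(log2_ppm(apportion_ms1(table))))


@dataclass(frozen=True)
class IPStatus:
    """QC verdict for one bait x condition IP set."""

    bait: str
    condition: str
    passed: bool
    reason: str
    samples: tuple[str, ...]  # usable replicate sample ids


@dataclass
class FailedIPReport:
    """QC verdicts plus the sample pool they feed back into the background."""

    statuses: dict[tuple[str, str], IPStatus]

    def passed(self, bait: str, condition: str) -> bool:
        st = self.statuses.get((bait, condition))
        return bool(st and st.passed)

    def retained_baits(self) -> list[str]:
        """Baits with >=2 usable replicates in at least one condition."""
        baits = sorted({b for b, _ in self.statuses})
        return [
            b for b in baits
            if any(st.passed for (bb, _), st in self.statuses.items() if bb == b)
        ]

    def failed_samples(self, condition: str) -> list[str]:
        """Bait-IP samples of failed sets in a condition (background pool)."""
        out: list[str] = []
        for (b, c), st in sorted(self.statuses.items()):
            if c == condition and not st.passed:
                out.extend(st.samples)
        return out

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"bait": s.bait, "condition": s.condition, "passed": s.passed,
                 "reason": s.reason, "n_samples": len(s.samples)}
                for s in self.statuses.values()
            ]
        )


def flag_failed_ips(
    norm: NormalizedTable,
    *,
    z_threshold: float = 1.645,
    sparsity_frac: float = 0.5,
) -> FailedIPReport:
    """QC every bait x condition IP set.

    A replicate is dropped as too sparse when it quantifies fewer proteins
    than ``sparsity_frac`` x the median over its mix's samples. The set
    fails when fewer than 2 usable replicates remain, when the bait is not
    measured, or when the bait's z exceeds ``z_threshold`` in fewer than 2
    usable replicates (i.e. the bait is not within the top 5% of the
    sample's distribution often enough).
    """
    counts = norm.values.notna().sum(axis=0)
    mix_median = {
        mix: float(counts[list(sub.index)].median())
        for mix, sub in norm.samples.groupby("mix")
    }
    statuses: dict[tuple[str, str], IPStatus] = {}
    ip_rows = norm.samples[norm.samples["role"] == "bait_ip"]
    for (bait, condition), sub in ip_rows.groupby(["bait", "condition"]):
        sample_ids = list(sub.index)
        usable = [
            s for s in sample_ids
            if counts[s] >= sparsity_frac * mix_median[norm.samples.loc[s, "mix"]]
        ]
        if bait not in norm.values.index:
            st = IPStatus(bait, condition, False, "bait unmeasured", tuple(usable))
        elif len(usable) < 2:
            st = IPStatus(bait, condition, False, "too sparse", tuple(usable))
        else:
            z = norm.values.loc[bait, usable]
            n_enriched = int((z > z_threshold).sum())
            if n_enriched >= 2:
                st = IPStatus(bait, condition, True, "ok", tuple(usable))
            else:
                st = IPStatus(
                    bait, condition, False,
                    f"bait enriched in {n_enriched} replicate(s)", tuple(usable),
                )
        statuses[(bait, condition)] = st
    return FailedIPReport(statuses)
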