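"""Synthetic ground-truth generator for the RNA-aware interactome pipeline.

Emulates the experimental design of an RNase-coupled IP-MS / SEC-MS study of
RNA-binding proteins (RBPs) across the mRNA life-cycle:

* TMT11 immunopurification mixes — per bait, one mix with 1 spike-in channel
  (126), 3 +RNase bait IPs, 3 -RNase bait IPs and 2+2 IgG controls;
* true bait-prey edges of four RNA-dependency classes (direct, RNA-mediated,
  RNA-shielded, undetermined) planted as log2 enrichments on a log-normal
  protein background;
* size-exclusion chromatography (SEC) elution profiles where complex members
  co-elute at a mass-calibrated apex fraction;
* a total-proteome abundance table; and
* per-RBP transcriptomic binding-site sets with type-dependent overlap.

Every generator is a pure function of (truth, config); randomness comes only
from the config seed, so all outputs are reproducible byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tmt import IntensityTable

# Major mRNA life-cycle stages used as bait step annotations.
LIFE_CYCLE_STEPS: tuple[str, ...] = (
    "transcription",
    "splicing",
    "modification",
    "three_prime_processing",
    "nuclear_export",
    "localization",
    "translation",
    "degradation",
)

INTERACTION_TYPES: tuple[str, ...] = ("direct", "mediated", "shielded", "undetermined")

CONDITIONS: tuple[str, str] = ("rnase_plus", "rnase_minus")

#: TMT11 reporter channel labels; 126 carries the pooled spike-in.
TMT11_CHANNELS: tuple[str, ...] = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131N", "131C",
)


class ConfigurationError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Intensity parameters are on the log2 scale; ``effect_size`` is the log2
    enrichment of a true prey in its bait's IP channels, ``bait_effect`` the
    bait's self-enrichment. ``dropout_threshold`` is on the raw intensity
    scale: values below it are censored (missing not at random), mimicking
    MS detection limits.
    """

    n_baits: int = 12
    n_preys: int = 300
    type_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "direct": 0.20,
            "mediated": 0.26,
            "shielded": 0.47,
            "undetermined": 0.07,
        }
    )
    n_complexes: int = 20
    edges_per_bait: int = 15
    n_ip_replicates: int = 3
    n_igg_replicates: int = 2
    background_mu: float = 13.0
    background_sigma: float = 2.0
    noise_sd: float = 0.3
    effect_size: float = 3.0
    bait_effect: float = 5.0
    dropout_threshold: float = 512.0
    # SEC design: fractions 10..66 inclusive.
    n_fractions: int = 57
    first_fraction: int = 10
    sec_noise_sd: float = 0.15
    complex_peak_sigma: float = 1.5
    monomer_sigma_range: tuple[float, float] = (1.0, 2.5)
    complex_amplitude: float = 1.0e6
    monomer_amplitude: float = 4.0e5
    # Binding-site universe (windows on a synthetic chromosome).
    site_universe: int = 2000
    site_base_rate: float = 0.05
    overlap_rho: Mapping[str, float] = field(
        default_factory=lambda: {
            "direct": 0.50,
            "mediated": 0.20,
            "shielded": 0.30,
            "undetermined": 0.55,
        }
    )
    bridge_n_baits: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.type_proportions.get(t, 0.0) for t in INTERACTION_TYPES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"type_proportions must sum to 1 (got {total!r})"
            )
        if set(self.type_proportions) - set(INTERACTION_TYPES):
            raise ConfigurationError("unknown interaction type in type_proportions")
        for name in ("n_baits", "n_preys", "n_complexes", "edges_per_bait",
                     "n_ip_replicates", "n_igg_replicates", "n_fractions",
                     "site_universe", "bridge_n_baits"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for t, rho in self.overlap_rho.items():
            if not 0.0 <= rho <= 1.0:
                raise ConfigurationError(f"overlap_rho[{t!r}] outside [0, 1]")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: proteins, typed edges, complexes, bridge node."""

    proteins: tuple[str, ...]
    baits: tuple[str, ...]
    preys: tuple[str, ...]
    bait_steps: Mapping[str, str]
    control_bait: str
    #: bait -> condition in which its IP is forced to fail QC
    undetermined_baits: Mapping[str, str]
    #: (bait, prey, type) triples; pairs are unique
    true_edges: tuple[tuple[str, str, str], ...]
    #: (member tuple, complex mass in kDa)
    complexes: tuple[tuple[tuple[str, ...], float], ...]
    monomer_masses: Mapping[str, float]
    planted_bridges: tuple[str, ...]

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.true_edges, columns=["bait", "prey", "ip_type"])


def _spread_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def make_truth(config: SimConfig) -> SyntheticTruth:
    """Draw a ground-truth network under ``config``.

    Edge types are drawn i.i.d. from ``type_proportions``; undetermined-type
    edges are attached to dedicated baits whose IP is later forced to fail QC
    in one RNase condition (that is the operational definition of the class).
    One prey is wired to baits of at least three distinct life-cycle steps as
    a planted multi-step "bridge". The negative-control bait carries a private
    five-member complex disconnected from the rest of the network.
    """
    rng = _spread_rng(config.seed, 0)
    baits = tuple(f"BAIT{i + 1:02d}" for i in range(config.n_baits))
    preys = tuple(f"PREY{i + 1:03d}" for i in range(config.n_preys))
    control = baits[-1]

    steps: dict[str, str] = {}
    for i, b in enumerate(baits[:-1]):
        steps[b] = LIFE_CYCLE_STEPS[i % len(LIFE_CYCLE_STEPS)]
    steps[control] = "replication"  # genome-replication negative control

    regular = [b for b in baits[:-1]]
    n_undet = max(1, round(config.type_proportions.get("undetermined", 0.0) * config.n_baits))
    n_undet = min(n_undet, len(regular) - 1)
    undet_baits = list(rng.choice(regular, size=n_undet, replace=False))
    undet_fail = {b: CONDITIONS[int(rng.integers(2))] for b in sorted(undet_baits)}
    enrichable = [b for b in regular if b not in undet_fail]

    # Control bait's private complex: 5 reserved preys, direct edges.
    reserved = list(preys[-5:])
    open_preys = list(preys[:-5])

    edges: dict[tuple[str, str], str] = {}
    for p in reserved:
        edges[(control, p)] = "direct"

    n_edges = config.edges_per_bait * (config.n_baits - 1)
    types = list(config.type_proportions)
    probs = np.array([config.type_proportions[t] for t in types])
    drawn = rng.choice(types, size=n_edges, p=probs)
    for t in drawn:
        pool = undet_baits if t == "undetermined" else enrichable
        for _ in range(50):  # retry to keep pairs unique
            b = pool[int(rng.integers(len(pool)))]
            p = open_preys[int(rng.integers(len(open_preys)))]
            if (b, p) not in edges:
                edges[(b, p)] = str(t)
                break

    # Planted connectors: preys wired by direct edges to several enrichable
    # baits spanning >= 3 distinct steps. The first (the "bridge") touches
    # the most baits and is the designated top-centrality node; the smaller
    # secondary connectors mirror the additional hub proteins real
    # interactomes contain.
    def plant_connector(n_baits_wired: int, taken: set[str]) -> str:
        node = open_preys[int(rng.integers(len(open_preys)))]
        while node in taken:
            node = open_preys[int(rng.integers(len(open_preys)))]
        k = min(n_baits_wired, len(enrichable))
        chosen: list[str] = []
        for b in rng.permutation(enrichable):
            if len(chosen) >= k and len({steps[x] for x in chosen}) >= 3:
                break
            chosen.append(str(b))
        for b in chosen:
            edges[(b, node)] = "direct"
        return node

    taken: set[str] = set()
    connectors: list[str] = []
    for wired in (config.bridge_n_baits,
                  max(3, config.bridge_n_baits - 3),
                  max(3, config.bridge_n_baits - 4)):
        node = plant_connector(wired, taken)
        taken.add(node)
        connectors.append(node)
    bridge = connectors[0]

    # SEC complexes: disjoint prey groups of size 3-6 plus the control complex.
    masses = {p: float(10 ** rng.normal(np.log10(50.0), 0.25)) for p in baits + preys}
    unassigned = [p for p in open_preys if p not in taken]
    rng.shuffle(unassigned)
    complexes: list[tuple[tuple[str, ...], float]] = []
    cursor = 0
    for _ in range(config.n_complexes):
        size = int(rng.integers(3, 7))
        if cursor + size > len(unassigned):
            break
        members = tuple(sorted(unassigned[cursor: cursor + size]))
        cursor += size
        complexes.append((members, float(sum(masses[m] for m in members))))
    control_members = tuple(sorted([control] + reserved))
    complexes.append((control_members, float(sum(masses[m] for m in control_members))))

    triples = tuple(sorted((b, p, t) for (b, p), t in edges.items()))
    return SyntheticTruth(
        proteins=baits + preys,
        baits=baits,
        preys=preys,
        bait_steps=steps,
        control_bait=control,
        undetermined_baits=undet_fail,
        true_edges=triples,
        complexes=tuple(complexes),
        monomer_masses=masses,
        planted_bridges=tuple(connectors),
    )


# ---------------------------------------------------------------------------
# TMT IP-MS simulation
# ---------------------------------------------------------------------------

def _mix_design(bait: str, config: SimConfig) -> pd.DataFrame:
    """Sample sheet rows for one TMT11 mix: spike-in, 3+3 IPs, 2+2 IgG."""
    mix = f"mix_{bait}"
    rows = [
        {"mix": mix, "channel": TMT11_CHANNELS[0], "bait": "", "condition": "na",
         "replicate": 1, "role": "spike_in"},
    ]
    ch = 1
    for cond in CONDITIONS:
        for r in range(config.n_ip_replicates):
            rows.append({"mix": mix, "channel": TMT11_CHANNELS[ch], "bait": bait,
                         "condition": cond, "replicate": r + 1, "role": "bait_ip"})
            ch += 1
    for cond in CONDITIONS:
        for r in range(config.n_igg_replicates):
            rows.append({"mix": mix, "channel": TMT11_CHANNELS[ch], "bait": "",
                         "condition": cond, "replicate": r + 1, "role": "igg"})
            ch += 1
    df = pd.DataFrame(rows)
    df.index = pd.Index(df["mix"] + ":" + df["channel"], name="sample")
    return df


def _complex_partners(truth: SyntheticTruth) -> dict[tuple[str, str], bool]:
    """Unordered pairs that co-reside in a planted complex."""
    out: dict[tuple[str, str], bool] = {}
    for members, _ in truth.complexes:
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                out[(min(a, b), max(a, b))] = True
    return out


def simulate_ip(truth: SyntheticTruth, config: SimConfig, *, noise: bool = True) -> IntensityTable:
    """Simulate raw TMT11 reporter intensities for every bait's mix.

    Background log2 intensities are normal(background_mu, background_sigma)
    per protein with replicate noise ``noise_sd``. Planted enrichment follows
    the RNA-dependency semantics: direct preys are enriched in both RNase
    conditions, mediated only without RNase, shielded only with RNase, and
    undetermined preys only in the condition where their bait's IP survives
    QC (the other condition's bait enrichment is suppressed so the IP fails).
    Preys sharing a planted complex with their bait are pulled down at the
    bait's own level (1:1 complex stoichiometry). The spike-in channel is the
    mean of all other channels (plus noise); IgG channels carry no planted
    signal. Intensities below ``dropout_threshold`` are censored to missing.
    """
    rng = _spread_rng(config.seed, 1)
    proteins = list(truth.proteins)
    baseline = pd.Series(
        rng.normal(config.background_mu, config.background_sigma, len(proteins)),
        index=proteins,
    )
    # Baits are selected proteins with IP-grade antibodies and detectable
    # expression; truncate their baselines to the expressed range so only the
    # designated undetermined baits can fail IP quality control.
    floor = config.background_mu - config.background_sigma
    for b in truth.baits:
        if baseline[b] < floor:
            baseline[b] = floor + (floor - baseline[b]) * 0.1
    # Connector preys bridging many baits are modeled as substoichiometric
    # partners: lower total abundance than their baits, so their prey/bait
    # intensity ratios sit below the rest of the network (batch-corrected
    # z-scores are baseline-free, so detectability is unaffected).
    for p in truth.planted_bridges:
        baseline[p] = config.background_mu - 2.5
    in_complex = _complex_partners(truth)
    # Preys in a complex with a bait share that bait's baseline level.
    for members, _ in truth.complexes:
        bait_members = [m for m in members if m in truth.baits]
        if bait_members:
            for m in members:
                baseline[m] = baseline[bait_members[0]]

    prey_enrich: dict[str, list[tuple[str, str, float]]] = {b: [] for b in truth.baits}
    for b, p, t in truth.true_edges:
        pair = (min(b, p), max(b, p))
        eff = config.bait_effect if in_complex.get(pair) else config.effect_size
        if t == "direct":
            conds = list(CONDITIONS)
        elif t == "mediated":
            conds = ["rnase_minus"]
        elif t == "shielded":
            conds = ["rnase_plus"]
        else:  # undetermined: enriched only where the bait IP survives
            failed = truth.undetermined_baits[b]
            conds = [c for c in CONDITIONS if c != failed]
        for c in conds:
            prey_enrich[b].append((p, c, eff))

    sheets = []
    columns: dict[str, np.ndarray] = {}
    top3_cols: dict[str, np.ndarray] = {}
    nsd = config.noise_sd if noise else 0.0
    for bait in truth.baits:
        sheet = _mix_design(bait, config)
        sheets.append(sheet)
        failed_cond = truth.undetermined_baits.get(bait)
        mix_cols: list[str] = []
        for sample, row in sheet.iterrows():
            if row["role"] == "spike_in":
                continue
            enrich = pd.Series(0.0, index=baseline.index)
            if row["role"] == "bait_ip":
                if row["condition"] != failed_cond:
                    enrich[bait] += config.bait_effect
                for p, c, eff in prey_enrich[bait]:
                    if c == row["condition"]:
                        enrich[p] += eff
            log2 = baseline + enrich
            if nsd:
                log2 = log2 + rng.normal(0.0, nsd, len(log2))
            columns[str(sample)] = np.power(2.0, log2.to_numpy())
            mix_cols.append(str(sample))
        spike_sample = sheet.index[sheet["role"] == "spike_in"][0]
        mean_other = np.mean([columns[c] for c in mix_cols], axis=0)
        if nsd:
            mean_other = mean_other * np.power(2.0, rng.normal(0.0, nsd, len(mean_other)))
        columns[str(spike_sample)] = mean_other
        # Top3 MS1 quantity per protein for the mix: total reporter signal
        # with a modest multiplicative error.
        total = np.sum([columns[c] for c in list(sheet.index)], axis=0)
        err = np.power(2.0, rng.normal(0.0, 0.2 if noise else 0.0, len(total)))
        top3_cols[f"mix_{bait}"] = total * err

    samples = pd.concat(sheets)
    values = pd.DataFrame(columns, index=baseline.index).loc[:, list(samples.index)]
    values = values.where(values >= config.dropout_threshold)
    top3 = pd.DataFrame(top3_cols, index=baseline.index)
    return IntensityTable(values=values, samples=samples, top3=top3)


# ---------------------------------------------------------------------------
# SEC simulation
# ---------------------------------------------------------------------------

def sec_calibration(config: SimConfig) -> pd.DataFrame:
    """Monotone fraction -> apparent mass (kDa) calibration, log-linear.

    Earlier fractions elute larger species: 5000 kDa at the first collected
    fraction falling to 10 kDa at the last.
    """
    fr = np.arange(config.first_fraction, config.first_fraction + config.n_fractions)
    hi, lo = np.log10(5000.0), np.log10(10.0)
    slope = (hi - lo) / (config.n_fractions - 1)
    mass = 10 ** (hi - slope * (fr - config.first_fraction))
    return pd.DataFrame({"fraction": fr, "mass_kda": mass})


def fraction_for_mass(mass_kda: float, calibration: pd.DataFrame) -> float:
    """Invert the calibration; masses outside its range clamp with a warning."""
    fr = calibration["fraction"].to_numpy(dtype=float)
    logm = np.log10(calibration["mass_kda"].to_numpy())
    x = np.log10(mass_kda)
    if x > logm[0] or x < logm[-1]:
        warnings.warn(
            f"mass {mass_kda:.1f} kDa outside calibration range; apex clamped",
            stacklevel=2,
        )
        x = min(max(x, logm[-1]), logm[0])
    # logm is strictly decreasing in fraction
    return float(np.interp(x, logm[::-1], fr[::-1]))


def simulate_sec(
    truth: SyntheticTruth,
    config: SimConfig,
    *,
    n_replicates: int = 3,
    noise: bool = True,
    with_complexes: bool = True,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate SEC fraction profiles (one matrix per replicate).

    Each protein elutes as a Gaussian monomer peak at the fraction implied by
    its monomer mass; members of a planted complex additionally share a
    Gaussian apex at the fraction implied by the summed complex mass.
    Replicate noise is multiplicative log-normal and independent.

    Returns (replicate matrices, calibration table).
    """
    rng = _spread_rng(config.seed, 2)
    calib = sec_calibration(config)
    fr = calib["fraction"].to_numpy(dtype=float)
    proteins = list(truth.proteins)

    lo, hi = config.monomer_sigma_range
    widths = {p: float(rng.uniform(lo, hi)) for p in proteins}
    amp_jitter = {p: float(2 ** rng.normal(0.0, 0.2)) for p in proteins}

    clean = np.zeros((len(proteins), len(fr)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamping warnings handled per-call
        mono_apex = {p: fraction_for_mass(truth.monomer_masses[p], calib) for p in proteins}
        cplx_apex = [
            (members, fraction_for_mass(mass, calib)) for members, mass in truth.complexes
        ]
    for i, p in enumerate(proteins):
        prof = config.monomer_amplitude * amp_jitter[p] * np.exp(
            -0.5 * ((fr - mono_apex[p]) / widths[p]) ** 2
        )
        clean[i] = prof
    if with_complexes:
        for members, apex in cplx_apex:
            shape = np.exp(-0.5 * ((fr - apex) / config.complex_peak_sigma) ** 2)
            for m in members:
                i = proteins.index(m)
                clean[i] = clean[i] + config.complex_amplitude * amp_jitter[m] * shape

    reps = []
    for _ in range(n_replicates):
        if noise:
            mat = clean * np.power(2.0, rng.normal(0.0, config.sec_noise_sd, clean.shape))
        else:
            mat = clean.copy()
        reps.append(pd.DataFrame(mat, index=proteins, columns=calib["fraction"].to_numpy()))
    return reps, calib


# ---------------------------------------------------------------------------
# Total proteome and binding sites
# ---------------------------------------------------------------------------

def simulate_total_proteome(
    truth: SyntheticTruth,
    config: SimConfig,
    *,
    n_replicates: int = 3,
    equal_complex_abundance: bool = True,
) -> pd.DataFrame:
    """Log-normal total-proteome abundances (protein x replicate, raw scale).

    With ``equal_complex_abundance`` members of a planted complex share one
    expected abundance, emulating 1:1 complex stoichiometry in the lysate.
    """
    rng = _spread_rng(config.seed, 3)
    base = pd.Series(
        rng.normal(config.background_mu, config.background_sigma, len(truth.proteins)),
        index=list(truth.proteins),
    )
    if equal_complex_abundance:
        for members, _ in truth.complexes:
            base[list(members)] = base[members[0]]
    cols = {}
    for r in range(n_replicates):
        noise = rng.normal(0.0, config.noise_sd, len(base))
        cols[f"rep{r + 1}"] = np.power(2.0, base.to_numpy() + noise)
    return pd.DataFrame(cols, index=base.index)


def simulate_binding_sites(
    truth: SyntheticTruth, config: SimConfig
) -> dict[str, set[int]]:
    """Per-protein binding-site window sets with type-dependent sharing.

    Each protein includes each of the ``site_universe`` windows independently
    at ``site_base_rate``; then, for every true edge, each private site of one
    partner is copied to the other with probability ``overlap_rho[type]``
    (symmetrically; rho = 1 makes the two sets identical).
    """
    rng = _spread_rng(config.seed, 4)
    n = config.site_universe
    sites: dict[str, set[int]] = {}
    for p in truth.proteins:
        mask = rng.random(n) < config.site_base_rate
        sites[p] = set(np.flatnonzero(mask).tolist())
    # rho = 1 means identical target repertoires; unify whole components of
    # such edges first so every fully-shared pair ends at Jaccard 1.
    parent: dict[str, str] = {p: p for p in truth.proteins}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for b, p, t in truth.true_edges:
        if config.overlap_rho.get(t, 0.0) >= 1.0:
            parent[find(b)] = find(p)
    comps: dict[str, set[int]] = {}
    for p in truth.proteins:
        comps.setdefault(find(p), set()).update(sites[p])
    for p in truth.proteins:
        sites[p] = set(comps[find(p)])
    for b, p, t in truth.true_edges:
        rho = config.overlap_rho.get(t, 0.0)
        if rho <= 0.0 or rho >= 1.0:
            continue
        a_only = sorted(sites[b] - sites[p])
        b_only = sorted(sites[p] - sites[b])
        take = rng.random(len(a_only)) < rho
        sites[p].update(s for s, keep in zip(a_only, take) if keep)
        take = rng.random(len(b_only)) < rho
        sites[b].update(s for s, keep in zip(b_only, take) if keep)
    return sites


def binding_sites_to_bed(sites: Mapping[str, set[int]], window: int = 100) -> dict[str, pd.DataFrame]:
    """Render window indices as 0-based half-open BED intervals on chrSim."""
    out = {}
    for protein, idx in sites.items():
        ordered = sorted(idx)
        out[protein] = pd.DataFrame(
            {
                "chrom": "chrSim",
                "start": [i * window for i in ordered],
                "end": [i * window + window for i in ordered],
                "name": [f"{protein}_w{i}" for i in ordered],
                "score": 0,
                "strand": "+",
            }
        )
    return out
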