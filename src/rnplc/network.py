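"""Assembly, annotation and export of the combined IP + SEC interactome.

Edges are unordered protein pairs. IP-MS edges carry an RNA-dependency type
(direct / mediated / shielded / undetermined) and the bait(s) that reported
them; SEC-MS co-elution edges carry support only. Merging collapses pairs
found by both into single dual-support records. Reference PPI resources
(e.g. a CORUM-style pair list) and subcellular localization tables annotate
each edge; interaction stoichiometry is the log2 prey/bait intensity ratio
in the bait's IP, computed from un-normalized intensities, with a matching
ratio from the total proteome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import networkx as nx

from .tmt import IntensityTable

TYPE_PRECEDENCE = ("direct", "mediated", "shielded", "undetermined")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class Network:
    """Edge table + node annotations, convertible to networkx."""

    edges: pd.DataFrame
    nodes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["protein_a"], self.edges["protein_b"]))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for _, row in self.nodes.iterrows():
            g.add_node(row.name, **{k: v for k, v in row.items() if pd.notna(v)})
        for _, row in self.edges.iterrows():
            attrs = {
                k: v for k, v in row.items()
                if k not in ("protein_a", "protein_b") and pd.notna(v)
            }
            g.add_edge(row["protein_a"], row["protein_b"], **attrs)
        return g


def build_ip_network(typed_edges: pd.DataFrame) -> Network:
    """Deduplicate typed bait-prey edges into an unordered-pair network.

    When two baits report the same pair with different RNA-dependency
    classes, the pair keeps the strongest claim (direct > mediated >
    shielded > undetermined) and is flagged as conflicting; all source
    baits are retained. Self edges are dropped with a warning.
    """
    records: dict[tuple[str, str], dict] = {}
    for _, row in typed_edges.iterrows():
        if row["bait"] == row["prey"]:
            warnings.warn(f"dropping self edge {row['bait']!r}", stacklevel=2)
            continue
        pair = canonical_pair(row["bait"], row["prey"])
        rec = records.setdefault(
            pair,
            {"types": [], "source_baits": []},
        )
        rec["types"].append(row["ip_type"])
        rec["source_baits"].append(row["bait"])
    rows = []
    for (a, b), rec in sorted(records.items()):
        types = rec["types"]
        best = min(types, key=TYPE_PRECEDENCE.index)
        rows.append(
            {
                "protein_a": a,
                "protein_b": b,
                "ip_type": best,
                "type_conflict": len(set(types)) > 1,
                "source_baits": ";".join(sorted(set(rec["source_baits"]))),
                "sec_support": False,
                "ip_support": True,
            }
        )
    edges = pd.DataFrame(
        rows,
        columns=["protein_a", "protein_b", "ip_type", "type_conflict",
                 "source_baits", "sec_support", "ip_support"],
    )
    node_ids = sorted(set(edges["protein_a"]) | set(edges["protein_b"]))
    baits = set(typed_edges["bait"])
    nodes = pd.DataFrame({"is_bait": [n in baits for n in node_ids]}, index=node_ids)
    return Network(edges=edges, nodes=nodes)


def merge_ip_sec(ip_net: Network, sec_pairs: Iterable[tuple[str, str]]) -> Network:
    """Union of the IP edge set with SEC co-elution pairs.

    Pairs found by both become single dual-support edges, so
    |merged| = |IP| + |SEC| - |overlap| holds exactly.
    """
    edges = ip_net.edges.copy()
    known = {canonical_pair(a, b): i for i, (a, b) in
             enumerate(zip(edges["protein_a"], edges["protein_b"]))}
    sec_canon = {canonical_pair(a, b) for a, b in sec_pairs}
    edges["sec_support"] = [
        canonical_pair(a, b) in sec_canon
        for a, b in zip(edges["protein_a"], edges["protein_b"])
    ]
    new_rows = []
    for a, b in sorted(sec_canon - set(known)):
        new_rows.append(
            {"protein_a": a, "protein_b": b, "ip_type": None, "type_conflict": False,
             "source_baits": "", "sec_support": True, "ip_support": False}
        )
    if new_rows:
        edges = pd.concat([edges, pd.DataFrame(new_rows)], ignore_index=True)
    node_ids = sorted(set(edges["protein_a"]) | set(edges["protein_b"]))
    nodes = ip_net.nodes.reindex(node_ids)
    nodes["is_bait"] = [bool(x) if pd.notna(x) else False for x in nodes["is_bait"]]
    return Network(edges=edges.reset_index(drop=True), nodes=nodes)


def colocalization_class(
    loc_a: set[str] | None, loc_b: set[str] | None
) -> str:
    """full / partial / none overlap of two localization sets; unknown if
    either protein is unannotated."""
    if not loc_a or not loc_b:
        return "unknown"
    if loc_a == loc_b:
        return "full"
    if loc_a & loc_b:
        return "partial"
    return "none"


def annotate_reference_support(
    net: Network,
    references: Mapping[str, Iterable[tuple[str, str]]],
    localization: Mapping[str, set[str]] | None = None,
) -> Network:
    """Add per-resource support flags and a colocalization class per edge."""
    edges = net.edges.copy()
    for name, pairs in references.items():
        canon = {canonical_pair(a, b) for a, b in pairs}
        edges[f"in_{name}"] = [
            canonical_pair(a, b) in canon
            for a, b in zip(edges["protein_a"], edges["protein_b"])
        ]
    if localization is not None:
        edges["colocalization"] = [
            colocalization_class(localization.get(a), localization.get(b))
            for a, b in zip(edges["protein_a"], edges["protein_b"])
        ]
    return Network(edges=edges, nodes=net.nodes)


def _log2_averaged(values: pd.DataFrame) -> pd.Series:
    """log2(x + 1) then mean over replicate columns (the paper's recipe for
    un-normalized stoichiometry inputs)."""
    return np.log2(values + 1.0).mean(axis=1, skipna=True)


def interaction_stoichiometry(
    typed_edges: pd.DataFrame,
    raw_ip: IntensityTable,
    total_proteome: pd.DataFrame,
) -> pd.DataFrame:
    """Per (bait, prey) stoichiometry records.

    ``stoichiometry_ip`` = mean log2(prey + 1) - mean log2(bait + 1) over the
    bait's IP replicate channels; ``stoichiometry_abundance`` is the same
    contrast in the replicate-averaged total proteome. Unmeasured proteins
    yield missing values, recorded rather than dropped.
    """
    log_total = _log2_averaged(total_proteome)
    rows = []
    for (bait, prey), sub in typed_edges.groupby(["bait", "prey"], sort=True):
        ip_cols = raw_ip.sample_ids(bait=bait, role="bait_ip")
        if bait in raw_ip.values.index and prey in raw_ip.values.index and ip_cols:
            lb = float(np.log2(raw_ip.values.loc[bait, ip_cols] + 1.0).mean(skipna=True))
            lp = float(np.log2(raw_ip.values.loc[prey, ip_cols] + 1.0).mean(skipna=True))
            st_ip = lp - lb
        else:
            st_ip = np.nan
        if bait in log_total.index and prey in log_total.index:
            st_ab = float(log_total[prey] - log_total[bait])
        else:
            st_ab = np.nan
        rows.append(
            {"bait": bait, "prey": prey, "ip_type": sub["ip_type"].iloc[0],
             "stoichiometry_ip": st_ip, "stoichiometry_abundance": st_ab}
        )
    return pd.DataFrame(rows)


def node_degrees(net: Network) -> pd.Series:
    both = pd.concat([net.edges["protein_a"], net.edges["protein_b"]])
    return both.value_counts()


def export_network(net: Network, path: str, fmt: str = "tsv") -> None:
    """Write the network as edge-list TSV, SIF or GraphML."""
    if fmt == "tsv":
        net.edges.to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for _, row in net.edges.iterrows():
                rel = row["ip_type"] if pd.notna(row["ip_type"]) and row["ip_type"] else "sec"
                fh.write(f"{row['protein_a']}\t{rel}\t{row['protein_b']}\n")
    elif fmt == "graphml":
        g = net.to_networkx()
        # GraphML cannot carry None attribute values
        for _, _, attrs in g.edges(data=True):
            for k, v in list(attrs.items()):
                if v is None:
                    attrs[k] = ""
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network(path: str, fmt: str = "tsv") -> Network:
    if fmt == "tsv":
        edges = pd.read_csv(path, sep="\t")
        node_ids = sorted(set(edges["protein_a"]) | set(edges["protein_b"]))
        return Network(edges=edges, nodes=pd.DataFrame(index=node_ids))
    if fmt == "graphml":
        g = nx.read_graphml(path)
        rows = []
        for a, b, attrs in g.edges(data=True):
            x, y = canonical_pair(str(a), str(b))
            rows.append({"protein_a": x, "protein_b": y, **attrs})
        edges = pd.DataFrame(rows).sort_values(["protein_a", "protein_b"]).reset_index(drop=True)
        nodes = pd.DataFrame(index=sorted(g.nodes()))
        return Network(edges=edges, nodes=nodes)
    raise ValueError(f"unknown import format {fmt!r}")
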