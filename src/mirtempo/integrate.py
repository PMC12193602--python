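"""Integration of temporal DEMs with mRNA DEGs through validated target pairs.

A gene enters the integrated record set when it (i) is significant in the
mRNA table (FDR <= 0.05), (ii) shows a substantial temporal change between
3 h and 8 h (|log2FC| >= 1; the boundary is inclusive because reported fold
changes are typically rounded), (iii) is expressed at >= 10 CPM, and (iv) has
at least one experimentally validated pairing to a T-DEM. One record
aggregates all of a gene's T-DEM partners with their early/late phases; the
record is flagged when any partner miRNA is abundant (average CPM > 200).

The records induce a bipartite miRNA-gene network whose maximum-degree miRNA
is the hub, and gene sets (GMT) can be scored by one-sided hypergeometric
overrepresentation with BH correction across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_adjust

__all__ = [
    "IntegrationRecord",
    "integrate_targets",
    "records_to_frame",
    "build_network",
    "hypergeom_enrich",
    "read_gmt",
    "ABUNDANT_CPM",
]

ABUNDANT_CPM = 200.0


@dataclass
class IntegrationRecord:
    """One target gene with its T-DEM partners (a row of the integrated table)."""

    gene_id: str
    gene_name: str
    mirnas: list[tuple[str, str]]  # (mirna_id, phase in {early, late})
    gene_fdr: float
    gene_avg_cpm: float
    fc_3h_to_8h: float  # linear fold change between the time points
    fc_8h_vs_nt: float  # linear fold change at 8 h vs untreated
    abundant_mirna: bool = False
    abundant_partners: list[str] = field(default_factory=list)


def _tdem_mean_cpm(tdems: pd.DataFrame, prior_cpm: float = 0.5) -> pd.Series:
    cpm = 2.0 ** tdems["avg_log2cpm"] - prior_cpm
    return cpm.clip(lower=0.0)


def integrate_targets(
    tdems: pd.DataFrame,
    deg_table: pd.DataFrame,
    pairs: pd.DataFrame,
    min_gene_cpm: float = 10.0,
    min_abs_tdeg_log2fc: float = 1.0,
    gene_fdr: float = 0.05,
    mirna_cpm: pd.Series | None = None,
    abundant_cpm: float = ABUNDANT_CPM,
) -> list[IntegrationRecord]:
    """Merge T-DEMs, the mRNA DEG table and validated pairs into records.

    ``tdems`` is the frame from :func:`mirtempo.temporal.call_tdems` (indexed
    by miRNA id with ``phase`` and ``avg_log2cpm``); ``deg_table`` needs
    columns gene_id, gene_name, log2fc_3h_to_8h, log2fc_8h_vs_nt, fdr,
    avg_cpm; ``pairs`` needs mirna_id / gene_id. ``mirna_cpm`` overrides the
    miRNA abundances used for the abundant flag (defaults to the T-DEM
    average CPM). Pairs naming unknown genes are skipped with a warning.
    """
    if tdems.empty:
        return []
    if mirna_cpm is None:
        mirna_cpm = _tdem_mean_cpm(tdems)
    genes = deg_table.set_index("gene_id")
    phase = tdems["phase"]
    records: list[IntegrationRecord] = []
    relevant = pairs[pairs["mirna_id"].isin(tdems.index)]
    unknown = sorted(set(relevant["gene_id"]) - set(genes.index))
    if unknown:
        warnings.warn(
            f"skipping {len(unknown)} pair(s) referencing unknown genes: {unknown[:5]}"
        )
    for gene_id, grp in relevant.groupby("gene_id", sort=True):
        if gene_id not in genes.index:
            continue
        row = genes.loc[gene_id]
        if row["fdr"] > gene_fdr:
            continue
        if abs(row["log2fc_3h_to_8h"]) < min_abs_tdeg_log2fc:
            continue
        if row["avg_cpm"] < min_gene_cpm:
            continue
        partners = sorted(set(grp["mirna_id"]))
        abundant = [m for m in partners if float(mirna_cpm.get(m, 0.0)) > abundant_cpm]
        records.append(
            IntegrationRecord(
                gene_id=str(gene_id),
                gene_name=str(row.get("gene_name", gene_id)),
                mirnas=[(m, str(phase.loc[m])) for m in partners],
                gene_fdr=float(row["fdr"]),
                gene_avg_cpm=float(row["avg_cpm"]),
                fc_3h_to_8h=2.0 ** float(row["log2fc_3h_to_8h"]),
                fc_8h_vs_nt=2.0 ** float(row["log2fc_8h_vs_nt"]),
                abundant_mirna=bool(abundant),
                abundant_partners=abundant,
            )
        )
    return records


def records_to_frame(records: list[IntegrationRecord]) -> pd.DataFrame:
    """Flat table of the integrated records (one row per gene)."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "gene_name": [r.gene_name for r in records],
            "mirnas": [";".join(f"{m}({p})" for m, p in r.mirnas) for r in records],
            "gene_fdr": [r.gene_fdr for r in records],
            "gene_avg_cpm": [r.gene_avg_cpm for r in records],
            "fc_3h_to_8h": [r.fc_3h_to_8h for r in records],
            "fc_8h_vs_nt": [r.fc_8h_vs_nt for r in records],
            "abundant_mirna": [r.abundant_mirna for r in records],
        }
    )


def build_network(
    records: list[IntegrationRecord],
) -> tuple[nx.Graph, pd.DataFrame, list[str]]:
    """Bipartite miRNA-gene graph, per-node degrees and the hub miRNA(s).

    Returns ``(graph, degree_table, hubs)``; ``hubs`` lists every miRNA at
    the maximum degree (usually one).
    """
    graph = nx.Graph()
    for rec in records:
        graph.add_node(rec.gene_id, bipartite="gene")
        for mirna, phase in rec.mirnas:
            graph.add_node(mirna, bipartite="mirna")
            graph.add_edge(mirna, rec.gene_id, phase=phase)
    rows = [
        {"node": n, "kind": graph.nodes[n]["bipartite"], "degree": d}
        for n, d in graph.degree()
    ]
    degrees = pd.DataFrame(rows, columns=["node", "kind", "degree"])
    mirna_deg = degrees[degrees["kind"] == "mirna"]
    hubs: list[str] = []
    if not mirna_deg.empty:
        top = mirna_deg["degree"].max()
        hubs = sorted(mirna_deg.loc[mirna_deg["degree"] == top, "node"])
    return graph, degrees, hubs


def hypergeom_enrich(
    query_genes,
    gene_sets: dict[str, set],
    universe,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of ``query_genes`` per set.

    ``p = P[X >= k]`` for overlap k, set size K, query size n, universe size
    N; BH-adjusted across sets. Query genes must belong to the universe; set
    members outside the universe are ignored.
    """
    universe = set(universe)
    query = set(query_genes)
    outside = query - universe
    if outside:
        raise ValueError(f"query genes outside the universe: {sorted(outside)[:5]}")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe
        k = len(members & query)
        big_k = len(members)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_query)) if k > 0 else 1.0
        rows.append(
            {
                "set_id": set_id,
                "overlap": k,
                "set_size": big_k,
                "query_size": n_query,
                "universe_size": n_universe,
                "pvalue": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "set_id", "overlap", "set_size", "query_size", "universe_size", "pvalue",
        ],
    )
    if not result.empty:
        result["qvalue"] = bh_adjust(result["pvalue"].to_numpy())
    else:
        result["qvalue"] = []
    return result


def read_gmt(path) -> dict[str, set]:
    """Read gene sets from a GMT file (set name, description, members...)."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
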