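"""Packaged reference data: validated T-DEM targets in activated microglia.

The tables describe 21 protein-coding genes differentially expressed between
3 h and 8 h after bzATP/LPS activation of primary murine microglia, each with
at least one experimentally validated pairing to a temporally regulated miRNA
(T-DEM). Reported statistics are the gene-level FDR, average CPM and the
linear fold changes between the time points and versus untreated culture;
each paired miRNA carries its temporal phase (early = maximal at 3 h, late =
maximal at 8 h) and whether it is abundant (average CPM > 200).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .integrate import IntegrationRecord

__all__ = [
    "load_target_genes",
    "load_target_pairs",
    "load_integration_records",
    "fixture_inputs",
]

# Average CPM of the abundant miRNAs where reported; the remaining entries are
# SYNTHETIC nominal stand-ins consistent only with the abundant/not-abundant
# flag (>200 or <200 CPM) and are used for nothing else.
MIRNA_AVG_CPM = {
    "miR-7a-5p": 16738.0,
    "miR-146a-5p": 11147.0,
    "miR-155-5p": 1000.0,  # synthetic stand-in, abundant
    "miR-155-3p": 50.0,  # synthetic stand-in
    "miR-146b-5p": 50.0,  # synthetic stand-in
    "miR-365-3p": 50.0,  # synthetic stand-in
    "miR-132-5p": 50.0,  # synthetic stand-in
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("mirtempo.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_target_genes() -> pd.DataFrame:
    """Gene-level statistics of the 21 validated target genes."""
    return _read("microglia_tdem_target_genes.tsv")


def load_target_pairs() -> pd.DataFrame:
    """The 23 validated miRNA-gene pairings with phase and abundance flags."""
    return _read("microglia_tdem_target_pairs.tsv")


def load_integration_records() -> list[IntegrationRecord]:
    """The packaged reference table as integration records (one per gene)."""
    genes = load_target_genes()
    pairs = load_target_pairs()
    records = []
    for _, row in genes.iterrows():
        sub = pairs[pairs["gene_id"] == row["gene_id"]]
        partners = [(m, p) for m, p in zip(sub["mirna_id"], sub["phase"])]
        abundant = sorted(sub.loc[sub["mirna_abundant"] == 1, "mirna_id"])
        records.append(
            IntegrationRecord(
                gene_id=row["gene_id"],
                gene_name=row["gene_name"],
                mirnas=sorted(partners),
                gene_fdr=float(row["fdr"]),
                gene_avg_cpm=float(row["avg_cpm"]),
                fc_3h_to_8h=float(row["fc_3h_to_8h"]),
                fc_8h_vs_nt=float(row["fc_8h_vs_nt"]),
                abundant_mirna=bool(abundant),
                abundant_partners=abundant,
            )
        )
    return records


def fixture_inputs() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Reference tables reshaped into ``integrate_targets`` inputs.

    Returns ``(tdems, deg_table, pairs, mirna_cpm)``: a T-DEM frame indexed by
    miRNA with phase and average log2-CPM, a DEG table of the 21 genes (log2
    fold changes derived from the printed linear FCs), the bare pair list and
    the per-miRNA CPM series used by the abundant flag.
    """
    genes = load_target_genes()
    pairs = load_target_pairs()
    mirna_cpm = pd.Series(MIRNA_AVG_CPM)
    phase = pairs.drop_duplicates("mirna_id").set_index("mirna_id")["phase"]
    tdems = pd.DataFrame(
        {
            "log2fc": np.where(phase == "early", -0.6, 0.6),  # sign only
            "avg_log2cpm": np.log2(mirna_cpm.reindex(phase.index) + 0.5),
            "qvalue": 0.01,
            "phase": phase,
        },
        index=phase.index,
    )
    deg_table = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "gene_name": genes["gene_name"],
            "log2fc_3h_to_8h": np.log2(genes["fc_3h_to_8h"]),
            "log2fc_8h_vs_nt": np.log2(genes["fc_8h_vs_nt"]),
            "fdr": genes["fdr"],
            "avg_cpm": genes["avg_cpm"],
        }
    )
    return tdems, deg_table, pairs[["mirna_id", "gene_id"]].copy(), mirna_cpm
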