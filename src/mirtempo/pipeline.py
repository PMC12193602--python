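"""End-to-end orchestration: filter -> TMM -> DE -> trends -> T-DEMs -> integration.

A run is driven by a :class:`PipelineConfig` that either points at input
tables (counts, design, DEG table, validated pairs, optional GMT gene sets)
or carries a simulation block; every stage writes its artifact as TSV under
the output directory and a machine-readable ``report.json`` collects the
thresholds, per-stage feature counts and -- when ground truth exists --
recovery metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, integrate, prep, simulate, temporal, trends

__all__ = ["PipelineConfig", "Thresholds", "run_pipeline"]

log = logging.getLogger("mirtempo")


@dataclass
class Thresholds:
    fdr: float = 0.05
    trend_log2fc: float = 0.33
    dem_log2fc: float = 0.33
    gene_min_cpm: float = 10.0
    tdeg_log2fc: float = 1.0
    abundant_cpm: float = 200.0

    def __post_init__(self):
        for name, value in asdict(self).items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")


@dataclass
class PipelineConfig:
    outdir: str = "mirtempo_out"
    seed: int = 0
    sim: simulate.SimConfig | None = None
    counts_path: str | None = None
    design_path: str | None = None
    deg_table_path: str | None = None
    pairs_path: str | None = None
    gene_sets_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    min_cpm: float = 4.0
    min_samples: int = 3

    def __post_init__(self):
        if self.sim is None and (self.counts_path is None or self.design_path is None):
            raise ValueError("config needs either a simulation block or counts + design paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = None
        if "simulate" in raw:
            block = dict(raw["simulate"] or {})
            drug = block.pop("drug_arm", False)
            sim = simulate.SimConfig(**block, seed=int(raw.get("seed", 0)))
            if drug:
                sim = sim.with_drug_arm()
        inputs = raw.get("inputs", {}) or {}
        thresholds = Thresholds(**(raw.get("thresholds", {}) or {}))
        filt = raw.get("filter", {}) or {}
        return cls(
            outdir=raw.get("outdir", "mirtempo_out"),
            seed=int(raw.get("seed", 0)),
            sim=sim,
            counts_path=inputs.get("counts"),
            design_path=inputs.get("design"),
            deg_table_path=inputs.get("deg_table"),
            pairs_path=inputs.get("pairs"),
            gene_sets_path=inputs.get("gene_sets"),
            thresholds=thresholds,
            min_cpm=float(filt.get("min_cpm", 4.0)),
            min_samples=int(filt.get("min_samples", 3)),
        )


def _contrast_groups(design: pd.DataFrame) -> dict[str, tuple[list[str], list[str]]]:
    """The fixed contrast set: each time point vs untreated, 8 h vs 3 h, and
    the same comparisons for the drug arm when present."""

    def grp(cond, tp):
        return list(design.index[(design["condition"] == cond) & (design["timepoint"] == tp)])

    nt = list(design.index[design["condition"] == "NT"])
    contrasts: dict[str, tuple[list[str], list[str]]] = {}
    a3, a8 = grp("activated", 3), grp("activated", 8)
    if nt and a3:
        contrasts["3h_vs_NT"] = (nt, a3)
    if nt and a8:
        contrasts["8h_vs_NT"] = (nt, a8)
    if a3 and a8:
        contrasts["8h_vs_3h"] = (a3, a8)
    d3, d8 = grp("activated_drug", 3), grp("activated_drug", 8)
    if nt and d3:
        contrasts["drug_3h_vs_NT"] = (nt, d3)
    if nt and d8:
        contrasts["drug_8h_vs_NT"] = (nt, d8)
    if d3 and d8:
        contrasts["drug_8h_vs_3h"] = (d3, d8)
    return contrasts


def _recovery_metrics(
    truth: pd.DataFrame,
    de_tables: dict[str, pd.DataFrame],
    modules: pd.DataFrame,
    tdems: pd.DataFrame,
    thr: Thresholds,
) -> dict:
    """Ground-truth comparison: DEM sensitivity/FDP, module accuracy, T-DEM recovery."""
    out: dict = {}
    truth = truth.reindex(modules.index)
    if "3h_vs_NT" in de_tables:
        calls = diffexp.call_dems(de_tables["3h_vs_NT"], thr.fdr, thr.dem_log2fc)
        true_dem = truth.index[truth["log2fc_3h_vs_nt"] != 0]
        called = calls.index
        tp = len(set(called) & set(true_dem))
        out["dem_3h"] = {
            "sensitivity": tp / max(len(true_dem), 1),
            "fdp": (len(called) - tp) / max(len(called), 1),
            "n_called": int(len(called)),
        }
    spiked = truth.index[truth["module"] != "same-same"]
    agree = (modules["module"].reindex(truth.index) == truth["module"])
    out["module_accuracy_all"] = float(agree.mean())
    out["module_accuracy_spiked"] = float(agree.loc[spiked].mean()) if len(spiked) else 1.0
    true_temporal = truth.index[truth["log2fc_8h_vs_3h"] != 0]
    correct_phase = 0
    for f in true_temporal:
        if f in tdems.index:
            want = "late" if truth.loc[f, "log2fc_8h_vs_3h"] > 0 else "early"
            correct_phase += int(tdems.loc[f, "phase"] == want)
    out["tdem_truth"] = int(len(true_temporal))
    out["tdem_recovered_correct_phase"] = int(correct_phase)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report dict (also written as report.json)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    report: dict = {"seed": config.seed, "thresholds": asdict(thr)}

    truth = None
    deg_table = None
    pairs = None
    if config.sim is not None:
        sim_cfg = config.sim
        counts, design, truth = simulate.simulate_experiment(sim_cfg)
        prep.write_count_table(counts, outdir / "counts.tsv")
        design.to_csv(outdir / "design.tsv", sep="\t")
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t")
        deg_table = simulate.simulate_deg_table(
            simulate.DegTableConfig(), seed=sim_cfg.seed + 1
        )
        pairs = simulate.make_target_pairs(truth, deg_table, seed=sim_cfg.seed + 2)
        deg_table.to_csv(outdir / "deg_table.tsv", sep="\t", index=False)
        pairs.to_csv(outdir / "target_pairs.tsv", sep="\t", index=False)
    else:
        counts = prep.read_count_table(config.counts_path)
        design = prep.read_design_table(config.design_path)
        if config.deg_table_path:
            deg_table = pd.read_csv(config.deg_table_path, sep="\t")
        if config.pairs_path:
            pairs = pd.read_csv(config.pairs_path, sep="\t")
    if set(counts.columns) != set(design.index):
        raise ValueError("sample ids differ between counts and design")
    design = design.loc[counts.columns]
    report["n_features_input"] = int(counts.shape[0])
    report["n_samples"] = int(counts.shape[1])

    filtered = prep.filter_low_expression(counts, config.min_cpm, config.min_samples)
    log.info("filter: %d of %d features retained", filtered.shape[0], counts.shape[0])
    report["n_features_filtered"] = int(filtered.shape[0])
    prep.write_count_table(filtered, outdir / "filtered_counts.tsv")

    factors = prep.tmm_factors(filtered)
    factors.to_frame().to_csv(outdir / "norm_factors.tsv", sep="\t")
    cpm = prep.compute_cpm(filtered, factors)
    cpm.to_csv(outdir / "cpm.tsv", sep="\t", index_label="feature_id")
    scores, var_frac = prep.pca_qc(cpm, design)
    scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="sample_id")
    report["pca_variance_fractions"] = [float(v) for v in var_frac]

    groups = [
        list(idx)
        for _, idx in design.groupby(["condition", "timepoint"]).groups.items()
        if len(idx) >= 2
    ]
    dispersion = diffexp.estimate_common_dispersion(filtered, groups, factors)
    log.info("common dispersion: %.4g", dispersion.common)
    report["common_dispersion"] = float(dispersion.common)

    contrasts = _contrast_groups(design)
    for needed in ("3h_vs_NT", "8h_vs_3h"):
        if needed not in contrasts:
            raise ValueError(
                f"design lacks the samples for the {needed} contrast "
                "(untreated plus activated 3 h and 8 h groups are required)"
            )
    de_tables: dict[str, pd.DataFrame] = {}
    for name, (ga, gb) in contrasts.items():
        de = diffexp.nb_exact_test(filtered, ga, gb, dispersion, factors)
        calls = diffexp.call_dems(de, thr.fdr, thr.dem_log2fc)
        de["dem"] = de.index.isin(calls.index)
        de["direction"] = np.where(de["log2fc"] > 0, "up", "down")
        de.to_csv(outdir / f"de_{name}.tsv", sep="\t", index_label="feature_id")
        de_tables[name] = de
        log.info("contrast %s: %d DEMs of %d features", name, len(calls), len(de))
        report[f"n_dems_{name}"] = int(len(calls))

    modules = trends.classify_modules(
        de_tables["3h_vs_NT"]["log2fc"],
        de_tables["8h_vs_3h"]["log2fc"],
        thr.trend_log2fc,
    )
    modules.to_csv(outdir / "modules.tsv", sep="\t", index_label="feature_id")
    summary = trends.summarize_modules(modules)
    summary.to_csv(outdir / "module_summary.tsv", sep="\t", index_label="module")
    report["module_counts"] = {m: int(c) for m, c in summary["count"].items()}
    profile = trends.abundance_profile(cpm.mean(axis=1))
    profile.to_csv(outdir / "abundance_profile.tsv", sep="\t", index_label="cpm_bin")

    tdems = temporal.call_tdems(de_tables["8h_vs_3h"], thr.fdr, thr.dem_log2fc)
    tdems.to_csv(outdir / "tdems.tsv", sep="\t", index_label="feature_id")
    temporal.ma_table(de_tables["8h_vs_3h"], tdems).to_csv(
        outdir / "ma_8h_vs_3h.tsv", sep="\t", index_label="feature_id"
    )
    report["n_tdems"] = int(len(tdems))
    report["n_tdems_early"] = int((tdems["phase"] == "early").sum())
    report["n_tdems_late"] = int((tdems["phase"] == "late").sum())

    if deg_table is not None and pairs is not None and not tdems.empty:
        records = integrate.integrate_targets(
            tdems,
            deg_table,
            pairs,
            min_gene_cpm=thr.gene_min_cpm,
            min_abs_tdeg_log2fc=thr.tdeg_log2fc,
            gene_fdr=thr.fdr,
            abundant_cpm=thr.abundant_cpm,
        )
        integrate.records_to_frame(records).to_csv(
            outdir / "integration_records.tsv", sep="\t", index=False
        )
        graph, degrees, hubs = integrate.build_network(records)
        degrees.to_csv(outdir / "node_degrees.tsv", sep="\t", index=False)
        edges = pd.DataFrame(
            [(u, v) for u, v in graph.edges()], columns=["mirna_or_gene", "gene_or_mirna"]
        )
        edges.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        report["n_integration_records"] = int(len(records))
        report["n_network_edges"] = int(graph.number_of_edges())
        report["hub_mirnas"] = hubs
        if config.gene_sets_path:
            gene_sets = integrate.read_gmt(config.gene_sets_path)
            universe = list(deg_table["gene_id"])
            query = [r.gene_id for r in records]
            enrich = integrate.hypergeom_enrich(query, gene_sets, universe)
            enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            report["n_enriched_sets_q05"] = int((enrich["qvalue"] <= 0.05).sum())

    if truth is not None:
        truth_f = truth.loc[truth.index.isin(filtered.index)]
        report["recovery"] = _recovery_metrics(truth_f, de_tables, modules, tdems, thr)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
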