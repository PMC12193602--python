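# mirtempo

Temporal miRNA-seq analysis of activated microglia: a tested, reusable
implementation of the count-based pipeline used to profile microRNA dynamics
in primary murine microglial cultures stimulated with bzATP/LPS, sampled at
3 h and 8 h post-activation (optionally with a drug arm).

It is written for computational biologists who start from a miRNA count
matrix (features × samples) plus a sample design table, and want the full
chain: expression filtering, TMM normalization, exact-test differential
expression, temporal trend classification, temporal-DEM calling, and
integration with mRNA differential-expression results through experimentally
validated miRNA–target pairs. A synthetic-data module generates count data
with known ground truth so every stage is exercisable and testable without
any download.

## The statistics

Counts are modeled as negative binomial: for feature *f* in sample *s*,

    y_fs ~ NB(mu_fs, phi),   mu_fs = N_s * c_f / 1e6,   Var = mu + phi * mu^2

where `N_s` is the effective library size (raw depth × TMM factor), `c_f`
the concentration in CPM, and `phi` the dispersion (squared biological
coefficient of variation). The pipeline:

1. **Filter** — keep features with CPM > 4 in ≥ 3 samples (library-size CPM).
2. **TMM** — per-sample factors from the precision-weighted, doubly trimmed
   (30% on M, 5% on A) mean of log2 count-fraction ratios against a
   reference sample; factors rescaled to geometric mean 1.
3. **Dispersion** — common `phi` by conditional maximum likelihood on
   library-equalized pseudo-counts (grid + golden-section refinement).
4. **Exact test** — per feature, conditional on the total pseudo-count of
   two groups, the group split follows a beta-binomial law with shapes
   `n_A/phi` and `n_B/phi`; the two-sided p-value sums all splits no more
   probable than the observed one. Benjamini–Hochberg across features.
   A DEM requires `q ≤ 0.05` and `|log2FC| > 0.33`.
5. **Trend modules** — each feature gets a label (`up`/`same`/`down`, with
   `same` meaning `|log2FC| ≤ 0.33`) at 3 h vs untreated and at 8 h vs 3 h;
   the pair maps to one of nine modules (`up-up`, `up-down` = transient
   wave, `same-up` = delayed response, …).
6. **T-DEMs** — significant features in the direct 8 h-vs-3 h contrast among
   activated samples; phase `early` (maximal at 3 h, log2FC < 0) or `late`.
7. **Integration** — genes from an mRNA DEG table that are significant
   (FDR ≤ 0.05), substantially changed between the time points
   (|log2FC| ≥ 1), expressed (≥ 10 CPM), and validated targets of a T-DEM;
   one record per gene with its miRNA partners and phases, an abundant-miRNA
   flag (partner CPM > 200), a bipartite miRNA–gene network with hub
   statistics, and one-sided hypergeometric gene-set overrepresentation.

## Worked example

The package ships a curated reference table of 21 validated miRNA–target
genes from bzATP/LPS-activated microglia:

```python
from mirtempo import datasets
from mirtempo.integrate import build_network

records = datasets.load_integration_records()
graph, degrees, hubs = build_network(records)
mir155 = {r.gene_id for r in records
          if any(m.startswith("miR-155") for m, _ in r.mirnas)}
print(len(records), len(mir155), sum(r.fc_8h_vs_nt > 2 for r in records), hubs)
```

prints `21 11 5 ['miR-155-5p']`: of the 21 target genes, 11 pair to a
miR-155 arm, 5 are induced more than 2-fold over untreated culture at 8 h
(Nos2 the strongest at 39.13-fold), and miR-155-5p is the network hub.

An end-to-end simulated run from the command line:

```bash
cat > demo.yaml <<'YAML'
seed: 5
outdir: demo_out
simulate:
  n_features: 150
  lib_size_mean: 1000000
  dispersion: 0.02
  module_fractions: {same-up: 0.0667, same-down: 0.0333}
  spike_min_cpm: 100
YAML
mirtempo -v run --config demo.yaml
```

logs each stage to stderr and prints

```
mirtempo INFO filter: 145 of 150 features retained
mirtempo INFO common dispersion: 0.02125
mirtempo INFO contrast 3h_vs_NT: 0 DEMs of 145 features
mirtempo INFO contrast 8h_vs_NT: 18 DEMs of 145 features
mirtempo INFO contrast 8h_vs_3h: 17 DEMs of 145 features
done: 145 features, 17 T-DEMs -> demo_out/report.json
```

Here 15 temporal effects were spiked (10 late, 5 early) on features with
baseline ≥ 100 CPM; `demo_out/report.json` records that all 15 were
recovered with the correct phase
(`"tdem_recovered_correct_phase": 15, "tdem_truth": 15`), the estimated
dispersion 0.0212 against the simulated 0.02, and every threshold used.
Stage artifacts (filtered counts, TMM factors, CPM, PCA scores, per-contrast
DE tables, module assignments, T-DEMs with MA-plot data, integration
records, network edges) are plain TSV files in `demo_out/`.

Subcommands `simulate`, `prep`, `de`, `trends`, `tdem` and `integrate` run
the stages individually on their TSV artifacts; exit code 2 flags validation
errors.

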