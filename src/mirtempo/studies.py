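"""Simulation studies validating the statistical behaviour of the pipeline.

Each study fixes one set of conditions (feature count, design, dispersion,
effect size, number of seeds), simulates with the package's own generator,
runs the analysis path under test, and returns summary metrics. They are the
package's calibration experiments: the test suite and the reproduction
script both run them unchanged.

All studies use biological triplicates and the generator's default library
depth (5e6 reads log-normal); the per-study feature counts follow the sizes
of the experiments they emulate (372 identified miRNAs for the recovery
studies, 2000 features for the error-control studies).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import diffexp, prep, simulate, temporal, trends

__all__ = [
    "null_fdr_study",
    "power_study",
    "module_recovery_study",
    "tdem_recovery_study",
    "dispersion_recovery_study",
]

TWO_GROUP_DESIGN = (("NT", 0, 3), ("activated", 3, 3))


def _study_seed(base_seed: int, i: int) -> int:
    return (base_seed * 1000 + i) % (2**31 - 1)


def _prepare(config: simulate.SimConfig):
    counts, design, truth = simulate.simulate_experiment(config)
    filtered = prep.filter_low_expression(counts)
    factors = prep.tmm_factors(filtered)
    groups = [
        list(idx)
        for _, idx in design.groupby(["condition", "timepoint"]).groups.items()
        if len(idx) >= 2
    ]
    dispersion = diffexp.estimate_common_dispersion(filtered, groups, factors)
    return counts, design, truth, filtered, factors, dispersion


def _group(design: pd.DataFrame, condition: str, timepoint: int) -> list[str]:
    mask = (design["condition"] == condition) & (design["timepoint"] == timepoint)
    return list(design.index[mask])


def null_fdr_study(
    base_seed: int = 1,
    n_seeds: int = 20,
    n_features: int = 2000,
    dispersion: float = 0.1,
) -> dict:
    """Error control under the global null.

    Two groups of three replicates with no spiked effects; the fraction of
    tested features reaching q <= 0.05 is averaged over seeds. Under a valid
    test plus BH this fraction is near zero.
    """
    fractions = []
    for i in range(n_seeds):
        cfg = simulate.SimConfig(
            n_features=n_features,
            groups=TWO_GROUP_DESIGN,
            module_fractions={},
            dispersion=dispersion,
            seed=_study_seed(base_seed, i),
        )
        counts, design, truth, filtered, factors, disp = _prepare(cfg)
        de = diffexp.nb_exact_test(
            filtered, _group(design, "NT", 0), _group(design, "activated", 3),
            disp, factors,
        )
        fractions.append(float((de["qvalue"] <= 0.05).mean()))
    return {
        "mean_fraction_q05": float(np.mean(fractions)),
        "n_seeds": n_seeds,
        "n_features": n_features,
    }


def power_study(
    base_seed: int = 1,
    n_seeds: int = 10,
    n_features: int = 2000,
    dispersion: float = 0.1,
    effect_log2fc: float = 1.0,
    spiked_fraction: float = 0.2,
    spike_min_cpm: float = 100.0,
) -> dict:
    """DEM sensitivity and false-discovery proportion with spiked 2-fold effects.

    Effects of |log2FC| = ``effect_log2fc`` are spiked (half up, half down) on
    features with baseline CPM >= ``spike_min_cpm``; sensitivity is the
    fraction of spiked features called as DEMs and the FDP the fraction of
    calls that were not spiked, averaged over seeds.
    """
    sens, fdp = [], []
    half = spiked_fraction / 2.0
    for i in range(n_seeds):
        cfg = simulate.SimConfig(
            n_features=n_features,
            groups=TWO_GROUP_DESIGN,
            module_fractions={"up-same": half, "down-same": half},
            dispersion=dispersion,
            effect_log2fc=effect_log2fc,
            spike_min_cpm=spike_min_cpm,
            seed=_study_seed(base_seed, i),
        )
        counts, design, truth, filtered, factors, disp = _prepare(cfg)
        de = diffexp.nb_exact_test(
            filtered, _group(design, "NT", 0), _group(design, "activated", 3),
            disp, factors,
        )
        calls = diffexp.call_dems(de)
        spiked = set(truth.index[truth["log2fc_3h_vs_nt"] != 0]) & set(filtered.index)
        called = set(calls.index)
        tp = len(called & spiked)
        sens.append(tp / max(len(spiked), 1))
        fdp.append((len(called) - tp) / max(len(called), 1))
    return {
        "sensitivity": float(np.mean(sens)),
        "fdp": float(np.mean(fdp)),
        "n_seeds": n_seeds,
        "n_features": n_features,
    }


def module_recovery_study(
    base_seed: int = 1,
    n_seeds: int = 10,
    n_features: int = 372,
    dispersion: float = 0.1,
    effect_log2fc: float = 1.0,
    spike_min_cpm: float = 100.0,
) -> dict:
    """Nine-module classification accuracy on spiked features.

    The full three-group design is simulated with the default module
    occupancies; spiked features sit at baseline CPM >= ``spike_min_cpm``.
    Accuracy is the fraction of spiked (non same-same) features assigned
    their true module from the estimated fold changes.
    """
    acc = []
    for i in range(n_seeds):
        cfg = simulate.SimConfig(
            n_features=n_features,
            dispersion=dispersion,
            effect_log2fc=effect_log2fc,
            spike_min_cpm=spike_min_cpm,
            seed=_study_seed(base_seed, i),
        )
        counts, design, truth, filtered, factors, disp = _prepare(cfg)
        nt = _group(design, "NT", 0)
        a3 = _group(design, "activated", 3)
        a8 = _group(design, "activated", 8)
        de3 = diffexp.nb_exact_test(filtered, nt, a3, disp, factors)
        de83 = diffexp.nb_exact_test(filtered, a3, a8, disp, factors)
        modules = trends.classify_modules(de3["log2fc"], de83["log2fc"])
        tr = truth.loc[filtered.index]
        spiked = tr.index[tr["module"] != "same-same"]
        acc.append(
            float((modules["module"].loc[spiked] == tr["module"].loc[spiked]).mean())
        )
    return {
        "module_recovery_spiked": float(np.mean(acc)),
        "n_seeds": n_seeds,
        "n_features": n_features,
    }


def tdem_recovery_study(
    base_seed: int = 1,
    n_seeds: int = 10,
    n_features: int = 372,
    n_late: int = 10,
    n_early: int = 5,
    dispersion: float = 0.1,
    effect_log2fc: float = 1.0,
    spike_min_cpm: float = 100.0,
) -> dict:
    """Recovery of spiked temporal effects with their early/late phase.

    15 temporal effects (10 late inductions, 5 early waves) of |log2FC| =
    ``effect_log2fc`` are spiked among the features at CPM >=
    ``spike_min_cpm``; a spike counts as recovered when called as a T-DEM
    with the matching phase. The mean recovered count over seeds is reported.
    """
    recovered = []
    for i in range(n_seeds):
        cfg = simulate.SimConfig(
            n_features=n_features,
            module_fractions={
                "same-up": n_late / n_features,
                "same-down": n_early / n_features,
            },
            dispersion=dispersion,
            effect_log2fc=effect_log2fc,
            spike_min_cpm=spike_min_cpm,
            seed=_study_seed(base_seed, i),
        )
        counts, design, truth, filtered, factors, disp = _prepare(cfg)
        de = temporal.temporal_contrast(filtered, design, disp, factors)
        tdems = temporal.call_tdems(de)
        tr = truth.loc[filtered.index]
        spiked = tr.index[tr["log2fc_8h_vs_3h"] != 0]
        n_ok = 0
        for f in spiked:
            if f in tdems.index:
                want = "late" if tr.loc[f, "log2fc_8h_vs_3h"] > 0 else "early"
                n_ok += int(tdems.loc[f, "phase"] == want)
        recovered.append(n_ok)
    return {
        "mean_recovered": float(np.mean(recovered)),
        "n_spiked": n_late + n_early,
        "n_seeds": n_seeds,
    }


def dispersion_recovery_study(
    base_seed: int = 1,
    n_features: int = 2000,
    dispersion: float = 0.1,
) -> dict:
    """Recovery of the simulating common dispersion by conditional ML."""
    cfg = simulate.SimConfig(
        n_features=n_features,
        groups=TWO_GROUP_DESIGN,
        module_fractions={},
        dispersion=dispersion,
        seed=_study_seed(base_seed, 0),
    )
    counts, design, truth, filtered, factors, disp = _prepare(cfg)
    return {
        "estimate": float(disp.common),
        "true": dispersion,
        "n_features": n_features,
    }
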