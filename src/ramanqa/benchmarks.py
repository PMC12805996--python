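"""Reference benchmark studies exercising every pipeline stage end to end.

Each function runs a self-contained, seeded study on synthetic ground truth
and returns the summary quantities a QA lab would monitor: worked counting
arithmetic for a multi-strain product, baseline-solver verification against
a dense direct solve, classification accuracy and its sampling-depth and
batch-effect behavior, mixture-composition recovery including rare-member
detection, spike-in counting linearity, and the D2O vitality metrics.

Problem sizes are desk-scale: 1500 cells per class for classification
studies (the recommended sampling depth), 5000 cells for rare-member
detection, and a 1e6-1e12 CFU/g grid for counting linearity.
"""

from __future__ import annotations

import numpy as np

from .classify import (
    evaluate_batch_holdout,
    evaluate_split,
    predict_cells,
    sampling_depth_curve,
    train_classifier,
)
from .preprocess import baseline_arpls, dense_penalty_matrix, preprocess_pipeline
from .quantify import (
    SpikeInDesign,
    absolute_concentration,
    cfu_per_g_to_concentration,
    concentration_to_cfu_per_g,
    live_cell_count,
    recommend_reference_dose,
)
from .simulate import (
    BatchEffectSpec,
    VitalitySpec,
    default_axis,
    make_species_cohort,
    moderate_noise_conditions,
    simulate_cells,
    simulate_mixture,
    simulate_spikein,
)
from .spectra import Ramanome
from .vitality import cdr_per_cell, compute_cdr, compute_mal, mal_hi, viability_rate

__all__ = [
    "bke3_worked_counts",
    "arpls_oracle_gap",
    "classification_study",
    "depth_sd_study",
    "batch_effect_study",
    "mixture_study",
    "spikein_recovery_study",
    "vitality_study",
]

# ---------------------------------------------------------------------------
# Worked multi-strain product arithmetic (inputs as printed on the product's
# QA datasheet: total count, strain proportions, strain viability rates, the
# reference dose and the classifier-predicted mixing ratio).

BKE3_TOTAL_CFU_PER_G = 6.15e10
BKE3_PROPORTIONS = {"BL-99": 0.4853, "ET-22": 0.2774, "K56": 0.2373}
BKE3_VIABILITY = {"BL-99": 0.5824, "ET-22": 0.6837, "K56": 0.4020}
BKE3_SPECIES = {"B. animalis": ("BL-99",), "L. paracasei": ("ET-22", "K56")}
BKE3_REFERENCE_DOSE = 4.87e8  # CFU/mL
BKE3_PREDICTED_RATIO = 143.48  # test:reference cell ratio at equal volumes


def bke3_worked_counts() -> dict:
    """Strain live counts and species totals for the three-strain product."""
    live = {
        strain: live_cell_count(BKE3_TOTAL_CFU_PER_G, BKE3_PROPORTIONS[strain],
                                BKE3_VIABILITY[strain])
        for strain in BKE3_PROPORTIONS
    }
    species_total = {
        species: live_cell_count(
            BKE3_TOTAL_CFU_PER_G, sum(BKE3_PROPORTIONS[s] for s in strains), 1.0
        )
        for species, strains in BKE3_SPECIES.items()
    }
    design = SpikeInDesign(n_ref=BKE3_REFERENCE_DOSE)
    p_ref = 1.0 / (1.0 + BKE3_PREDICTED_RATIO)
    premix = absolute_concentration(1.0 - p_ref, p_ref, design)
    return {"live": live, "species_total": species_total,
            "premix_concentration_cfu_per_ml": premix}


def arpls_oracle_gap(seed: int = 0, n_spectra: int = 50) -> float:
    """Worst relative gap between the banded iterative baseline solver and a
    dense direct solve of the identical weighted penalized system, over all
    iterations of random drift+peaks spectra (length <= 200)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_spectra):
        n = int(rng.integers(50, 201))
        x = np.linspace(0, 1, n)
        y = (
            rng.uniform(5, 50) * (x - rng.uniform(0.2, 0.8)) ** 2
            + rng.uniform(-10, 10) * x
            + rng.normal(0, 0.5, n)
        )
        for _ in range(int(rng.integers(1, 4))):
            y += rng.uniform(20, 100) * np.exp(
                -0.5 * ((x - rng.uniform(0.1, 0.9)) / rng.uniform(0.01, 0.05)) ** 2
            )
        _, _, iterates = baseline_arpls(y, return_iterates=True)
        penalty = dense_penalty_matrix(n, 1e6)
        for w, z in iterates:
            z_dense = np.linalg.solve(np.diag(w) + penalty, w * y)
            worst = max(worst, float(np.abs(z - z_dense).max() / np.abs(z_dense).max()))
    return worst


def _simulate_classes(cohort, n_per_class, seed, batch=None, batch_id="batch1", **cell_kwargs):
    rng = np.random.default_rng(seed)
    rams = [
        simulate_cells(
            spec, n_per_class, batch=batch, seed=int(rng.integers(2**31)),
            batch_id=batch_id, **cell_kwargs,
        )
        for spec in cohort
    ]
    return Ramanome(rams[0].axis, tuple(c for r in rams for c in r.cells))


def _subsample_per_class(ramanome, n_per_class, seed):
    rng = np.random.default_rng(seed)
    labels = np.asarray(ramanome.labels(), dtype=object)
    idx = np.concatenate(
        [
            rng.choice(np.where(labels == lab)[0], size=n_per_class, replace=False)
            for lab in np.unique(labels)
        ]
    )
    return ramanome.select_cells(sorted(int(i) for i in idx))


def classification_study(seed: int = 0, n_per_class: int = 1500) -> dict:
    """LDA 70/30x5 accuracy on a 4-species high-separation simulation at the
    recommended sampling depth, default noise."""
    cohort = make_species_cohort(4, seed=seed)
    r = _simulate_classes(cohort, n_per_class + 60, seed + 1)
    processed, _ = preprocess_pipeline(r, normalize=False)
    processed = _subsample_per_class(processed, n_per_class, seed + 2)
    res = evaluate_split(processed, "LDA", repeats=5, seed=seed + 3)
    return {
        "accuracy_mean_pct": res.accuracy_mean,
        "accuracy_sd_pct": res.accuracy_sd,
        "n_cells": len(processed),
    }


def depth_sd_study(seed: int = 0, n_curves: int = 10) -> dict:
    """Replicate sampling-depth curves in the moderately-noisy regime;
    counts how often accuracy SD at 500 spectra exceeds the SD at 1500."""
    wins = 0
    sd500, sd1500 = [], []
    for k in range(n_curves):
        cohort = make_species_cohort(
            4, seed=seed + 10 * k, separation="low", **moderate_noise_conditions()
        )
        r = _simulate_classes(cohort, 1560, seed + 10 * k + 1)
        processed, _ = preprocess_pipeline(r, normalize=False)
        curve = sampling_depth_curve(
            processed, "LDA", sizes=[500, 1500], repeats=5, seed=seed + 10 * k + 2
        )
        sd500.append(curve[0][2])
        sd1500.append(curve[1][2])
        wins += curve[0][2] > curve[1][2]
    return {
        "wins": wins,
        "n_curves": n_curves,
        "sd_500_mean_pct": float(np.mean(sd500)),
        "sd_1500_mean_pct": float(np.mean(sd1500)),
    }


#: Strong session effects: axis shift at the calibration tolerance limit,
#: >=30% gain swings, and visible baseline perturbation.
STRONG_BATCHES = (
    BatchEffectSpec(axis_shift=-5.0, intensity_gain=0.7, baseline_perturbation=1.0),
    BatchEffectSpec(axis_shift=0.0, intensity_gain=1.0, baseline_perturbation=0.0),
    BatchEffectSpec(axis_shift=5.0, intensity_gain=1.4, baseline_perturbation=1.5),
)


def batch_effect_study(seed: int = 0, n_runs: int = 20, n_per_class: int = 150) -> dict:
    """Single-batch vs two-batch training under strong batch effects,
    evaluated on held-out batches over seeded replicate simulations."""
    wins = 0
    acc_one, acc_two = [], []
    for run in range(n_runs):
        cohort = make_species_cohort(
            4, seed=seed + 100 * run, separation="low", **moderate_noise_conditions()
        )
        parts = []
        for b, beff in enumerate(STRONG_BATCHES):
            parts.append(
                _simulate_classes(
                    cohort, n_per_class, seed + 100 * run + b + 1,
                    batch=beff, batch_id=f"batch{b}",
                )
            )
        r = Ramanome(parts[0].axis, tuple(c for p in parts for c in p.cells))
        processed, _ = preprocess_pipeline(r, normalize=False)
        one = evaluate_batch_holdout(processed, "LDA", train_batches=1, seed=run)
        two = evaluate_batch_holdout(processed, "LDA", train_batches=2, seed=run)
        acc_one.append(one.accuracy_mean)
        acc_two.append(two.accuracy_mean)
        wins += one.accuracy_mean < two.accuracy_mean
    return {
        "wins": wins,
        "n_runs": n_runs,
        "single_batch_accuracy_pct": float(np.mean(acc_one)),
        "two_batch_accuracy_pct": float(np.mean(acc_two)),
    }


def mixture_study(seed: int = 0, n_detection_seeds: int = 20) -> dict:
    """Two-species mixture recovery at 1:1 and 9:1 (n=1500) and rare-member
    detection at 999:1 (n=5000)."""
    cohort = make_species_cohort(2, seed=seed)
    train = _simulate_classes(cohort, 1550, seed + 1)
    train_processed, _ = preprocess_pipeline(train, normalize=False)
    model = train_classifier(train_processed, "LDA", seed=seed)

    errors = {}
    for offset, (name, weights) in enumerate({"1to1": (1.0, 1.0), "9to1": (9.0, 1.0)}.items()):
        mix = simulate_mixture(cohort, weights, 1500, seed=seed + 101 + offset)
        processed, _ = preprocess_pipeline(mix, normalize=False)
        preds = predict_cells(model, processed)
        predicted = float(np.mean(preds["label"] == "species1"))
        true = mix.provenance["true_counts"]["species1"] / len(mix)
        errors[name] = 100.0 * abs(predicted - true)

    detections = 0
    for k in range(n_detection_seeds):
        mix = simulate_mixture(cohort, (999.0, 1.0), 5000, seed=seed + 5000 + k)
        processed, _ = preprocess_pipeline(mix, normalize=False)
        preds = predict_cells(model, processed)
        truth = dict(zip(processed.cell_ids(), processed.labels()))
        hits = sum(
            1
            for cid, lab in zip(preds["cell_id"], preds["label"])
            if truth[cid] == "species2" and lab == "species2"
        )
        detections += hits >= 1
    return {
        "error_1to1_pp": errors["1to1"],
        "error_9to1_pp": errors["9to1"],
        "detection_rate_pct": 100.0 * detections / n_detection_seeds,
        "n_detection_seeds": n_detection_seeds,
    }


def spikein_recovery_study(seed: int = 0, n_cells: int = 1500, n_reps: int = 3) -> dict:
    """Counting linearity: recover a 1e6-1e12 CFU/g grid with a perfect
    classifier (true labels) and regress log10(recovered) on log10(true).
    Each grid point is acquired ``n_reps`` times at ``n_cells`` spectra."""
    cohort = make_species_cohort(2, seed=seed)
    test_spec, ref_spec = cohort
    axis = default_axis(16.0)
    base = SpikeInDesign(n_ref=1.0, dilution_chain=(100.0,), mass_per_ml=0.1 / 0.9)
    grid = 10.0 ** np.arange(6.0, 12.01, 0.5)
    log_true, log_rec = [], []
    for k, true_cfu in enumerate(grid):
        n_ref = recommend_reference_dose(true_cfu, base)
        design = SpikeInDesign(
            n_ref=n_ref, dilution_chain=base.dilution_chain, mass_per_ml=base.mass_per_ml
        )
        for rep in range(n_reps):
            r = simulate_spikein(
                [test_spec], [1.0], ref_spec, design, true_cfu_per_g=float(true_cfu),
                n_total=n_cells, seed=seed + 31 * k + 1009 * rep, axis=axis,
            )
            counts = r.provenance["true_counts"]
            n_ref_cells = counts[ref_spec.name]
            n_test_cells = counts[test_spec.name]
            if n_ref_cells == 0:
                continue
            conc = absolute_concentration(
                n_test_cells / n_cells, n_ref_cells / n_cells, design
            )
            recovered = concentration_to_cfu_per_g(conc, design)
            if recovered > 0:
                log_true.append(np.log10(true_cfu))
                log_rec.append(np.log10(recovered))
    slope, intercept = np.polyfit(log_true, log_rec, 1)
    fitted = np.polyval([slope, intercept], log_true)
    ss_res = float(np.sum((np.asarray(log_rec) - fitted) ** 2))
    ss_tot = float(np.sum((np.asarray(log_rec) - np.mean(log_rec)) ** 2))
    return {
        "slope": float(slope),
        "r2": 1.0 - ss_res / ss_tot,
        "n_grid_points": len(log_true),
    }


def vitality_study(seed: int = 0, n_cells: int = 1500) -> dict:
    """Vitality-metric verification suite.

    Scale invariance of CDR over random gains; recovery of the simulator's
    per-cell transfer fraction by MAL with noise off; binomial recovery of a
    90%-live population's viability rate (noise off, so truly dead cells sit
    exactly at the MAL=0 boundary rather than scattering across it); MAL-HI
    of identical cells.
    """
    rng = np.random.default_rng(seed)
    axis = default_axis()

    spec = make_species_cohort(1, seed=seed, noise_sd=0.0)[0]
    labeled = simulate_cells(
        spec, 200, vitality=VitalitySpec(1.0, 0.06, 0.015), d2o_hours=3.0,
        seed=seed + 1, include_baseline=False,
    )
    twin = simulate_cells(
        spec, 200, vitality=VitalitySpec(1.0, 0.06, 0.015), d2o_hours=0.0,
        seed=seed + 1, include_baseline=False,
    )

    y = labeled.cells[0].intensities
    base_cdr = compute_cdr(y, axis)
    scale_dev = max(
        abs(compute_cdr(y * g, axis) - base_cdr)
        for g in 10.0 ** rng.uniform(-3, 3, 20)
    )

    mal = compute_mal(cdr_per_cell(labeled), cdr_per_cell(twin))
    transfer = np.array([c.meta["true_transfer"] for c in labeled.cells])
    transfer_err = float(np.max(np.abs(mal - transfer) / transfer))

    live90 = simulate_cells(
        spec, n_cells, vitality=VitalitySpec(0.9, 0.06, 0.015), d2o_hours=3.0,
        seed=seed + 2, include_baseline=False,
    )
    control = simulate_cells(spec, 300, d2o_hours=0.0, seed=seed + 3, include_baseline=False)
    mal90 = compute_mal(cdr_per_cell(live90), cdr_per_cell(control))
    rate = viability_rate(mal90)

    return {
        "cdr_scale_invariance_max_dev": float(scale_dev),
        "transfer_recovery_max_rel_err_pct": 100.0 * transfer_err,
        "viability_rate_90live_pct": rate,
        "true_live_fraction_pct": 100.0 * float(
            np.mean([c.meta["true_live"] for c in live90.cells])
        ),
        "mal_hi_identical_cells": mal_hi([0.01] * 10),
        "n_cells": n_cells,
    }
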