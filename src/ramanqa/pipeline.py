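"""End-to-end QA orchestration: preprocess -> identify -> count -> vitality.

One call produces a :class:`QAReport` with, per strain, the predicted
proportion, total CFU/g (when a spike-in design and reference label are
supplied), the viability rate, live CFU/g, mean MAL and MAL-HI, plus
dataset-level bookkeeping (spectra acquired, spectra passing QC, model and
design manifests, warnings).  Reports are deterministic for fixed inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classify import ClassifierModel, estimate_composition, predict_cells
from .preprocess import PreprocessConfig, preprocess_pipeline
from .quantify import SpikeInDesign, live_cell_count, spikein_counts
from .spectra import Ramanome
from .vitality import vitality_profile

__all__ = ["QAReport", "run_qa", "compare_groups", "RECOMMENDED_SAMPLING_DEPTH"]

#: Minimum recommended number of spectra for robust classification.
RECOMMENDED_SAMPLING_DEPTH = 1500


def _sig3(x: float) -> str:
    """Format to 3 significant figures for the human-readable table."""
    if not np.isfinite(x):
        return str(x)
    return f"{x:.3g}"


@dataclass
class QAReport:
    per_strain: dict
    dataset: dict
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        props = [s.get("proportion_pct") for s in self.per_strain.values()
                 if s.get("proportion_pct") is not None]
        if props and abs(sum(props) - 100.0) > 0.01:
            raise ValueError("strain proportions must sum to 100%")
        for name, s in self.per_strain.items():
            total, live = s.get("total_cfu_per_g"), s.get("live_cfu_per_g")
            if total is not None and live is not None and live > total * (1 + 1e-12):
                raise ValueError(f"live > total for {name!r}")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {"per_strain": self.per_strain, "dataset": self.dataset, "warnings": self.warnings},
            indent=2,
            sort_keys=True,
            default=str,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    def to_table(self) -> str:
        """Human-readable summary; counts shown to 3 significant figures."""
        cols = ["strain", "proportion_pct", "total_cfu_per_g", "viability_rate_pct",
                "live_cfu_per_g", "mean_mal", "mal_hi"]
        lines = ["\t".join(cols)]
        for name, s in self.per_strain.items():
            row = [name] + [
                "" if s.get(c) is None else _sig3(s[c]) for c in cols[1:]
            ]
            lines.append("\t".join(row))
        for wmsg in self.warnings:
            lines.append(f"# warning: {wmsg}")
        return "\n".join(lines)


def run_qa(
    product: Ramanome,
    model: ClassifierModel,
    design: SpikeInDesign | None = None,
    control0h: Ramanome | None = None,
    ref_label: str | None = None,
    cfg: PreprocessConfig | None = None,
) -> QAReport:
    """Run the full QA chain on a raw product ramanome.

    ``product`` holds the mixed acquisition (including reference-strain
    cells when a spike-in was used); ``control0h`` is the unlabeled 0 h
    acquisition for the MAL reference.  Counting is skipped with a
    diagnostic when the design or the reference strain is missing; vitality
    is skipped without a 0 h control.
    """
    cfg = cfg or PreprocessConfig()
    warnings: list = []

    corrected, qc_report = preprocess_pipeline(product, cfg, normalize=False)
    n_acquired, n_kept = len(product), len(corrected)
    if n_kept < RECOMMENDED_SAMPLING_DEPTH:
        warnings.append(
            f"below recommended sampling depth ({RECOMMENDED_SAMPLING_DEPTH}): "
            f"{n_kept} spectra passed QC"
        )

    predictions = predict_cells(model, corrected)
    composition = estimate_composition(predictions, labels=list(model.labels))

    counting_available = design is not None and ref_label is not None
    count_result = None
    if counting_available:
        if composition.counts.get(ref_label, 0) == 0:
            warnings.append(
                f"reference strain {ref_label!r} absent from predictions; counting skipped"
            )
            counting_available = False
        else:
            count_result = spikein_counts(
                predictions, ref_label, design, labels=list(model.labels)
            )

    strain_labels = [lab for lab in model.labels if lab != ref_label]
    p_nonref = sum(composition.proportions[lab] for lab in strain_labels)
    strain_proportions = {
        lab: composition.proportions[lab] / p_nonref if p_nonref > 0 else 0.0
        for lab in strain_labels
    }

    vitality_available = control0h is not None
    profiles = {}
    if vitality_available:
        control_corrected, _ = preprocess_pipeline(control0h, cfg, normalize=False)
        if len(control_corrected) == 0:
            warnings.append("no 0 h control spectra passed QC; vitality skipped")
            vitality_available = False
        else:
            by_label = dict(zip(predictions["cell_id"], predictions["label"]))
            for lab in strain_labels:
                idx = [i for i, cid in enumerate(corrected.cell_ids()) if by_label[cid] == lab]
                if len(idx) >= 2:
                    profiles[lab] = vitality_profile(
                        corrected.select_cells(idx), control_corrected
                    )

    per_strain = {}
    for lab in strain_labels:
        entry = {
            "proportion_pct": 100.0 * strain_proportions[lab],
            "n_cells": composition.counts[lab],
            "total_cfu_per_g": None,
            "viability_rate_pct": None,
            "live_cfu_per_g": None,
            "mean_mal": None,
            "mal_hi": None,
        }
        if count_result is not None:
            entry["total_cfu_per_g"] = count_result.total_cfu_per_g[lab]
        prof = profiles.get(lab)
        if prof is not None:
            entry["viability_rate_pct"] = prof.viability_rate
            entry["mean_mal"] = prof.mean_mal
            entry["mal_hi"] = prof.mal_hi
            if entry["total_cfu_per_g"] is not None:
                entry["live_cfu_per_g"] = live_cell_count(
                    entry["total_cfu_per_g"], 1.0, prof.viability_rate / 100.0
                )
        per_strain[lab] = entry

    if not counting_available and design is None:
        warnings.append("no spike-in design supplied; counting unavailable")
    if control0h is None:
        warnings.append("no 0 h control supplied; vitality unavailable")

    dataset = {
        "n_spectra_acquired": n_acquired,
        "n_passing_qc": n_kept,
        "reference_label": ref_label,
        "reference_proportion_pct": (
            100.0 * composition.proportions.get(ref_label, 0.0) if ref_label else None
        ),
        "total_product_cfu_per_g": (
            sum(count_result.total_cfu_per_g.values()) if count_result is not None else None
        ),
        "classifier_manifest": dict(model.manifest),
        "design_manifest": (
            {
                "n_ref": design.n_ref,
                "vol_ratio": list(design.vol_ratio),
                "dilution_chain": list(design.dilution_chain),
                "mass_per_ml": design.mass_per_ml,
            }
            if design is not None
            else None
        ),
        "qc_dropped": {
            reason: int((qc_report["reason"] == reason).sum())
            for reason in ("low_snr", "outlier")
        },
    }
    return QAReport(per_strain, dataset, warnings)


def compare_groups(a, b, alpha: float = 0.05) -> dict:
    """Two-group comparison with normality-guided test selection.

    Shapiro-Wilk on each group; if both look normal and Levene finds the
    variances homogeneous, a two-sample t test is used, otherwise the
    Mann-Whitney rank-sum test.  Returns the test name, p-value and which
    branch fired.  Statistical machinery is delegated to scipy.stats.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return {"test": "t", "pvalue": 1.0, "branch": "identical-groups"}
    sw_a = stats.shapiro(a).pvalue if np.ptp(a) > 0 else 0.0
    sw_b = stats.shapiro(b).pvalue if np.ptp(b) > 0 else 0.0
    normal = sw_a > alpha and sw_b > alpha
    if normal:
        homoscedastic = stats.levene(a, b).pvalue > alpha
        if homoscedastic:
            res = stats.ttest_ind(a, b)
            return {"test": "t", "pvalue": float(res.pvalue), "branch": "normal-homoscedastic"}
        res = stats.ttest_ind(a, b, equal_var=False)
        return {"test": "welch-t", "pvalue": float(res.pvalue), "branch": "normal-heteroscedastic"}
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "mann-whitney", "pvalue": float(res.pvalue), "branch": "non-normal"}
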