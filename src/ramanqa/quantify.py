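"""Spike-in reference-strain absolute counting.

A reference strain of known concentration is mixed into the product
suspension; classifier-derived per-cell proportions then convert to absolute
counts: ``c_test = n_ref * (p_test / p_ref) * (v_ref / v_test)`` in the
pre-mix suspension, and CFU/g follows from the dilution chain and the grams
of powder per millilitre of initial suspension.  CFU and cell count are
treated as interchangeable units throughout, a deliberate simplification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SpikeInDesign",
    "CountResult",
    "absolute_concentration",
    "concentration_to_cfu_per_g",
    "recommend_reference_dose",
    "live_cell_count",
    "spikein_counts",
    "count_standard_error",
]

#: Validated test:reference cell-ratio window.
RATIO_WINDOW = (1.0, 1000.0)
#: Supported product concentration range, CFU/g.
SUPPORTED_RANGE = (1e6, 1e12)


@dataclass(frozen=True)
class SpikeInDesign:
    """Reference-strain dose and dilution bookkeeping.

    n_ref
        Reference concentration in the pre-mix suspension, CFU/mL.
    vol_ratio
        (test, reference) mixing volumes; default equal volumes.
    dilution_chain
        Ordered dilution factors from product suspension to the measured
        suspension (each >= 1).
    mass_per_ml
        Grams of product powder per mL of the initial suspension.
    """

    n_ref: float
    vol_ratio: tuple = (1.0, 1.0)
    dilution_chain: tuple = (1.0,)
    mass_per_ml: float = 1.0
    n_ref_sd: float = 0.0

    def __post_init__(self) -> None:
        # coerce, so YAML scalars such as "1.0e8" (a string under YAML 1.1) work
        object.__setattr__(self, "n_ref", float(self.n_ref))
        object.__setattr__(self, "mass_per_ml", float(self.mass_per_ml))
        object.__setattr__(self, "n_ref_sd", float(self.n_ref_sd))
        if self.n_ref <= 0:
            raise ValueError("n_ref must be > 0")
        if len(self.vol_ratio) != 2 or min(self.vol_ratio) <= 0:
            raise ValueError("vol_ratio must be two positive volumes (test, reference)")
        if any(f < 1 for f in self.dilution_chain):
            raise ValueError("all dilution factors must be >= 1")
        if self.mass_per_ml <= 0:
            raise ValueError("mass_per_ml must be > 0")
        object.__setattr__(self, "vol_ratio", tuple(float(v) for v in self.vol_ratio))
        object.__setattr__(self, "dilution_chain", tuple(float(f) for f in self.dilution_chain))

    @property
    def total_dilution(self) -> float:
        return float(np.prod(self.dilution_chain))

    def to_yaml(self, path) -> None:
        d = {
            "n_ref": self.n_ref,
            "vol_ratio": list(self.vol_ratio),
            "dilution_chain": list(self.dilution_chain),
            "mass_per_ml": self.mass_per_ml,
            "n_ref_sd": self.n_ref_sd,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SpikeInDesign":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["vol_ratio"] = tuple(d.get("vol_ratio", (1.0, 1.0)))
        d["dilution_chain"] = tuple(d.get("dilution_chain", (1.0,)))
        return cls(**d)


@dataclass
class CountResult:
    """Per-strain absolute counts plus the intermediates they came from."""

    total_cfu_per_g: dict
    live_cfu_per_g: dict = field(default_factory=dict)
    intermediate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for strain, total in self.total_cfu_per_g.items():
            if total < 0:
                raise ValueError(f"negative count for {strain!r}")
            live = self.live_cfu_per_g.get(strain)
            if live is not None and live > total * (1 + 1e-12):
                raise ValueError(f"live > total for {strain!r}")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "total_cfu_per_g": self.total_cfu_per_g,
                "live_cfu_per_g": self.live_cfu_per_g,
                "intermediate": self.intermediate,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload


def absolute_concentration(p_test: float, p_ref: float, design: SpikeInDesign) -> float:
    """Test-strain concentration in the pre-mix suspension, CFU/mL.

    ``p_test`` and ``p_ref`` are the classifier-derived cell fractions of the
    test and reference strains among all classified cells.
    """
    if p_ref <= 0:
        raise ValueError("reference strain undetected (p_ref = 0): counting impossible")
    if p_test < 0 or p_ref > 1 or p_test + p_ref > 1 + 1e-9:
        raise ValueError("proportions must satisfy 0 <= p_test, p_test + p_ref <= 1")
    v_test, v_ref = design.vol_ratio
    return design.n_ref * (p_test / p_ref) * (v_ref / v_test)


def concentration_to_cfu_per_g(concentration: float, design: SpikeInDesign) -> float:
    """Convert a measured-suspension concentration (CFU/mL) to CFU/g of powder."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return concentration * design.total_dilution / design.mass_per_ml


def cfu_per_g_to_concentration(cfu_per_g: float, design: SpikeInDesign) -> float:
    """Inverse of :func:`concentration_to_cfu_per_g`."""
    return cfu_per_g * design.mass_per_ml / design.total_dilution


def recommend_reference_dose(expected_cfu_per_g: float, design: SpikeInDesign) -> float:
    """Reference dose (CFU/mL) keeping the expected test:ref ratio in [1, 1000].

    The dose is rounded to the nearest power of ten ("an appropriate order of
    magnitude"), aimed at the geometric midpoint of the validated window so
    rounding cannot push the ratio outside it.
    """
    lo, hi = SUPPORTED_RANGE
    if not lo <= expected_cfu_per_g <= hi:
        raise ValueError(
            f"expected_cfu_per_g outside the validated window [{lo:g}, {hi:g}] CFU/g"
        )
    conc = cfu_per_g_to_concentration(expected_cfu_per_g, design)
    v_test, v_ref = design.vol_ratio
    target = conc * v_test / v_ref / math.sqrt(RATIO_WINDOW[1])
    return 10.0 ** round(math.log10(target))


def live_cell_count(total_cfu_per_g: float, proportion: float, viability_rate: float) -> float:
    """Strain live count: total x strain proportion x viability fraction."""
    if total_cfu_per_g < 0:
        raise ValueError("total_cfu_per_g must be >= 0")
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must be in [0, 1]")
    if not 0 <= viability_rate <= 1:
        raise ValueError("viability_rate must be in [0, 1]")
    return total_cfu_per_g * proportion * viability_rate


def count_standard_error(
    p_test: float, p_ref: float, n_cells: int, design: SpikeInDesign
) -> float:
    """Delta-method SE of the CFU/g estimate.

    Combines binomial variance of the two proportions (treated as
    independent multinomial fractions of ``n_cells`` classified cells) with
    the stated reference-dose SD.  This is a model-based SE, distinct from
    replicate SDs.
    """
    c = concentration_to_cfu_per_g(absolute_concentration(p_test, p_ref, design), design)
    if c == 0 or n_cells == 0:
        return 0.0
    var_rel = (
        (1 - p_test) / (p_test * n_cells) if p_test > 0 else 0.0
    ) + (1 - p_ref) / (p_ref * n_cells) + (design.n_ref_sd / design.n_ref) ** 2
    return c * math.sqrt(var_rel)


def spikein_counts(
    predictions,
    ref_label: str,
    design: SpikeInDesign,
    viability_rates: Mapping[str, float] | None = None,
    labels: Sequence[str] | None = None,
) -> CountResult:
    """Full spike-in counting from per-cell predictions.

    Proportions fed to the concentration formula are computed over *all*
    classified cells (reference included); strain proportions reported for
    live-count arithmetic are renormalized over non-reference labels so they
    sum to 1.
    """
    from .classify import estimate_composition  # local import to avoid cycle

    comp = estimate_composition(predictions, labels=labels)
    if comp.counts.get(ref_label, 0) == 0:
        raise ValueError(f"reference strain {ref_label!r} absent from predictions")
    p_ref = comp.proportions[ref_label]
    n_cells = sum(comp.counts.values())
    totals, intermediates = {}, {"p_ref": p_ref, "p_test": {}, "ratio_test_to_ref": {}}
    test_labels = [lab for lab in comp.proportions if lab != ref_label]
    for lab in test_labels:
        p = comp.proportions[lab]
        conc = absolute_concentration(p, p_ref, design)
        totals[lab] = concentration_to_cfu_per_g(conc, design)
        intermediates["p_test"][lab] = p
        intermediates["ratio_test_to_ref"][lab] = p / p_ref
    p_nonref = sum(comp.proportions[lab] for lab in test_labels)
    intermediates["strain_proportions"] = {
        lab: comp.proportions[lab] / p_nonref for lab in test_labels
    } if p_nonref > 0 else {}
    intermediates["n_cells"] = n_cells
    intermediates["se_cfu_per_g"] = {
        lab: count_standard_error(comp.proportions[lab], p_ref, n_cells, design)
        for lab in test_labels
        if comp.proportions[lab] > 0
    }
    live = {}
    if viability_rates is not None:
        for lab in test_labels:
            if lab in viability_rates:
                live[lab] = live_cell_count(totals[lab], 1.0, viability_rates[lab])
    return CountResult(totals, live, intermediates)
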