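"""Seeded synthetic-ramanome generator.

Provides ground truth for every pipeline stage: species-specific fingerprint
peaks, polynomial + exponential baseline drift, additive noise, lognormal
whole-cell intensity jitter (which makes features correlated across the
spectrum, as in real acquisitions), batch effects (axis shift, gain,
baseline perturbation) and D2O labeling modeled as a mass-conserving
transfer of a per-cell fraction of the C-H band area into a broad C-D
component.

Defaults emulate the acquisition regime the pipeline targets: a 320-4256
cm^-1 axis at 2 cm^-1 spacing, a dominant C-H band, and fingerprint peaks an
order of magnitude above the noise floor.  The generator makes no claim of
physically realistic Raman cross-sections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .quantify import SpikeInDesign, cfu_per_g_to_concentration
from .spectra import Ramanome, SingleCellSpectrum, WavenumberAxis

__all__ = [
    "SyntheticSpeciesSpec",
    "BatchEffectSpec",
    "VitalitySpec",
    "default_axis",
    "make_species_spec",
    "make_species_cohort",
    "moderate_noise_conditions",
    "simulate_cells",
    "simulate_mixture",
    "simulate_spikein",
]

CH_CENTER, CH_WIDTH = 2935.0, 55.0
CD_CENTER, CD_WIDTH = 2170.0, 40.0

#: Shared biological fingerprint peaks (center, width) present in every species.
_SHARED_PEAKS = ((1003.0, 7.0), (1095.0, 11.0), (1250.0, 14.0), (1450.0, 13.0), (1660.0, 15.0))

_UNIQUE_AMPLITUDE = {"high": 0.8, "medium": 0.35, "low": 0.15}


def default_axis(spacing: float = 2.0) -> WavenumberAxis:
    """Calibration-range axis, 320-4256 cm^-1 (1969 points at 2 cm^-1)."""
    return WavenumberAxis(np.arange(320.0, 4256.0 + spacing / 2, spacing))


@dataclass(frozen=True)
class SyntheticSpeciesSpec:
    """Generative recipe for one species' single-cell spectra."""

    name: str
    peaks: tuple  # of (center, width, amplitude, shape in {gaussian, lorentzian})
    ch_amplitude: float = 3.0
    baseline_poly: tuple = (1.0, 0.0, 0.0)
    baseline_exp_amplitude: float = 1.0
    noise_sd: float = 0.02
    cell_variability: float = 0.20

    def __post_init__(self) -> None:
        peaks = tuple((float(c), float(w), float(a), str(s)) for c, w, a, s in self.peaks)
        if any(w <= 0 for _, w, _, _ in peaks):
            raise ValueError("peak widths must be > 0")
        if any(a < 0 for _, _, a, _ in peaks):
            raise ValueError("peak amplitudes must be >= 0")
        if not any(500 <= c <= 1800 for c, _, _, _ in peaks):
            raise ValueError("need at least one fingerprint peak in [500, 1800]")
        if self.ch_amplitude <= 0:
            raise ValueError("need a C-H component in [2800, 3100] (ch_amplitude > 0)")
        object.__setattr__(self, "peaks", peaks)


@dataclass(frozen=True)
class BatchEffectSpec:
    """Instrument/session effects: axis shift, gain, and baseline change."""

    axis_shift: float = 0.0
    intensity_gain: float = 1.0
    baseline_perturbation: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity_gain <= 0:
            raise ValueError("intensity_gain must be > 0")
        if abs(self.axis_shift) > 5:
            raise ValueError("|axis_shift| must be <= 5 cm^-1")


@dataclass(frozen=True)
class VitalitySpec:
    """Population viability and per-cell C-H -> C-D transfer distribution."""

    live_fraction: float = 0.8
    vitality_mean: float = 0.06
    vitality_sd: float = 0.015

    def __post_init__(self) -> None:
        if not 0 <= self.live_fraction <= 1:
            raise ValueError("live_fraction must be in [0, 1]")
        if not 0 <= self.vitality_mean <= 0.5:
            raise ValueError("transfer fraction mean must be in [0, 0.5]")
        if self.vitality_sd < 0:
            raise ValueError("vitality_sd must be >= 0")


def _peak_profile(w: np.ndarray, center: float, width: float, shape: str) -> np.ndarray:
    if shape == "gaussian":
        return np.exp(-0.5 * ((w - center) / width) ** 2)
    if shape == "lorentzian":
        return 1.0 / (1.0 + ((w - center) / width) ** 2)
    raise ValueError(f"unknown peak shape {shape!r}")


def make_species_cohort(
    n_species: int,
    seed: int = 0,
    n_fingerprint_peaks: int = 6,
    separation: str = "high",
    **overrides,
) -> list:
    """Reproducible cohort of species specs sharing one seed stream.

    At 'high' separation every species carries >= 2 fingerprint peaks unique
    to it within the cohort (drawn from a disjoint partition of a reserved
    center grid); 'medium'/'low' reduce the unique-peak amplitude so spectra
    overlap progressively more.
    """
    if n_fingerprint_peaks < 3:
        raise ValueError("need n_fingerprint_peaks >= 3")
    if separation not in _UNIQUE_AMPLITUDE:
        raise ValueError(f"separation must be one of {sorted(_UNIQUE_AMPLITUDE)}")
    rng = np.random.default_rng(seed)
    n_shared = min(len(_SHARED_PEAKS), n_fingerprint_peaks - 2)
    n_unique = n_fingerprint_peaks - n_shared
    candidates = [
        c for c in np.arange(540.0, 1790.0, 18.0)
        if all(abs(c - sc) > 25 for sc, _ in _SHARED_PEAKS)
    ]
    if n_species * n_unique > len(candidates):
        raise ValueError("cohort too large for the reserved unique-center grid")
    order = rng.permutation(len(candidates))
    amp_u = _UNIQUE_AMPLITUDE[separation]
    specs = []
    for i in range(n_species):
        peaks = []
        for center, width in _SHARED_PEAKS[:n_shared]:
            peaks.append((center, width, float(rng.uniform(0.25, 0.55)), "gaussian"))
        for j in range(n_unique):
            center = candidates[order[i * n_unique + j]]
            peaks.append(
                (float(center), float(rng.uniform(6, 12)),
                 amp_u * float(rng.uniform(0.8, 1.2)), "gaussian")
            )
        spec = SyntheticSpeciesSpec(
            name=f"species{i + 1}",
            peaks=tuple(peaks),
            baseline_poly=(float(rng.uniform(0.5, 1.5)), float(rng.uniform(-0.8, 0.8)),
                           float(rng.uniform(-0.5, 0.5))),
            baseline_exp_amplitude=float(rng.uniform(0.5, 1.5)),
        )
        specs.append(replace(spec, **overrides) if overrides else spec)
    return specs


def make_species_spec(
    seed: int = 0,
    n_fingerprint_peaks: int = 6,
    separation: str = "high",
    **overrides,
) -> SyntheticSpeciesSpec:
    """Single reproducible species spec (cohort of one)."""
    return make_species_cohort(1, seed, n_fingerprint_peaks, separation, **overrides)[0]


def moderate_noise_conditions() -> dict:
    """Spec overrides for the moderately-noisy regime used in sampling-depth
    studies, where accuracy is limited by sample size rather than saturated."""
    return {"noise_sd": 0.10, "cell_variability": 0.35}


def simulate_cells(
    spec: SyntheticSpeciesSpec,
    n_cells: int,
    batch: BatchEffectSpec | None = None,
    vitality: VitalitySpec | None = None,
    d2o_hours: float = 0.0,
    axis: WavenumberAxis | None = None,
    seed: int = 0,
    *,
    batch_id: str = "batch1",
    sample_id: str = "sample1",
    include_baseline: bool = True,
    label: str | None = None,
    cell_id_prefix: str | None = None,
) -> Ramanome:
    """Simulate one species' ramanome.

    If ``d2o_hours > 0`` each cell is live with probability
    ``vitality.live_fraction``; live cells move a per-cell fraction ``f`` of
    their C-H band area into the C-D component (dead cells transfer
    nothing).  Ground-truth live flags and transfer fractions are recorded
    in cell metadata.  The per-cell random draws are made in a fixed order
    regardless of ``d2o_hours`` so the same seed produces an exact unlabeled
    twin of a labeled population.
    """
    axis = axis or default_axis()
    w = axis.values
    if not (axis.covers(2040, 2300) and axis.covers(2800, 3100)):
        raise ValueError("axis must cover the C-D and C-H band windows")
    batch = batch or BatchEffectSpec()
    vit = vitality or VitalitySpec()
    rng = np.random.default_rng(seed)
    label = label if label is not None else spec.name
    prefix = cell_id_prefix if cell_id_prefix is not None else f"{label}_{batch_id}"

    t = (w - w[0]) / (w[-1] - w[0])
    base_shape = np.polyval(spec.baseline_poly[::-1], t) + spec.baseline_exp_amplitude * np.exp(-t / 0.3)
    batch_perturb = batch.baseline_perturbation * np.sin(2 * np.pi * (2.0 * t + 0.25))
    shift = batch.axis_shift
    ch_area_unit = CH_WIDTH * math.sqrt(2 * math.pi)  # area of a unit-amplitude C-H Gaussian
    cd_area_unit = CD_WIDTH * math.sqrt(2 * math.pi)

    cells = []
    for i in range(n_cells):
        gain = float(rng.lognormal(0.0, spec.cell_variability))
        peak_jitter = rng.lognormal(0.0, 0.08, size=len(spec.peaks))
        ch_jitter = float(rng.lognormal(0.0, 0.08))
        base_jitter = float(rng.lognormal(0.0, 0.10))
        u_live = float(rng.random())
        f_draw = float(rng.normal(vit.vitality_mean, vit.vitality_sd))
        noise = rng.normal(0.0, spec.noise_sd, size=w.size) if spec.noise_sd > 0 else 0.0

        live = u_live < vit.live_fraction
        f = float(np.clip(f_draw, 0.0, 0.5)) if (d2o_hours > 0 and live) else 0.0

        signal = np.zeros_like(w)
        for (center, width, amp, shape), jit in zip(spec.peaks, peak_jitter):
            signal += amp * gain * jit * _peak_profile(w, center + shift, width, shape)
        a_ch = spec.ch_amplitude * gain * ch_jitter
        signal += (1.0 - f) * a_ch * _peak_profile(w, CH_CENTER + shift, CH_WIDTH, "gaussian")
        if f > 0:
            a_cd = f * a_ch * ch_area_unit / cd_area_unit
            signal += a_cd * _peak_profile(w, CD_CENTER + shift, CD_WIDTH, "gaussian")

        y = signal * batch.intensity_gain
        if include_baseline:
            y = y + (base_shape * base_jitter + batch_perturb) * batch.intensity_gain
        y = y + noise

        meta = {
            "sample_id": sample_id,
            "batch_id": batch_id,
            "label": label,
            "d2o_hours": float(d2o_hours),
            "true_live": bool(live) if d2o_hours > 0 else None,
            "true_transfer": f,
        }
        cells.append(SingleCellSpectrum(f"{prefix}_{i:05d}", y, meta))
    return Ramanome(
        axis,
        tuple(cells),
        {"simulator": {"species": spec.name, "seed": int(seed), "n_cells": int(n_cells),
                       "d2o_hours": float(d2o_hours), "batch_id": batch_id}},
    )


def simulate_mixture(
    specs: Sequence[SyntheticSpeciesSpec],
    weights: Sequence[float],
    n_total: int,
    axis: WavenumberAxis | None = None,
    seed: int = 0,
    batch: BatchEffectSpec | None = None,
    vitality: Mapping[str, VitalitySpec] | VitalitySpec | None = None,
    d2o_hours: float = 0.0,
    *,
    batch_id: str = "batch1",
    include_baseline: bool = True,
) -> Ramanome:
    """Multinomial mixture of species; true composition kept in provenance."""
    weights = np.asarray(weights, dtype=float)
    if weights.size != len(specs):
        raise ValueError("one weight per species spec required")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be >= 0 with a positive sum")
    axis = axis or default_axis()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_total, weights / weights.sum())
    parts = []
    for spec, count in zip(specs, counts):
        if count == 0:
            continue
        vit = vitality.get(spec.name) if isinstance(vitality, Mapping) else vitality
        parts.append(
            simulate_cells(
                spec, int(count), batch=batch, vitality=vit, d2o_hours=d2o_hours,
                axis=axis, seed=int(rng.integers(2**31)), batch_id=batch_id,
                include_baseline=include_baseline,
            )
        )
    cells = [c for part in parts for c in part.cells]
    order = rng.permutation(len(cells))
    cells = tuple(cells[i] for i in order)
    true_counts = {spec.name: int(c) for spec, c in zip(specs, counts)}
    return Ramanome(
        axis,
        cells,
        {
            "true_counts": true_counts,
            "true_proportions": {k: v / max(1, n_total) for k, v in true_counts.items()},
            "weights": {spec.name: float(wt) for spec, wt in zip(specs, weights)},
            "seed": int(seed),
        },
    )


def simulate_spikein(
    product_specs: Sequence[SyntheticSpeciesSpec],
    product_weights: Sequence[float],
    reference_spec: SyntheticSpeciesSpec,
    design: SpikeInDesign,
    true_cfu_per_g: float,
    n_total: int,
    axis: WavenumberAxis | None = None,
    seed: int = 0,
    **mixture_kwargs,
) -> Ramanome:
    """Spike-in acquisition: product strains plus the reference strain.

    Sampling probabilities follow the design's dilution algebra: the product
    contributes cells in proportion to its measured-suspension concentration
    times the test volume, the reference in proportion to ``n_ref`` times
    the reference volume.  The truth manifest holds exactly the quantities
    the counting stage must recover.
    """
    product_weights = np.asarray(product_weights, dtype=float)
    if product_weights.sum() <= 0:
        raise ValueError("product weights must have a positive sum")
    conc_product = cfu_per_g_to_concentration(true_cfu_per_g, design)
    v_test, v_ref = design.vol_ratio
    ref_weight = design.n_ref * v_ref
    if ref_weight <= 0:
        raise ValueError("reference weight is zero")
    strain_weights = conc_product * v_test * product_weights / product_weights.sum()
    r = simulate_mixture(
        list(product_specs) + [reference_spec],
        np.concatenate([strain_weights, [ref_weight]]),
        n_total,
        axis=axis,
        seed=seed,
        **mixture_kwargs,
    )
    prov = dict(r.provenance)
    prov["spikein_truth"] = {
        "true_cfu_per_g": float(true_cfu_per_g),
        "true_strain_cfu_per_g": {
            spec.name: float(true_cfu_per_g * wt / product_weights.sum())
            for spec, wt in zip(product_specs, product_weights)
        },
        "reference_label": reference_spec.name,
        "n_ref": design.n_ref,
        "concentration_product_premix": float(conc_product),
    }
    return Ramanome(r.axis, r.cells, prov)
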