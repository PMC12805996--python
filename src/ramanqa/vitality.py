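"""D2O-probing analytics: C-D ratio, metabolic activity level, viability.

Metabolically active cells incubated in heavy water transfer intensity from
the C-H band (2800-3100 cm^-1) into the C-D band (2040-2300 cm^-1).  The
per-cell C-D ratio is ``CDR = CD / (CD + CH)`` on baseline-corrected,
un-normalized intensities (the ratio is scale-invariant); band "intensity"
is the trapezoidal band area by default, with a peak-maximum mode available
for sensitivity analysis.  The metabolic activity level of a D2O-incubated
cell is ``MAL = CDR - mean CDR of the 0 h control``; MAL > 0 defines a live
cell and MAL <= 0 a dead one.  The heterogeneity index MAL-HI is the
variance of per-cell MAL within a group (SD available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CD_BAND, CH_BAND, BandDefinition
from .spectra import Ramanome, WavenumberAxis

__all__ = [
    "VitalityProfile",
    "compute_cdr",
    "cdr_per_cell",
    "compute_mal",
    "viability_rate",
    "mal_hi",
    "cv_precision",
    "vitality_profile",
]


def _band_signal(intensities, axis: WavenumberAxis, band: BandDefinition, mode: str) -> float:
    mask = axis.band_mask(band.lo, band.hi)
    if not mask.any():
        raise ValueError(f"axis does not cover the {band.name} band [{band.lo}, {band.hi}]")
    # negatives left by baseline correction are floored so CDR stays in [0,1]
    y = np.clip(np.asarray(intensities, dtype=float)[mask], 0.0, None)
    if mode == "area":
        return float(np.trapezoid(y, axis.values[mask]))
    if mode == "max":
        return float(y.max())
    raise ValueError(f"unknown band intensity mode {mode!r}")


def compute_cdr(
    intensities,
    axis: WavenumberAxis,
    cd_band: BandDefinition = CD_BAND,
    ch_band: BandDefinition = CH_BAND,
    mode: str = "area",
) -> float:
    """C-D ratio CD/(CD+CH) of one baseline-corrected spectrum."""
    s_cd = _band_signal(intensities, axis, cd_band, mode)
    s_ch = _band_signal(intensities, axis, ch_band, mode)
    if s_cd + s_ch == 0:
        raise ValueError("both band integrals are zero: no signal")
    # a band integral below double-precision resolution of the total is
    # tail leakage, not signal; floor it so unlabeled cells get exactly 0
    if s_cd <= 1e-12 * (s_cd + s_ch):
        return 0.0
    return s_cd / (s_cd + s_ch)


def cdr_per_cell(
    ramanome: Ramanome,
    cd_band: BandDefinition = CD_BAND,
    ch_band: BandDefinition = CH_BAND,
    mode: str = "area",
) -> np.ndarray:
    return np.array(
        [compute_cdr(c.intensities, ramanome.axis, cd_band, ch_band, mode) for c in ramanome.cells]
    )


def compute_mal(cdr_cells, cdr0_cells) -> np.ndarray:
    """Per-cell MAL: CDR of each labeled cell minus the mean 0 h control CDR.

    The mean-level reference (rather than per-cell pairing) is what yields a
    per-cell MAL distribution, which the heterogeneity index requires.
    """
    cdr_cells = np.asarray(cdr_cells, dtype=float)
    cdr0_cells = np.asarray(cdr0_cells, dtype=float)
    if cdr0_cells.size == 0:
        raise ValueError("empty 0 h control")
    if cdr_cells.size == 0:
        raise ValueError("empty labeled sample")
    return cdr_cells - cdr0_cells.mean()


def viability_rate(mal_per_cell) -> float:
    """Percent of cells with MAL strictly > 0 (MAL = 0 counts dead)."""
    mal = np.asarray(mal_per_cell, dtype=float)
    if mal.size == 0:
        raise ValueError("empty MAL set")
    return 100.0 * float(np.mean(mal > 0))


def mal_hi(mal_per_cell, population: bool = False, as_sd: bool = False) -> float:
    """MAL heterogeneity index: variance of per-cell MAL (SD optional)."""
    mal = np.asarray(mal_per_cell, dtype=float)
    if mal.size < 2:
        raise ValueError("MAL-HI needs at least 2 cells")
    v = float(np.var(mal, ddof=0 if population else 1))
    return float(np.sqrt(v)) if as_sd else v


def cv_precision(groups) -> dict:
    """Coefficient of variation SD/mean per group of repeated CDR measures.

    ``groups`` maps a condition name to its repeated measurements; supports
    a condition grid such as laser power x integration time.
    """
    out = {}
    for name, values in dict(groups).items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"group {name!r}: need at least 2 repeats")
        mean = v.mean()
        if mean <= 0:
            raise ValueError(f"group {name!r}: zero or negative mean")
        out[name] = float(v.std(ddof=1) / mean)
    return out


@dataclass
class VitalityProfile:
    """Per-cell CDR/MAL and the group summary they roll up to."""

    cdr_per_cell: np.ndarray
    mal_per_cell: np.ndarray
    reference_cdr0: float
    viability_rate: float
    mean_mal: float
    mal_hi: float
    per_cell: pd.DataFrame = field(repr=False, default=None)


def vitality_profile(
    sample: Ramanome,
    control0h: Ramanome,
    cd_band: BandDefinition = CD_BAND,
    ch_band: BandDefinition = CH_BAND,
    mode: str = "area",
) -> VitalityProfile:
    """CDR/MAL/viability/MAL-HI for a D2O-labeled sample vs its 0 h control.

    Both ramanomes must be baseline-corrected (un-normalized) spectra.
    """
    cdr0 = cdr_per_cell(control0h, cd_band, ch_band, mode)
    cdr = cdr_per_cell(sample, cd_band, ch_band, mode)
    mal = compute_mal(cdr, cdr0)
    per_cell = pd.DataFrame(
        {
            "cell_id": sample.cell_ids(),
            "label": sample.labels(),
            "cdr": cdr,
            "mal": mal,
            "live": mal > 0,
        }
    )
    return VitalityProfile(
        cdr_per_cell=cdr,
        mal_per_cell=mal,
        reference_cdr0=float(cdr0.mean()),
        viability_rate=viability_rate(mal),
        mean_mal=float(mal.mean()),
        mal_hi=mal_hi(mal) if mal.size >= 2 else float("nan"),
        per_cell=per_cell,
    )
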