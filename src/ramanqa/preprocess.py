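"""Preprocessing chain for single-cell Raman spectra.

Stages, in pipeline order: axis harmonization, arPLS baseline correction,
quality control (low-SNR and outlier removal), band selection, and per-cell
max-min normalization to [0, 1].

Baseline estimation is asymmetrically reweighted penalized least squares
(arPLS): minimize ``(y-z)'W(y-z) + lam * z'D'Dz`` with a second-difference
penalty ``D`` and weights updated each iteration by a logistic function of
the negative residuals' mean and standard deviation, so baseline drift is
suppressed while peaks are preserved.  The smoothness parameter defaults to
1e6 and the sensitivity (weight-convergence ratio) to 0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import sparse
from scipy.linalg import cho_solve_banded, cholesky_banded
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

from .spectra import Ramanome, WavenumberAxis, harmonize_axis

__all__ = [
    "BandDefinition",
    "CD_BAND",
    "CH_BAND",
    "FINGERPRINT_BAND",
    "PreprocessConfig",
    "baseline_arpls",
    "minmax_normalize",
    "quality_control",
    "band_select",
    "preprocess_pipeline",
    "ArplsBaselineCorrector",
    "RowMinMaxScaler",
    "BandSelector",
]


@dataclass(frozen=True)
class BandDefinition:
    """Named wavenumber interval, cm^-1."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: lo must be < hi")


#: Carbon-deuterium band formed by D2O metabolism.
CD_BAND = BandDefinition("CD", 2040.0, 2300.0)
#: Carbon-hydrogen band of intracellular macromolecules.
CH_BAND = BandDefinition("CH", 2800.0, 3100.0)
#: Information-dense biological fingerprint window used for classification.
FINGERPRINT_BAND = BandDefinition("fingerprint", 500.0, 1800.0)


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables for the preprocessing chain.

    lam
        arPLS smoothness penalty (default 1e6).
    ratio
        arPLS sensitivity: relative weight-vector change at which the
        reweighting iteration stops (default 0.05).
    max_iter
        arPLS iteration cap.
    snr_threshold
        Minimum SNR (max baseline-corrected fingerprint intensity over the
        silent-region noise SD) to keep a cell.
    outlier_rho
        Minimum Pearson correlation to the mean spectrum of SNR-passing
        cells to keep a cell.
    silent_region
        Wavenumber window used as the noise estimate; any overlap with the
        fingerprint/CD/CH bands is excluded from the mask.
    """

    lam: float = 1e6
    ratio: float = 0.05
    max_iter: int = 50
    snr_threshold: float = 3.0
    outlier_rho: float = 0.70
    silent_region: tuple = (1730.0, 1980.0)
    fingerprint: BandDefinition = FINGERPRINT_BAND

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not 0 < self.ratio < 1:
            raise ValueError("ratio must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.snr_threshold < 0:
            raise ValueError("snr_threshold must be >= 0")
        if not -1 <= self.outlier_rho <= 1:
            raise ValueError("outlier_rho must be in [-1, 1]")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["fingerprint"] = [self.fingerprint.name, self.fingerprint.lo, self.fingerprint.hi]
        d["silent_region"] = list(self.silent_region)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PreprocessConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if "fingerprint" in d:
            name, lo, hi = d["fingerprint"]
            d["fingerprint"] = BandDefinition(name, float(lo), float(hi))
        if "silent_region" in d:
            d["silent_region"] = tuple(d["silent_region"])
        return cls(**d)


# ---------------------------------------------------------------------------
# arPLS baseline


_PENALTY_CACHE: dict = {}


def _penalty_bands(n: int, lam: float) -> np.ndarray:
    """Upper-banded form (bandwidth 2) of lam * D'D for second differences."""
    key = (n, float(lam))
    if key not in _PENALTY_CACHE:
        D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
        H = (lam * (D.T @ D)).todia()
        ab = np.zeros((3, n))
        ab[0, 2:] = H.diagonal(2)
        ab[1, 1:] = H.diagonal(1)
        ab[2, :] = H.diagonal(0)
        _PENALTY_CACHE[key] = ab
    return _PENALTY_CACHE[key]


def _banded_matvec(ab: np.ndarray, z: np.ndarray) -> np.ndarray:
    """(W + lam*D'D) @ z from the upper-banded representation."""
    out = ab[2] * z
    out[:-1] += ab[1, 1:] * z[1:]
    out[1:] += ab[1, 1:] * z[:-1]
    out[:-2] += ab[0, 2:] * z[2:]
    out[2:] += ab[0, 2:] * z[:-2]
    return out


def dense_penalty_matrix(n: int, lam: float) -> np.ndarray:
    """Dense lam * D'D; the brute-force counterpart of the banded solver."""
    D = np.diff(np.eye(n), n=2, axis=0)
    return lam * (D.T @ D)


def baseline_arpls(
    spectrum: np.ndarray,
    cfg: PreprocessConfig | None = None,
    *,
    lam: float | None = None,
    ratio: float | None = None,
    max_iter: int | None = None,
    return_iterates: bool = False,
):
    """arPLS baseline estimation for one spectrum.

    Returns ``(baseline, corrected)`` with ``corrected = spectrum - baseline``
    exactly.  With ``return_iterates=True`` additionally returns the list of
    ``(weights, baseline)`` pairs visited, one per solve, enabling external
    verification of every iteration against a dense solve of the identical
    weighted penalized system.
    """
    cfg = cfg or PreprocessConfig()
    lam = cfg.lam if lam is None else lam
    ratio = cfg.ratio if ratio is None else ratio
    max_iter = cfg.max_iter if max_iter is None else max_iter

    y = np.asarray(spectrum, dtype=float)
    if y.ndim != 1 or y.size < 10:
        raise ValueError("spectrum must be a 1-D vector of length >= 10")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")

    n = y.size
    ab = _penalty_bands(n, lam)
    w = np.ones(n)
    iterates = []
    z = np.zeros(n)
    for _ in range(max_iter):
        abw = ab.copy()
        abw[2, :] += w
        rhs = w * y
        factor = cholesky_banded(abw, lower=False)
        z = cho_solve_banded((factor, False), rhs)
        # one step of iterative refinement tightens the banded solve to the
        # accuracy of a dense direct solve of the same system
        z = z + cho_solve_banded((factor, False), rhs - _banded_matvec(abw, z))
        if return_iterates:
            iterates.append((w.copy(), z.copy()))
        d = y - z
        neg = d[d < 0]
        if neg.size == 0:
            break
        m, s = neg.mean(), neg.std()
        if s == 0:
            break
        w_new = expit(-(2.0 / s) * (d - (2.0 * s - m)))
        change = np.linalg.norm(w_new - w) / np.linalg.norm(w)
        w = w_new
        if change < ratio:
            break
    corrected = y - z
    if return_iterates:
        return z, corrected, iterates
    return z, corrected


def minmax_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Max-min normalization onto [0, 1]; errors on a constant spectrum."""
    x = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("spectrum contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant spectrum cannot be max-min normalized")
    return (x - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# sklearn-style transformers (operate on (n_cells, n_points) matrices)


class ArplsBaselineCorrector(BaseEstimator, TransformerMixin):
    """Row-wise arPLS baseline removal as a scikit-learn transformer."""

    def __init__(self, lam: float = 1e6, ratio: float = 0.05, max_iter: int = 50):
        self.lam = lam
        self.ratio = ratio
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for i, row in enumerate(X):
            _, out[i] = baseline_arpls(
                row, lam=self.lam, ratio=self.ratio, max_iter=self.max_iter
            )
        return out


class RowMinMaxScaler(BaseEstimator, TransformerMixin):
    """Per-row max-min normalization onto [0, 1]."""

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        lo = X.min(axis=1, keepdims=True)
        hi = X.max(axis=1, keepdims=True)
        span = hi - lo
        if np.any(span == 0):
            raise ValueError("constant spectrum cannot be max-min normalized")
        return (X - lo) / span


class BandSelector(BaseEstimator, TransformerMixin):
    """Restrict columns to the union of wavenumber bands."""

    def __init__(self, axis_values: Sequence[float], bands: Sequence[BandDefinition]):
        self.axis_values = axis_values
        self.bands = bands

    def fit(self, X, y=None):
        w = np.asarray(self.axis_values, dtype=float)
        mask = np.zeros(w.size, dtype=bool)
        for b in self.bands:
            mask |= (w >= b.lo) & (w <= b.hi)
        if not mask.any():
            raise ValueError("no axis point falls inside any selected band")
        self.mask_ = mask
        self.selected_wavenumbers_ = w[mask]
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.mask_]


# ---------------------------------------------------------------------------
# Ramanome-level operations


def _silent_mask(axis: WavenumberAxis, cfg: PreprocessConfig) -> np.ndarray:
    lo, hi = cfg.silent_region
    mask = axis.band_mask(lo, hi)
    for band in (cfg.fingerprint, CD_BAND, CH_BAND):
        mask &= ~axis.band_mask(band.lo, band.hi)
    return mask


def quality_control(ramanome: Ramanome, cfg: PreprocessConfig | None = None):
    """Drop low-SNR cells, then outliers, from a baseline-corrected ramanome.

    SNR is the maximum corrected intensity in the fingerprint band over the
    SD of the corrected intensity in the silent region.  Cells passing the
    SNR gate are then screened once by Pearson correlation with the mean of
    the SNR-passing spectra.  Returns ``(kept, report)`` where ``report`` is
    a per-cell DataFrame (cell_id, snr, rho, kept, reason).
    """
    cfg = cfg or PreprocessConfig()
    if len(ramanome) == 0:
        raise ValueError("empty ramanome")
    silent = _silent_mask(ramanome.axis, cfg)
    if not silent.any():
        raise ValueError("silent region does not overlap the axis")
    finger = ramanome.axis.band_mask(cfg.fingerprint.lo, cfg.fingerprint.hi)
    if not finger.any():
        raise ValueError("fingerprint band does not overlap the axis")

    X = ramanome.to_matrix()
    noise = X[:, silent].std(axis=1)
    peak = X[:, finger].max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise > 0, peak / noise, np.inf)
    pass_snr = snr >= cfg.snr_threshold

    rho = np.full(len(ramanome), np.nan)
    pass_rho = pass_snr.copy()
    if pass_snr.any():
        mean_spec = X[pass_snr].mean(axis=0)
        mc = mean_spec - mean_spec.mean()
        denom_m = np.sqrt((mc**2).sum())
        for i in np.where(pass_snr)[0]:
            xc = X[i] - X[i].mean()
            denom = np.sqrt((xc**2).sum()) * denom_m
            rho[i] = (xc @ mc) / denom if denom > 0 else 0.0
        pass_rho = pass_snr & (rho >= cfg.outlier_rho)

    reasons = np.where(~pass_snr, "low_snr", np.where(~pass_rho, "outlier", ""))
    report = pd.DataFrame(
        {
            "cell_id": ramanome.cell_ids(),
            "snr": snr,
            "rho": rho,
            "kept": pass_rho,
            "reason": reasons,
        }
    )
    kept = ramanome.select_cells(
        list(np.where(pass_rho)[0]),
        {"qc": {"n_in": len(ramanome), "n_kept": int(pass_rho.sum())}},
    )
    return kept, report


def band_select(ramanome: Ramanome, bands: Sequence[BandDefinition]) -> Ramanome:
    """Restrict the ramanome to the union of the given bands."""
    selector = BandSelector(ramanome.axis.values, list(bands)).fit(None)
    axis = WavenumberAxis(selector.selected_wavenumbers_)
    cells = tuple(
        c.with_intensities(c.intensities[selector.mask_]) for c in ramanome.cells
    )
    prov = dict(ramanome.provenance)
    prov["bands"] = [(b.name, b.lo, b.hi) for b in bands]
    return Ramanome(axis, cells, prov)


def preprocess_pipeline(
    ramanome: Ramanome,
    cfg: PreprocessConfig | None = None,
    *,
    target_axis: WavenumberAxis | None = None,
    normalize: bool = True,
):
    """Full chain: harmonize -> arPLS per cell -> QC -> max-min normalize.

    With ``normalize=False`` the output stays baseline-corrected but
    un-normalized (the form the C-D ratio is computed from; the ratio is
    scale-invariant so normalization is deliberately skipped there).
    Returns ``(processed, qc_report)``.
    """
    cfg = cfg or PreprocessConfig()
    r = harmonize_axis(ramanome, target_axis) if target_axis is not None else ramanome
    corrector = ArplsBaselineCorrector(cfg.lam, cfg.ratio, cfg.max_iter).fit(r.to_matrix())
    corrected = r.with_matrix(
        corrector.transform(r.to_matrix()), {"baseline": "arpls", "lam": cfg.lam, "ratio": cfg.ratio}
    )
    kept, report = quality_control(corrected, cfg)
    if not normalize or len(kept) == 0:
        return kept, report
    normed = kept.with_matrix(
        RowMinMaxScaler().fit(kept.to_matrix()).transform(kept.to_matrix()),
        {"normalization": "max-min"},
    )
    return normed, report
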