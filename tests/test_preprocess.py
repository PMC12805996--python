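"""Baseline correction, normalization, QC and band selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanqa.preprocess import (
    CD_BAND,
    CH_BAND,
    FINGERPRINT_BAND,
    BandDefinition,
    PreprocessConfig,
    band_select,
    baseline_arpls,
    dense_penalty_matrix,
    minmax_normalize,
    preprocess_pipeline,
    quality_control,
)
from ramanqa.simulate import make_species_spec, simulate_cells
from ramanqa.spectra import Ramanome, SingleCellSpectrum, WavenumberAxis


def drift_and_peaks(n=1000, noise=0.005, peaks=True, seed=7):
    """Quadratic drift (+ optional Gaussian peaks) with a small noise floor.

    A noise floor is part of the construction: the asymmetric reweighting is
    degenerate on exactly noiseless input (weights harden and the baseline
    erodes to the lower envelope), which no real detector produces.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(n, dtype=float)
    drift = 100 * (x / n - 0.5) ** 2 + 20 * (x / n)
    y = drift + rng.normal(0, noise * np.ptp(drift), n)
    centers = [n // 5, n // 2, 4 * n // 5]
    if peaks:
        for c in centers:
            y += 100 * np.exp(-0.5 * ((x - c) / 10) ** 2)
    return x, drift, y, centers


class TestArpls:
    def test_all_zero_spectrum(self):
        z, corrected = baseline_arpls(np.zeros(100))
        assert np.all(z == 0) and np.all(corrected == 0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            baseline_arpls(np.ones(5))
        with pytest.raises(ValueError):
            baseline_arpls(np.full(50, np.nan))

    def test_pure_drift_removed(self):
        _, drift, y, _ = drift_and_peaks(peaks=False)
        z, corrected = baseline_arpls(y)
        assert np.abs(corrected).max() < 0.01 * np.ptp(drift) + 3 * 0.005 * np.ptp(drift)

    def test_drift_plus_peaks_recovery(self):
        x, drift, y, centers = drift_and_peaks()
        z, corrected = baseline_arpls(y)
        for c in centers:
            assert abs(corrected[c] - 100) / 100 < 0.05
        away = np.ones(x.size, bool)
        for c in centers:
            away[c - 50 : c + 50] = False
        assert np.abs(z - drift)[away].max() < 0.02 * np.ptp(drift)

    def test_baseline_plus_corrected_is_input(self):
        _, _, y, _ = drift_and_peaks()
        z, corrected = baseline_arpls(y)
        np.testing.assert_allclose(z + corrected, y, rtol=1e-14, atol=1e-12)

    def test_deterministic(self):
        _, _, y, _ = drift_and_peaks()
        a = baseline_arpls(y)
        b = baseline_arpls(y)
        np.testing.assert_array_equal(a[0], b[0])

    def test_matches_dense_solve_every_iteration(self):
        """The banded iterative solver equals a dense direct solve of the
        same weighted penalized system at every visited iterate."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(60, 201))
            x = np.linspace(0, 1, n)
            y = (
                rng.uniform(5, 50) * (x - 0.4) ** 2
                + rng.uniform(20, 100) * np.exp(-0.5 * ((x - 0.5) / 0.04) ** 2)
                + rng.normal(0, 0.5, n)
            )
            _, _, iterates = baseline_arpls(y, return_iterates=True)
            penalty = dense_penalty_matrix(n, 1e6)
            for w, z in iterates:
                z_dense = np.linalg.solve(np.diag(w) + penalty, w * y)
                assert np.abs(z - z_dense).max() / np.abs(z_dense).max() < 1e-8


class TestMinMax:
    def test_example(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50))
    def test_range_and_idempotence(self, values):
        x = np.asarray(values)
        if x.max() == x.min():
            with pytest.raises(ValueError):
                minmax_normalize(x)
            return
        y = minmax_normalize(x)
        assert y.min() == 0.0 and y.max() == 1.0
        np.testing.assert_allclose(minmax_normalize(y), y, atol=1e-15)

    def test_constant_spectrum_errors(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize(np.full(10, 3.0))


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(lam=-1)
        with pytest.raises(ValueError):
            PreprocessConfig(ratio=2.0)
        with pytest.raises(ValueError):
            PreprocessConfig(outlier_rho=1.5)

    def test_yaml_round_trip(self, tmp_path):
        cfg = PreprocessConfig(lam=1e5, snr_threshold=4.0)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert PreprocessConfig.from_yaml(tmp_path / "cfg.yaml") == cfg


def _corrected_ramanome(n_cells=30, seed=0):
    spec = make_species_spec(5)
    r = simulate_cells(spec, n_cells, seed=seed, include_baseline=False)
    return r


class TestQualityControl:
    def test_identical_spectra_all_kept(self):
        axis = WavenumberAxis(np.arange(320.0, 4257.0, 4.0))
        template = np.exp(-0.5 * ((axis.values - 1000) / 20) ** 2)
        rng = np.random.default_rng(0)
        cells = tuple(
            SingleCellSpectrum(f"c{i}", template + rng.normal(0, 1e-6, axis.values.size))
            for i in range(10)
        )
        kept, report = quality_control(Ramanome(axis, cells))
        assert len(kept) == 10
        assert np.all(report["rho"] > 0.999)

    def test_noise_only_cells_dropped_low_snr(self):
        r = _corrected_ramanome(40)
        rng = np.random.default_rng(1)
        noise_cells = tuple(
            SingleCellSpectrum(f"noise{i}", rng.normal(0, 0.02, len(r.axis)))
            for i in range(4)
        )
        mixed = Ramanome(r.axis, r.cells + noise_cells)
        cfg = PreprocessConfig(snr_threshold=5.0)
        kept, report = quality_control(mixed, cfg)
        dropped = report[~report["kept"]]
        assert set(dropped["cell_id"]) == {f"noise{i}" for i in range(4)}
        assert (dropped["reason"] == "low_snr").all()

    def test_inverted_spectrum_dropped_as_outlier(self):
        r = _corrected_ramanome(50)
        inverted = r.cells[0].intensities.max() - r.cells[0].intensities
        mixed = Ramanome(r.axis, r.cells + (SingleCellSpectrum("weird", inverted),))
        kept, report = quality_control(mixed)
        row = report[report["cell_id"] == "weird"].iloc[0]
        assert not row["kept"] and row["reason"] == "outlier"

    def test_permissive_thresholds_are_identity(self):
        r = _corrected_ramanome(20)
        cfg = PreprocessConfig(snr_threshold=0.0, outlier_rho=-1.0)
        kept, _ = quality_control(r, cfg)
        assert kept.cell_ids() == r.cell_ids()

    def test_never_increases_count_and_empty_errors(self):
        r = _corrected_ramanome(10)
        kept, _ = quality_control(r)
        assert len(kept) <= len(r)
        with pytest.raises(ValueError):
            quality_control(Ramanome(r.axis, ()))


class TestBandSelect:
    def test_fingerprint_selection(self):
        r = _corrected_ramanome(3)
        out = band_select(r, [FINGERPRINT_BAND])
        assert out.axis.values.min() >= 500 and out.axis.values.max() <= 1800

    def test_cd_ch_union_length(self):
        r = _corrected_ramanome(3)
        out = band_select(r, [CD_BAND, CH_BAND])
        w = r.axis.values
        expected = np.sum(((w >= 2040) & (w <= 2300)) | ((w >= 2800) & (w <= 3100)))
        assert len(out.axis) == expected

    def test_disjoint_band_errors(self):
        r = _corrected_ramanome(3)
        with pytest.raises(ValueError):
            band_select(r, [BandDefinition("nowhere", 9000.0, 9500.0)])


class TestPipeline:
    def test_output_normalized_per_cell(self):
        spec = make_species_spec(9)
        r = simulate_cells(spec, 25, seed=4)
        out, report = preprocess_pipeline(r)
        X = out.to_matrix()
        np.testing.assert_allclose(X.min(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(X.max(axis=1), 1, atol=1e-12)

    def test_noise_cells_are_the_dropped_set(self):
        spec = make_species_spec(9)
        r = simulate_cells(spec, 40, seed=4)
        rng = np.random.default_rng(2)
        noise = tuple(
            SingleCellSpectrum(f"junk{i}", rng.normal(0, 0.02, len(r.axis)))
            for i in range(2)
        )
        mixed = Ramanome(r.axis, r.cells + noise)
        out, report = preprocess_pipeline(mixed, PreprocessConfig(snr_threshold=5.0))
        dropped = set(report.loc[~report["kept"], "cell_id"])
        assert dropped == {"junk0", "junk1"}

    def test_chain_deterministic(self):
        spec = make_species_spec(9)
        r = simulate_cells(spec, 10, seed=5)
        a, _ = preprocess_pipeline(r)
        b, _ = preprocess_pipeline(r)
        np.testing.assert_array_equal(a.to_matrix(), b.to_matrix())

    def test_simulator_output_passes_qc_at_defaults(self):
        spec = make_species_spec(9)
        r = simulate_cells(spec, 50, seed=6)
        out, report = preprocess_pipeline(r)
        assert report["kept"].all()
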