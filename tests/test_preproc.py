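"""Preprocessing tests: referencing, normalization, COW, icoshift, STOCSY,
relative integrals."""

import numpy as np
import pandas as pd
import pytest

from rheumet import SyntheticConfig, simulate_cohort
from rheumet.containers import Spectrum1D, window_mask
from rheumet.preproc import (NoiseSpec, RegionDef, cow_align, icoshift_align,
                             integrate_regions, load_regions,
                             normalize_to_tsp, panel_to_regions,
                             preprocess_set, reference_to_tsp, save_regions,
                             stocsy, _merged_intervals)
from conftest import toy_spectra_set


def lorentz(ppm, center, hw=0.005, area=1.0):
    return area * (hw / np.pi) / ((ppm - center) ** 2 + hw ** 2)


class TestReferencing:
    def test_shifted_apex_moved_to_zero(self):
        ppm = np.linspace(10, -1, 4096)
        s = Spectrum1D(ppm, lorentz(ppm, 0.020), "s")
        out = reference_to_tsp(s)
        apex = out.ppm[np.argmax(out.intensity)]
        assert abs(apex) < 0.005
        assert np.array_equal(out.intensity, s.intensity)

    def test_already_referenced_is_identity(self):
        ppm = np.linspace(10, -1, 8192)
        s = Spectrum1D(ppm, lorentz(ppm, 0.0), "s")
        out = reference_to_tsp(s)
        # parabolic apex of a symmetric peak on-grid: shift ~ 0
        assert np.abs(out.ppm - s.ppm).max() < 1e-3

    def test_flat_spectrum_rejected(self):
        ppm = np.linspace(10, -1, 1024)
        with pytest.raises(ValueError, match="TSP not found"):
            reference_to_tsp(Spectrum1D(ppm, np.ones_like(ppm), "s"))


class TestNormalization:
    def _tsp_spectrum(self, scale=1.0):
        ppm = np.linspace(10, -1, 8192)
        return Spectrum1D(ppm, scale * lorentz(ppm, 0.0, hw=0.003), "s")

    def test_tsp_sum_reaches_target(self):
        s = self._tsp_spectrum(3.7)
        out = normalize_to_tsp(s, target_area=1.0)
        got = out.intensity[window_mask(out.ppm, -0.05, 0.05)].sum()
        assert got == pytest.approx(1.0, rel=1e-9)

    def test_halving(self):
        s = self._tsp_spectrum()
        tsp_sum = s.intensity[window_mask(s.ppm, -0.05, 0.05)].sum()
        out = normalize_to_tsp(s, target_area=tsp_sum / 2)
        assert np.allclose(out.intensity, s.intensity / 2)

    def test_global_factor_invariance(self):
        a = normalize_to_tsp(self._tsp_spectrum(1.0))
        b = normalize_to_tsp(self._tsp_spectrum(3.0))
        assert np.allclose(a.intensity, b.intensity, rtol=1e-9)

    def test_idempotent(self):
        once = normalize_to_tsp(self._tsp_spectrum(2.2))
        twice = normalize_to_tsp(once)
        assert np.allclose(once.intensity, twice.intensity, rtol=1e-12)

    def test_nonpositive_tsp_rejected(self):
        ppm = np.linspace(10, -1, 1024)
        s = Spectrum1D(ppm, -np.abs(lorentz(ppm, 0.0)), "s")
        with pytest.raises(ValueError):
            normalize_to_tsp(s)


class TestCow:
    def _pair(self, n=1024, shift=0):
        ppm = np.linspace(10, 0, n)
        y = sum(lorentz(ppm, c, hw=0.01) for c in (2.0, 4.5, 7.0))
        return (Spectrum1D(ppm, np.roll(y, shift), "t"),
                Spectrum1D(ppm, y, "r"))

    def test_identity_on_equal_input(self):
        t, r = self._pair()
        out = cow_align(Spectrum1D(t.ppm, r.intensity.copy(), "t"), r)
        assert np.allclose(out.intensity, r.intensity)

    def test_recovers_constant_shift(self):
        t, r = self._pair(shift=4)
        before = np.corrcoef(t.intensity, r.intensity)[0, 1]
        out = cow_align(t, r, segment_length=60, slack=5)
        after = np.corrcoef(out.intensity, r.intensity)[0, 1]
        assert after >= before
        assert after >= 0.999

    def test_correlation_never_decreases(self):
        """Identity-warp fallback guarantees the global correlation with
        the reference cannot drop, even on pure-noise input."""
        for seed in range(8):
            rng = np.random.default_rng(seed)
            ppm = np.linspace(5, 0, 512)
            a, b = rng.normal(size=512), rng.normal(size=512)
            out = cow_align(Spectrum1D(ppm, a, "a"), Spectrum1D(ppm, b, "b"),
                            segment_length=40, slack=3)
            assert (np.corrcoef(out.intensity, b)[0, 1]
                    >= np.corrcoef(a, b)[0, 1] - 1e-12)

    def test_infeasible_geometry_rejected(self):
        t, r = self._pair(n=64)
        with pytest.raises(ValueError):
            cow_align(t, r, segment_length=4, slack=3)


class TestIcoshift:
    def test_identical_spectra_zero_lag(self):
        sset = toy_spectra_set(n_samples=4, seed=1)
        sset.matrix[:] = sset.matrix[0]
        out = icoshift_align(sset, [(1.8, 2.2)], max_shift=5)
        assert np.array_equal(out.matrix, sset.matrix)

    def test_planted_shift_recovered(self):
        sset = toy_spectra_set(n_samples=5, seed=2)
        idx = np.flatnonzero(window_mask(sset.ppm, 1.8, 2.2))
        sl = slice(idx.min(), idx.max() + 1)
        # displace sample 0's peak by +5 points within the interval
        seg = sset.matrix[0, sl].copy()
        sset.matrix[0, sl] = np.concatenate([seg[:1].repeat(5), seg[:-5]])
        out = icoshift_align(sset, [(1.8, 2.2)], max_shift=8)
        apexes = [out.ppm[sl][np.argmax(out.matrix[i, sl])]
                  for i in range(5)]
        step = abs(sset.ppm[1] - sset.ppm[0])
        assert abs(apexes[0] - np.median(apexes[1:])) <= step + 1e-12

    def test_short_interval_rejected(self):
        sset = toy_spectra_set()
        with pytest.raises(ValueError):
            icoshift_align(sset, [(2.0, 2.001)], max_shift=2)

    def test_jitter_reduced_by_alignment(self, small_cohort):
        """Mean absolute apex error after icoshift < 1/3 of before under
        the default 0.003 ppm jitter."""
        from rheumet.preproc import _parabolic_apex
        cfg, sset, _ = small_cohort
        regions = panel_to_regions(cfg.panel)
        aligned = icoshift_align(sset, _merged_intervals(regions, 0.0),
                                 max_shift=10)
        centers = [m.center_ppm for m in cfg.panel
                   if m.pattern == "singlet" and m.name != "TSP"]

        def mean_apex_err(mat):
            errs = []
            for row in mat:
                for c in centers:
                    w = np.flatnonzero(
                        window_mask(sset.ppm, c - 0.03, c + 0.03))
                    x, y = sset.ppm[w], row[w]
                    apex = _parabolic_apex(x, y, int(np.argmax(y)))
                    errs.append(abs(apex - c))
            return np.mean(errs)

        assert mean_apex_err(aligned.matrix) \
            < mean_apex_err(sset.matrix) / 3.0

    def test_tsp_window_integral_preserved(self, small_cohort):
        """Alignment leaves the TSP normalization anchor untouched (TSP is
        excluded from the alignment intervals)."""
        cfg, sset, _ = small_cohort
        regions = panel_to_regions(cfg.panel)
        aligned = icoshift_align(sset, _merged_intervals(regions, 0.0),
                                 max_shift=10)
        m = window_mask(sset.ppm, -0.05, 0.05)
        before = sset.matrix[:, m].sum(axis=1)
        after = aligned.matrix[:, m].sum(axis=1)
        assert np.all(np.abs(after - before) <= 0.01 * np.abs(before))


class TestStocsy:
    def test_driver_autocorrelation_is_one(self):
        sset = toy_spectra_set(n_samples=10, seed=3)
        corr, _ = stocsy(sset, 4.5)
        j = int(np.argmin(np.abs(sset.ppm - 4.5)))
        assert corr[j] == pytest.approx(1.0)

    def test_common_source_multiplets_correlate(self):
        rng = np.random.default_rng(4)
        ppm = np.linspace(10, 0, 2048)
        mat = np.zeros((20, ppm.size))
        for i in range(20):
            c = rng.uniform(0.5, 2.0)
            mat[i] = c * (lorentz(ppm, 2.0, 0.01) + lorentz(ppm, 7.0, 0.01))
        meta = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(20)],
             "disease": "RA", "timepoint": "BT", "response": ""},
            index=pd.Index([f"s{i}" for i in range(20)], name="sample_id"))
        from rheumet.containers import SpectraSet
        corr, cov = stocsy(SpectraSet(ppm, mat, meta), 2.0)
        j = int(np.argmin(np.abs(ppm - 7.0)))
        assert corr[j] == pytest.approx(1.0, abs=1e-9)
        assert cov[j] > 0

    def test_noise_region_uncorrelated(self):
        rng = np.random.default_rng(5)
        sset = toy_spectra_set(n_samples=50, seed=6)
        sset.matrix += rng.normal(0, 1e-4, size=sset.matrix.shape)
        corr, _ = stocsy(sset, 2.0)
        noise = window_mask(sset.ppm, 8.5, 9.9)
        assert (np.abs(corr[noise]) < 0.5).mean() > 0.95

    def test_zero_variance_driver_rejected(self):
        sset = toy_spectra_set()
        sset.matrix[:, :] = 1.0
        with pytest.raises(ValueError):
            stocsy(sset, 5.0)


class TestIntegrateRegions:
    def _flat_set(self, level=1.0, noise_level=0.2):
        sset = toy_spectra_set(n_samples=3, n_points=1100)
        sset.matrix[:] = level
        # noise region [9.0, 9.5): constant noise_level
        sset.matrix[:, window_mask(sset.ppm, 9.0, 9.5)] = noise_level
        return sset

    @staticmethod
    def _ten_point_window(sset):
        # window edges aligned to the grid so it holds exactly 10 points
        step = abs(sset.ppm[1] - sset.ppm[0])
        lo = float(sset.ppm[509])        # descending axis: lower edge
        hi = float(sset.ppm[500]) + step / 2
        assert window_mask(sset.ppm, lo, hi).sum() == 10
        return lo, hi

    def test_q3_once_hand_value(self):
        """Flat spectrum at 1.0, 10-point region, constant noise 0.2:
        mode=once gives 10 - 0.2 = 9.8."""
        sset = self._flat_set()
        lo, hi = self._ten_point_window(sset)
        ft = integrate_regions(sset, [RegionDef("r", [(lo, hi)])],
                               NoiseSpec((9.0, 9.5), "once"))
        assert ft.values["r"].iloc[0] == pytest.approx(10 - 0.2)

    def test_q3_per_point_hand_value(self):
        sset = self._flat_set()
        lo, hi = self._ten_point_window(sset)
        ft = integrate_regions(sset, [RegionDef("r", [(lo, hi)])],
                               NoiseSpec((9.0, 9.5), "per_point"))
        assert ft.values["r"].iloc[0] == pytest.approx(10 - 0.2 * 10)

    def test_zero_spectrum_zero_integral(self):
        sset = toy_spectra_set(n_samples=2)
        sset.matrix[:] = 0.0
        ft = integrate_regions(sset, [RegionDef("r", [(2.0, 2.5)])],
                               NoiseSpec((9.0, 9.5), "once"))
        assert np.allclose(ft.values["r"], 0.0)

    def test_additive_over_disjoint_windows(self):
        sset = toy_spectra_set(n_samples=4, seed=8)
        noise = NoiseSpec((9.0, 9.5), "once")
        both = integrate_regions(
            sset, [RegionDef("b", [(1.9, 2.1), (4.4, 4.6)])], noise)
        w1 = integrate_regions(sset, [RegionDef("a", [(1.9, 2.1)])], noise)
        w2 = integrate_regions(sset, [RegionDef("a", [(4.4, 4.6)])], noise)
        # additivity up to one extra Q3 subtraction (mode=once)
        q3 = np.percentile(
            sset.matrix[:, window_mask(sset.ppm, 9.0, 9.5)], 75, axis=1)
        assert np.allclose(both.values["b"],
                           w1.values["a"] + w2.values["a"] + q3)

    def test_off_axis_region_names_offender(self):
        sset = toy_spectra_set()
        with pytest.raises(ValueError, match="badregion"):
            integrate_regions(sset, [RegionDef("badregion", [(90.0, 91.0)])],
                              NoiseSpec((9.0, 9.5)))

    def test_negative_integrals_flagged_not_clipped(self):
        sset = self._flat_set(level=0.0, noise_level=1.0)
        ft = integrate_regions(sset, [RegionDef("r", [(2.0, 2.3)])],
                               NoiseSpec((9.0, 9.5), "once"))
        assert (ft.values["r"] < 0).all()
        assert ft.flags["r"].all()


class TestEndToEnd:
    def test_features_track_true_concentrations(self, small_cohort):
        """Noise-free jittered cohort: every metabolite's relative integral
        correlates with its planted concentration at r > 0.99."""
        cfg, sset, truth = small_cohort
        ft = preprocess_set(sset, panel_to_regions(cfg.panel), NoiseSpec())
        for m in ft.metabolites:
            r = np.corrcoef(ft.values[m], truth.concentrations[m])[0, 1]
            assert r > 0.99, m

    def test_failed_tsp_detection_drops_sample(self, small_cohort):
        cfg, sset, _ = small_cohort
        broken = sset.copy()
        broken.matrix[0, :] = 1.0  # flat: no TSP
        ft = preprocess_set(broken, panel_to_regions(cfg.panel), NoiseSpec())
        assert len(ft.values) == broken.n_samples - 1

    def test_regions_yaml_round_trip(self, panel, tmp_path):
        regions = panel_to_regions(panel)
        path = tmp_path / "regions.yaml"
        save_regions(regions, path)
        loaded = load_regions(path)
        assert [r.name for r in loaded] == [r.name for r in regions]
        assert loaded[0].windows == [tuple(map(float, w))
                                     for w in regions[0].windows]
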