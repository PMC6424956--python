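"""Peak picking, envelope matching and light/heavy ratio recovery."""

import numpy as np
import pytest

from isopair import (
    MissingInternalStandardError,
    QuantSettings,
    SimConfig,
    Spectrum,
    adduct_mz,
    compose_peptide,
    isotope_pattern,
    light_heavy_ratio,
    simulate_spectrum,
)
from isopair.chem import AdductSpecies, IsotopePattern
from isopair.quantify import (
    Peak,
    PeakPair,
    correct_overlap,
    estimate_noise,
    match_envelope,
    pick_peaks,
)


def _flat(mz0=100.0, n=1000, step=0.01, value=0.0):
    mz = mz0 + step * np.arange(n)
    return Spectrum(mz, np.full(n, value))


class TestPickPeaks:
    def test_all_zero_spectrum_yields_nothing(self):
        assert pick_peaks(_flat()) == []

    def test_empty_spectrum_yields_nothing(self):
        assert pick_peaks(Spectrum(np.array([]), np.array([]))) == []

    def test_single_gaussian_centroid_and_area(self, hai_light, clean_config):
        s = simulate_spectrum([(hai_light, 1.0)], clean_config)
        peaks = pick_peaks(s)
        mono = adduct_mz(hai_light.monoisotopic_mass(), "H")
        nearest = min(peaks, key=lambda p: abs(p.centroid_mz - mono))
        assert abs(nearest.centroid_mz - mono) <= clean_config.mz_step / 2
        pat = isotope_pattern(compose_peptide(hai_light))
        expected = clean_config.intensity_scale * pat.abundance(0)
        assert nearest.area == pytest.approx(expected, rel=1e-6)

    def test_equal_gaussians_have_equal_areas(self, hai_light):
        # equal H and Na adduct propensities give two identical-area peaks 22 Da apart
        cfg = SimConfig(mz_range=(920.0, 980.0), adduct_abundances={"H": 0.5, "Na": 0.5},
                        seed=1)
        s = simulate_spectrum([(hai_light, 1.0)], cfg)
        peaks = pick_peaks(s)
        mono_h = adduct_mz(hai_light.monoisotopic_mass(), "H")
        mono_na = adduct_mz(hai_light.monoisotopic_mass(), "Na")
        ph = min(peaks, key=lambda p: abs(p.centroid_mz - mono_h))
        pna = min(peaks, key=lambda p: abs(p.centroid_mz - mono_na))
        assert ph.area == pytest.approx(pna.area, rel=1e-6)

    def test_noise_estimate_robust_to_peaks(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 2.0, 5000)
        x[::100] += 500.0  # sparse tall peaks must not inflate the estimate
        assert estimate_noise(x) == pytest.approx(2.0, rel=0.1)


class TestMatchEnvelope:
    pattern = IsotopePattern((0, 1, 2), (1000.0, 1001.003, 1002.006), (0.6, 0.3, 0.1))

    def _peak(self, mz):
        return Peak(mz, 10.0, 5.0, 100.0)

    def test_exact_positions_all_assigned(self):
        adduct = AdductSpecies("H")
        peaks = [self._peak(adduct_mz(m, adduct)) for m in self.pattern.masses]
        assigned = match_envelope(peaks, self.pattern, adduct, tol=0.15, k_range=3)
        assert sorted(assigned) == [0, 1, 2]

    def test_peak_beyond_tolerance_unassigned(self):
        adduct = AdductSpecies("H")
        peaks = [self._peak(adduct_mz(1000.0, adduct) + 0.151)]
        assigned = match_envelope(peaks, self.pattern, adduct, tol=0.15, k_range=1)
        assert assigned == {}

    def test_nearest_wins_tie_toward_lower_mz(self):
        adduct = AdductSpecies("H")
        target = adduct_mz(1000.0, adduct)
        near, far = self._peak(target + 0.02), self._peak(target - 0.05)
        assert match_envelope([far, near], self.pattern, adduct, k_range=1)[0] is near
        lo, hi = self._peak(target - 0.03), self._peak(target + 0.03)
        assert match_envelope([hi, lo], self.pattern, adduct, k_range=1)[0] is lo

    def test_peak_assigned_at_most_once(self):
        adduct = AdductSpecies("H")
        lone = self._peak(adduct_mz(1000.5, adduct))
        taken: set = set()
        a1 = match_envelope([lone], self.pattern, adduct, tol=0.6, k_range=1, taken=taken)
        a2 = match_envelope([lone], self.pattern, adduct, tol=0.6, k_range=1, taken=taken)
        assert a1 == {0: lone} and a2 == {}


class TestCorrectOverlap:
    light = IsotopePattern(
        (0, 1, 2, 3, 4, 5),
        (3000.0, 3001.0, 3002.0, 3003.0, 3004.0, 3005.0),
        (0.30, 0.30, 0.20, 0.12, 0.05, 0.03),
    )

    def _pair(self, heavy_areas):
        adduct = AdductSpecies("H")
        light_peaks = {0: Peak(3001.007, 10.0, 30.0, 100.0)}
        heavy_peaks = {
            j: Peak(3004.007 + j, 10.0, a, 100.0) for j, a in heavy_areas.items()
        }
        return PeakPair(adduct=adduct, light_peaks=light_peaks, heavy_peaks=heavy_peaks)

    def test_no_tail_leaves_areas_unchanged(self):
        clean = IsotopePattern((0, 1), (3000.0, 3001.0), (0.7, 0.3))
        pair = self._pair({0: 8.0, 1: 4.0})
        out = correct_overlap(clean, pair)
        assert out.heavy_areas == {0: 8.0, 1: 4.0}
        assert out.clipped_offsets == ()

    def test_exact_tail_clips_to_zero_with_flag(self):
        # heavy area equals the predicted light tail: 30 * 0.05/0.30 = 5
        pair = self._pair({0: 5.0})
        out = correct_overlap(self.light, pair)
        assert out.heavy_areas[0] == 0.0
        assert out.clipped_offsets == (0,)

    def test_subtracts_predicted_contribution(self):
        pair = self._pair({0: 8.0, 1: 4.0})
        out = correct_overlap(self.light, pair)
        assert out.heavy_areas[0] == pytest.approx(8.0 - 30.0 * 0.05 / 0.30)
        assert out.heavy_areas[1] == pytest.approx(4.0 - 30.0 * 0.03 / 0.30)

    def test_requires_light_monoisotopic(self):
        pair = PeakPair(adduct=AdductSpecies("H"), heavy_peaks={0: Peak(3004.0, 1, 1, 1)})
        with pytest.raises(ValueError):
            correct_overlap(self.light, pair)


class TestLightHeavyRatio:
    def test_two_to_one_mixture(self, hai_light, hai_heavy, clean_config):
        s = simulate_spectrum([(hai_light, 2.0), (hai_heavy, 1.0)], clean_config)
        res = light_heavy_ratio(s, hai_light, hai_heavy, QuantSettings(correct_overlap=True))
        assert res.ratio == pytest.approx(2.0, rel=1e-6)

    def test_unity_mixture(self, hai_light, hai_heavy, clean_config):
        s = simulate_spectrum([(hai_light, 2.0), (hai_heavy, 2.0)], clean_config)
        res = light_heavy_ratio(s, hai_light, hai_heavy, QuantSettings(correct_overlap=True))
        assert res.ratio == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("true_ratio", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_ratio_recovery_noiseless(self, hai_light, hai_heavy, clean_config, true_ratio):
        s = simulate_spectrum(
            [(hai_light, true_ratio), (hai_heavy, 1.0)], clean_config
        )
        res = light_heavy_ratio(s, hai_light, hai_heavy, QuantSettings(correct_overlap=True))
        assert res.ratio / true_ratio == pytest.approx(1.0, abs=1e-6)

    def test_heavy_only_flags_below_detection(self, hai_light, hai_heavy, clean_config):
        s = simulate_spectrum([(hai_heavy, 1.0)], clean_config)
        res = light_heavy_ratio(s, hai_light, hai_heavy)
        assert res.ratio == 0.0
        assert res.below_detection

    def test_missing_standard_raises_on_empty_spectrum(self, hai_light, hai_heavy):
        empty = _flat(mz0=920.0, n=4000)
        with pytest.raises(MissingInternalStandardError):
            light_heavy_ratio(empty, hai_light, hai_heavy)

    def test_light_tail_alone_is_not_a_standard(self, hai_light, hai_heavy, clean_config):
        """With only light present, the apparent 'heavy' signal is the light
        k>=4 tail; the overlap correction removes it entirely and the missing
        internal standard is detected."""
        s = simulate_spectrum([(hai_light, 1.0)], clean_config)
        with pytest.raises(MissingInternalStandardError):
            light_heavy_ratio(s, hai_light, hai_heavy, QuantSettings(correct_overlap=True))

    def test_scale_invariance(self, hai_light, hai_heavy, clean_config):
        s = simulate_spectrum([(hai_light, 2.0), (hai_heavy, 1.0)], clean_config)
        r1 = light_heavy_ratio(s, hai_light, hai_heavy).ratio
        r2 = light_heavy_ratio(s.scaled(37.5), hai_light, hai_heavy).ratio
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_adduct_independence(self, hai_light, hai_heavy):
        cfg = SimConfig(mz_range=(900.0, 1010.0), seed=3)
        s = simulate_spectrum([(hai_light, 2.0), (hai_heavy, 1.0)], cfg)
        res = light_heavy_ratio(
            s, hai_light, hai_heavy,
            QuantSettings(adducts=("H", "Na", "K"), correct_overlap=True),
        )
        values = list(res.per_adduct.values())
        assert all(v == pytest.approx(values[0], rel=1e-6) for v in values)
        assert res.ratio == pytest.approx(values[0], rel=1e-6)

    def test_same_label_state_rejected(self, hai_light, clean_config):
        s = simulate_spectrum([(hai_light, 1.0)], clean_config)
        with pytest.raises(ValueError):
            light_heavy_ratio(s, hai_light, hai_light)

    def test_noisy_ratio_within_five_percent(self, hai_light, hai_heavy):
        """1% apex noise keeps the measured ratio within +-5% almost always."""
        base = SimConfig(mz_range=(920.0, 960.0), adduct_abundances={"H": 1.0}, seed=0)
        clean = simulate_spectrum([(hai_light, 2.0), (hai_heavy, 2.0)], base)
        apex = float(clean.intensity.max())
        good = 0
        n_rep = 200
        for i in range(n_rep):
            cfg = SimConfig(
                mz_range=(920.0, 960.0), adduct_abundances={"H": 1.0},
                noise_sd=0.01 * apex, seed=10_000 + i,
            )
            s = simulate_spectrum([(hai_light, 2.0), (hai_heavy, 2.0)], cfg)
            r = light_heavy_ratio(s, hai_light, hai_heavy).ratio
            if 0.95 <= r <= 1.05:
                good += 1
        assert good >= int(0.95 * n_rep)
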