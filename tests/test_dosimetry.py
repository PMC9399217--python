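"""Dosimetry: %IA extraction, TIAC fitting, dose sums, weighting schemes."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from petquant.constants import C11_HALF_LIFE_MIN, C11_LAMBDA_PER_MIN
from petquant.dosimetry import (
    SValueTable,
    SourceOrganSeries,
    TIACSet,
    WeightingScheme,
    effective_dose,
    fit_tiac,
    fit_tiac_set,
    load_reference_percent_ia,
    load_toy_svalue_table,
    load_weighting_scheme,
    organ_equivalent_doses,
    percent_ia_from_volumes,
)
from petquant.errors import GeometryError, InvalidInputError
from petquant.image_quant import ImageVolume
from petquant.synthetic_data import SyntheticSubjectSpec, generate_organ_percent_ia


def make_series(times, pia, organ="liver", decay_corrected=True):
    return SourceOrganSeries(organ=organ, times=np.asarray(times, float),
                             percent_ia=np.asarray(pia, float),
                             decay_corrected=decay_corrected)


class TestPercentIAFromVolumes:
    def test_uniform_volume_closed_form(self):
        """Uniform value a, mask fraction f: %IA = 100 a V f / injected."""
        a = 5000.0  # Bq/mL
        shape = (10, 10, 10)
        vol = ImageVolume(data=np.full(shape, a), spacing_mm=(2.0, 2.0, 2.0),
                          mid_time_min=3.0)
        mask = np.zeros(shape, dtype=bool)
        mask[:5] = True  # f = 0.5
        injected = 200.0  # MBq
        series = percent_ia_from_volumes([vol], {"liver": mask}, injected)
        v_total_ml = 1000 * 8.0 / 1000.0  # voxels * voxel volume
        expected = 100.0 * a * v_total_ml * 0.5 / (injected * 1e6)
        liver = [s for s in series if s.organ == "liver"][0]
        assert liver.percent_ia[0] == pytest.approx(expected, rel=1e-12)

    def test_full_mask_leaves_zero_remainder(self):
        shape = (6, 6, 6)
        vol = ImageVolume(data=np.random.default_rng(1).uniform(0, 1e4, shape),
                          spacing_mm=(2.0, 2.0, 2.0), mid_time_min=3.0)
        series = percent_ia_from_volumes([vol], {"body": np.ones(shape, bool)}, 500.0)
        rem = [s for s in series if s.organ == "remainder"][0]
        np.testing.assert_allclose(rem.percent_ia, 0.0, atol=1e-12)

    def test_phantom_region_round_trip(self):
        """%IA recovered from a synthetic phantom's labelled regions
        matches activity * volume / injected ground truth within 2%."""
        from petquant.synthetic_data import generate_dynamic_phantom

        spec = SyntheticSubjectSpec(seed=6, noise_scale=0.0, volume_shape=(64, 64, 64))
        ph = generate_dynamic_phantom(spec)
        masks = {"affected-joint": ph.labels["affected-joint"]}
        series = percent_ia_from_volumes(ph.frames, masks, spec.injected_mbq)
        got = [s for s in series if s.organ == "affected-joint"][0]
        vol_ml = ph.labels["affected-joint"].sum() * ph.frames[0].voxel_volume_ml
        expected = 100.0 * ph.region_tacs["affected-joint"].values * vol_ml \
            / (spec.injected_mbq * 1e6)
        sel = expected > 0
        np.testing.assert_allclose(got.percent_ia[sel], expected[sel], rtol=0.02)

    def test_misaligned_mask_raises(self):
        vol = ImageVolume(data=np.zeros((6, 6, 6)), spacing_mm=(2, 2, 2),
                          mid_time_min=1.0)
        with pytest.raises(GeometryError):
            percent_ia_from_volumes([vol], {"liver": np.ones((5, 5, 5), bool)}, 100.0)


class TestFitTiac:
    def test_constant_series_integrates_to_physical_bound(self):
        """Constant 100 %IA (decay-corrected): residence time is
        T1/2 / ln 2 = 29.38 min = 0.4897 h."""
        t = np.array([3.0, 10.5, 21.0, 41.0, 61.0, 81.0])
        hours = fit_tiac(make_series(t, np.full(6, 100.0)), method="exp-fit")
        assert hours == pytest.approx(C11_HALF_LIFE_MIN / np.log(2.0) / 60.0, rel=1e-3)

    def test_monoexponential_non_corrected_matches_quadrature(self):
        """A0 e^{-lam_eff t} measured (not decay-corrected): integral is
        A0 / lam_eff / 100 minutes, cross-checked by quadrature."""
        lam_eff = 0.06  # > physical lambda, so the corrected curve decays
        a0 = 40.0
        t = np.array([3.0, 10.5, 21.0, 41.0, 61.0, 81.0])
        series = make_series(t, a0 * np.exp(-lam_eff * t), decay_corrected=False)
        hours = fit_tiac(series, method="exp-fit")
        closed_h = a0 / lam_eff / 100.0 / 60.0
        numeric, _ = quad(lambda x: a0 / 100.0 * np.exp(-lam_eff * x), 0, np.inf)
        assert numeric / 60.0 == pytest.approx(closed_h, rel=1e-6)
        assert hours == pytest.approx(closed_h, rel=1e-6)

    def test_zero_series_gives_zero(self):
        t = np.array([3.0, 10.5, 21.0])
        assert fit_tiac(make_series(t, np.zeros(3))) == 0.0

    def test_exp_fit_agrees_with_quadrature_on_reference_organs(self):
        """For every organ of the bundled reference %IA table, analytic
        integration of the fitted model matches adaptive quadrature to
        1e-6 relative."""
        lam = C11_LAMBDA_PER_MIN
        for series in load_reference_percent_ia(decay_corrected=True):
            hours, diag = fit_tiac(series, method="exp-fit", return_details=True)
            amps, rates = diag.amplitudes, diag.rates
            numeric, _ = quad(
                lambda x: float(np.sum(amps * np.exp(-(rates + lam) * x))),
                0, np.inf, limit=200)
            assert hours == pytest.approx(numeric / 60.0, rel=1e-6), series.organ

    def test_growing_tail_falls_back_to_physical_decay(self):
        t = np.array([3.0, 10.5, 21.0, 41.0, 61.0, 81.0])
        rising = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        hours, diag = fit_tiac(make_series(t, rising), method="trapezoid-tail",
                               return_details=True)
        assert diag.physical_tail_fallback
        assert hours > 0

    def test_methods_agree_roughly_on_smooth_decay(self):
        t = np.array([3.0, 10.5, 21.0, 41.0, 61.0, 81.0])
        series = make_series(t, 50.0 * np.exp(-0.01 * t))
        h_exp = fit_tiac(series, method="exp-fit")
        h_trap = fit_tiac(series, method="trapezoid-tail")
        assert h_trap == pytest.approx(h_exp, rel=0.05)

    def test_reference_table_total_below_physical_bound(self):
        """Summed residence times of the reference organ set (decay-
        corrected reading) stay strictly below T1/2 / ln 2."""
        tiacs = fit_tiac_set(load_reference_percent_ia(decay_corrected=True))
        assert tiacs.total_hours() < C11_HALF_LIFE_MIN / np.log(2.0) / 60.0


class TestDoseEngine:
    def toy_table(self):
        df = pd.DataFrame([
            {"source": "organA", "target": "organA", "s_mGy_per_MBq_h": 2.0},
            {"source": "organB", "target": "organA", "s_mGy_per_MBq_h": 1.0},
            {"source": "organA", "target": "organB", "s_mGy_per_MBq_h": 1.0},
            {"source": "organB", "target": "organB", "s_mGy_per_MBq_h": 3.0},
        ])
        mat = df.pivot(index="target", columns="source", values="s_mGy_per_MBq_h")
        return SValueTable(phantom="toy", table=mat)

    def test_hand_matrix_multiply(self):
        """S = [[2,1],[1,3]], TIACs (0.5, 0.25) h -> H = (1.25, 1.25)."""
        tiacs = TIACSet(residence_h={"organA": 0.5, "organB": 0.25}, half_life_min=None)
        doses = organ_equivalent_doses(tiacs, self.toy_table())
        assert doses["organA"] == pytest.approx(1.25)
        assert doses["organB"] == pytest.approx(1.25)

    def test_zero_tiacs_give_zero_doses(self):
        tiacs = TIACSet(residence_h={"organA": 0.0, "organB": 0.0}, half_life_min=None)
        doses = organ_equivalent_doses(tiacs, self.toy_table())
        assert all(v == 0.0 for v in doses.values())

    def test_linearity_in_tiacs(self):
        t1 = TIACSet(residence_h={"organA": 0.1, "organB": 0.2}, half_life_min=None)
        t2 = TIACSet(residence_h={"organA": 0.2, "organB": 0.4}, half_life_min=None)
        d1 = organ_equivalent_doses(t1, self.toy_table())
        d2 = organ_equivalent_doses(t2, self.toy_table())
        for organ in d1:
            assert d2[organ] == pytest.approx(2.0 * d1[organ], rel=1e-12)

    def test_missing_source_routes_to_remainder(self):
        tiacs = TIACSet(residence_h={"brain": 0.01, "liver": 0.02, "spleen": 0.005})
        table = load_toy_svalue_table()
        with pytest.warns(UserWarning, match="spleen"):
            doses = organ_equivalent_doses(tiacs, table)
        assert all(v >= 0 for v in doses.values())

    def test_effective_dose_identity_and_convexity(self):
        scheme = WeightingScheme(name="toy", weights={"organA": 0.6, "organB": 0.4})
        rep = effective_dose({"organA": 1.25, "organB": 1.25}, scheme)
        assert rep.effective == pytest.approx(1.25)
        rep2 = effective_dose({"organA": 2.0, "organB": 1.0}, scheme)
        assert 1.0 <= rep2.effective <= 2.0
        one = WeightingScheme(name="single", weights={"organA": 1.0})
        assert effective_dose({"organA": 0.7}, one).effective == pytest.approx(0.7)

    def test_uniform_doses_give_that_dose_for_any_scheme(self):
        for name in ("icrp60", "icrp103"):
            scheme = load_weighting_scheme(name)
            doses = {t: 1.0 for t in scheme.weights}
            assert effective_dose(doses, scheme).effective == pytest.approx(1.0)

    def test_bundled_schemes_sum_to_one(self):
        for name in ("icrp60", "icrp103"):
            scheme = load_weighting_scheme(name)
            assert sum(scheme.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_schemes_differ_only_through_weights(self):
        """Same organ doses under ICRP 60 vs ICRP 103: only w_T changes
        the effective dose, organ doses pass through untouched."""
        tiacs = fit_tiac_set(load_reference_percent_ia(decay_corrected=True))
        table = load_toy_svalue_table()
        doses = organ_equivalent_doses(tiacs, table)
        with pytest.warns(UserWarning):
            r60 = effective_dose(doses, load_weighting_scheme("icrp60"))
        with pytest.warns(UserWarning):
            r103 = effective_dose(doses, load_weighting_scheme("icrp103"))
        assert r60.organ_doses == r103.organ_doses
        assert r60.effective != r103.effective

    def test_pipeline_linear_in_percent_ia(self):
        """Scaling every %IA by c scales every organ dose and the
        effective dose by c (whole-chain linearity)."""
        spec = SyntheticSubjectSpec(seed=8, noise_scale=0.0)
        base = generate_organ_percent_ia(spec)
        half = [SourceOrganSeries(organ=s.organ, times=s.times,
                                  percent_ia=0.5 * s.percent_ia,
                                  decay_corrected=s.decay_corrected)
                for s in base]
        table = load_toy_svalue_table()
        d1 = organ_equivalent_doses(fit_tiac_set(base), table)
        d2 = organ_equivalent_doses(fit_tiac_set(half), table)
        for organ in d1:
            assert d2[organ] == pytest.approx(0.5 * d1[organ], rel=1e-6)

    def test_negative_total_residence_rejected(self):
        bound_h = C11_HALF_LIFE_MIN / np.log(2.0) / 60.0
        with pytest.raises(InvalidInputError):
            TIACSet(residence_h={"a": bound_h, "b": 0.01})


class TestWeightingSchemeValidation:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            WeightingScheme(name="bad", weights={"a": 0.5, "b": 0.3})

    def test_negative_weight_rejected(self):
        with pytest.raises(InvalidInputError):
            WeightingScheme(name="bad", weights={"a": 1.5, "b": -0.5})
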