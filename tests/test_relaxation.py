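"""hetNOE/HDX classification semantics and CPMG dispersion model/fit checks."""
import numpy as np
import pytest

from glucnmr import relaxation, synthetic
from glucnmr.relaxation import (
    CpmgSeries,
    HdxRecord,
    HetNoeProfile,
    carver_richards_r2eff,
    classify_flexible,
    classify_hdx,
    delta_r2,
    fit_two_state,
    interpolate_missing_noe,
    luz_meiboom_r2eff,
    r2eff_from_intensities,
)

RATES = np.asarray(relaxation.STUDY_CPMG_RATES, dtype=float)


def series_from_forward(seq_id, r20, phi, kex, rates=RATES, t_relax=0.040):
    r2 = luz_meiboom_r2eff(rates, r20, phi, kex)
    return CpmgSeries(
        seq_id=seq_id, rates=rates, intensities=np.exp(-r2 * t_relax),
        intensity_ref=1.0, t_relax=t_relax,
    )


class TestInterpolation:
    def test_complete_profile_unchanged(self):
        p = HetNoeProfile(seq_ids=[1, 2, 3], values=[0.8, 0.7, 0.6])
        out = interpolate_missing_noe(p)
        np.testing.assert_allclose(out.values, [0.8, 0.7, 0.6])
        assert out.provenance == ["measured"] * 3

    def test_single_gap_is_flanking_mean(self):
        p = HetNoeProfile(seq_ids=[1, 2, 3], values=[0.8, np.nan, 0.6])
        out = interpolate_missing_noe(p)
        assert out.values[1] == pytest.approx(0.7)
        assert out.provenance[1] == "interpolated"

    def test_double_gap_both_get_nearest_neighbour_mean(self):
        p = HetNoeProfile(seq_ids=[1, 2, 3, 4], values=[0.8, np.nan, np.nan, 0.6])
        out = interpolate_missing_noe(p)
        np.testing.assert_allclose(out.values[1:3], [0.7, 0.7])

    def test_leading_and_trailing_gaps_stay_missing(self):
        p = HetNoeProfile(seq_ids=[1, 2, 3], values=[np.nan, 0.7, np.nan])
        out = interpolate_missing_noe(p)
        assert np.isnan(out.values[0]) and np.isnan(out.values[2])


class TestClassification:
    @pytest.mark.parametrize(
        "noe,label",
        [(0.8, "rigid"), (-0.2, "flexible"), (0.5, "rigid"), (0.4999, "flexible")],
    )
    def test_noe_threshold_is_strict(self, noe, label):
        p = HetNoeProfile(seq_ids=[1], values=[noe])
        assert classify_flexible(p)[1] == label

    def test_missing_left_unlabeled(self):
        p = HetNoeProfile(seq_ids=[1, 2], values=[np.nan, 0.8])
        labels = classify_flexible(p)
        assert 1 not in labels and labels[2] == "rigid"

    @pytest.mark.parametrize(
        "r20m,r18h,cls",
        [(False, False, "fast"), (True, False, "protected_20min"), (True, True, "protected_18h")],
    )
    def test_hdx_classes(self, r20m, r18h, cls):
        rec = HdxRecord(seq_id=60, retained_20min=r20m, retained_18h=r18h)
        assert classify_hdx([rec])[60] == cls

    def test_hdx_inconsistent_record_errors(self):
        with pytest.raises(ValueError, match="time-course"):
            HdxRecord(seq_id=1, retained_20min=False, retained_18h=True)


class TestR2eff:
    def test_reference_intensity_gives_zero(self):
        s = CpmgSeries(1, [50.0, 1000.0], [1.0, 1.0], intensity_ref=1.0)
        np.testing.assert_allclose(r2eff_from_intensities(s), 0.0)

    def test_closed_form_values(self):
        s = CpmgSeries(1, [50.0, 100.0], [np.exp(-1.0), 0.5], intensity_ref=1.0, t_relax=0.040)
        r2 = r2eff_from_intensities(s)
        assert r2[0] == pytest.approx(25.0)
        assert r2[1] == pytest.approx(np.log(2) / 0.04, abs=0.01)  # 17.33 1/s

    def test_nonpositive_intensity_names_rate(self):
        s = CpmgSeries(1, [50.0, 1000.0], [0.9, -0.1], intensity_ref=1.0)
        with pytest.raises(ValueError, match="1000"):
            r2eff_from_intensities(s)


class TestLuzMeiboomModel:
    def test_fast_pulsing_limit_recovers_r20(self):
        assert luz_meiboom_r2eff(1e5, 12.0, 2e4, 2500.0) == pytest.approx(12.0, abs=1e-3)

    def test_slow_pulsing_limit_adds_phi_over_kex(self):
        val = luz_meiboom_r2eff(1e-3, 12.0, 2e4, 2500.0)
        assert val == pytest.approx(12.0 + 2e4 / 2500.0, abs=1e-4)

    def test_monotone_non_increasing_in_rate(self):
        nu = np.logspace(0, 4, 200)
        r2 = luz_meiboom_r2eff(nu, 10.0, 3e4, 2500.0)
        assert np.all(np.diff(r2) <= 1e-12)

    def test_carver_richards_fast_exchange_limit(self):
        nu = np.array([50.0, 100.0, 200.0, 400.0, 1000.0])
        kex, pa, dw = 5000.0, 0.97, 150.0
        phi = pa * (1 - pa) * dw**2
        lm = luz_meiboom_r2eff(nu, 10.0, phi, kex)
        cr = carver_richards_r2eff(nu, 10.0, kex, pa, dw)
        np.testing.assert_allclose(cr, lm, rtol=2e-3)


class TestDeltaR2:
    def test_flat_series_not_flagged(self):
        s = CpmgSeries(1, RATES, np.full(len(RATES), 0.8), intensity_ref=1.0)
        rows = delta_r2([s])
        assert rows[0]["delta_r2"] == pytest.approx(0.0)
        assert not rows[0]["flagged"]

    def test_exchange_produces_flag(self):
        s = series_from_forward(1, 12.0, 1e4, 2500.0)
        rows = delta_r2([s])
        assert rows[0]["delta_r2"] > 2.0
        assert rows[0]["flagged"]

    def test_boundary_value_not_flagged(self):
        # the flag is strict ">": a residue sitting exactly at the threshold
        # is excluded, one epsilon above is included
        t = 0.040
        i50 = np.exp(-(10.0 + 2.0) * t)
        i1000 = np.exp(-10.0 * t)
        s = CpmgSeries(1, [50.0, 1000.0], [i50, i1000], intensity_ref=1.0, t_relax=t)
        d0 = delta_r2([s])[0]["delta_r2"]
        assert d0 == pytest.approx(2.0, abs=1e-12)
        assert not delta_r2([s], threshold=d0)[0]["flagged"]
        assert delta_r2([s], threshold=np.nextafter(d0, 0))[0]["flagged"]

    def test_missing_endpoint_skipped_with_warning(self):
        s = CpmgSeries(1, [100.0, 200.0, 400.0, 800.0], [0.8] * 4, intensity_ref=1.0)
        with pytest.warns(UserWarning, match="skipped"):
            assert delta_r2([s]) == []

    def test_zero_phi_forward_model_gives_zero_delta(self):
        s = series_from_forward(1, 15.0, 0.0, 2500.0)
        assert delta_r2([s])[0]["delta_r2"] == pytest.approx(0.0, abs=1e-10)


class TestFitTwoState:
    def test_noiseless_recovery_within_one_percent(self):
        rng = np.random.default_rng(5)
        phis = rng.uniform(5e3, 5e4, size=5)
        series = [series_from_forward(i + 1, 10.0 + i, p, 2500.0) for i, p in enumerate(phis)]
        fit = fit_two_state(series, n_bootstrap=0)
        assert fit.identifiable
        assert fit.kex == pytest.approx(2500.0, rel=0.01)
        np.testing.assert_allclose(fit.r20, [10.0 + i for i in range(5)], atol=0.05)
        np.testing.assert_allclose(fit.phiex, phis, rtol=0.02)

    def test_noisy_median_recovery(self):
        errs = []
        for rep in range(15):
            rng = np.random.default_rng(700 + rep)
            residues = tuple(
                (i + 1, 10.0 + 2 * i, float(rng.uniform(5e3, 5e4))) for i in range(5)
            )
            spec = synthetic.DispersionSpec(
                residues=residues, kex=2500.0, noise=0.02, seed=800 + rep
            )
            fit = fit_two_state(synthetic.make_dispersion_dataset(spec), n_bootstrap=0)
            errs.append(abs(fit.kex - 2500.0) / 2500.0)
        assert np.median(errs) <= 0.20

    def test_bootstrap_covers_truth(self):
        covered = 0
        n_rep = 15
        for rep in range(n_rep):
            rng = np.random.default_rng(40 + rep)
            residues = tuple(
                (i + 1, 10.0 + 2 * i, float(rng.uniform(5e3, 5e4))) for i in range(5)
            )
            spec = synthetic.DispersionSpec(
                residues=residues, kex=2500.0, noise=0.02, seed=140 + rep
            )
            fit = fit_two_state(
                synthetic.make_dispersion_dataset(spec), n_bootstrap=200, seed=rep
            )
            if np.isfinite(fit.kex_sd) and abs(fit.kex - 2500.0) <= 1.4 * fit.kex_sd:
                covered += 1
        assert covered >= round(0.8 * n_rep)

    def test_flat_data_marked_unidentifiable(self):
        series = [series_from_forward(i + 1, 12.0 + i, 0.0, 2500.0) for i in range(3)]
        fit = fit_two_state(series, n_bootstrap=0)
        assert not fit.identifiable
        np.testing.assert_allclose(fit.r20, [12.0, 13.0, 14.0], atol=1e-6)

    def test_too_few_rates_errors(self):
        s = CpmgSeries(1, [50.0, 100.0, 1000.0], [0.8] * 3, intensity_ref=1.0)
        with pytest.raises(ValueError, match=">= 4"):
            fit_two_state([s])

    def test_general_model_matches_fast_exchange_on_fast_data(self):
        series = [series_from_forward(i + 1, 10.0, 2e4 + 5e3 * i, 2500.0) for i in range(4)]
        fit = fit_two_state(series, model="general", n_bootstrap=0)
        assert fit.model == "general"
        assert fit.kex == pytest.approx(2500.0, rel=0.1)

    def test_fitted_curves_monotone_non_increasing(self):
        rng = np.random.default_rng(9)
        residues = tuple((i + 1, 12.0, float(rng.uniform(1e4, 4e4))) for i in range(3))
        spec = synthetic.DispersionSpec(residues=residues, kex=3000.0, noise=0.01, seed=2)
        fit = fit_two_state(synthetic.make_dispersion_dataset(spec), n_bootstrap=0)
        nu = np.logspace(1, 4, 100)
        for r20, phi in zip(fit.r20, fit.phiex):
            curve = luz_meiboom_r2eff(nu, r20, phi, fit.kex)
            assert np.all(np.diff(curve) <= 1e-10)
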