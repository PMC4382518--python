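import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kturnfold.errors import InputError
from kturnfold.synthetic_data import TitrationSpec, simulate_titration
from kturnfold.titration import (
    TitrationCurve,
    bootstrap_ci,
    fit_titration,
    fit_report_text,
    half_point,
    model_efret,
    read_titration_table,
    write_titration_table,
)


def make_curve(E0=0.2, dE=0.36, KA=1 / 70.0, n=1.0, n_points=12, noise_sd=0.0,
               seed=0, **kw):
    return simulate_titration(TitrationSpec(E0=E0, dE=dE, KA=KA, n=n,
                                            n_points=n_points, noise_sd=noise_sd,
                                            seed=seed, **kw))


class TestModel:
    def test_zero_concentration_gives_E0(self):
        assert model_efret(0.2, 0.36, 1 / 70, 1.0, 0.0) == pytest.approx(0.2)

    def test_half_point_gives_midpoint_exactly(self):
        KA, n = 0.004, 1.7
        c_half = (1 / KA) ** (1 / n)
        e = model_efret(0.15, 0.4, KA, n, c_half)
        assert e == pytest.approx(0.15 + 0.2, abs=1e-12)

    def test_simple_substitution(self):
        # n=1, KA=1/90 per μM, conc=90 μM → E0 + dE/2
        assert model_efret(0.2, 0.3, 1 / 90, 1.0, 90.0) == pytest.approx(0.35)

    def test_saturation_limit(self):
        assert model_efret(0.2, 0.36, 1 / 70, 1.0, 1e12) == pytest.approx(0.56, abs=1e-9)

    def test_monotone_when_dE_positive(self):
        c = np.logspace(-2, 4, 50)
        e = model_efret(0.2, 0.36, 1 / 70, 1.3, c)
        assert np.all(np.diff(e) > 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InputError):
            model_efret(0.2, 0.36, 1 / 70, 1.0, -1.0)

    def test_nonpositive_KA_rejected(self):
        with pytest.raises(InputError):
            model_efret(0.2, 0.36, 0.0, 1.0, 1.0)

    @settings(max_examples=100, deadline=None)
    @given(
        E0=st.floats(0.0, 0.5),
        dE=st.floats(0.05, 0.6),
        KA=st.floats(1e-6, 1e3),
        n=st.floats(0.3, 5.0),
    )
    def test_half_point_identity_property(self, E0, dE, KA, n):
        c_half = half_point(KA, n)
        assert model_efret(E0, dE, KA, n, c_half) == pytest.approx(
            E0 + dE / 2, abs=1e-12
        )


class TestHalfPoint:
    def test_ka_one_over_90(self):
        assert half_point(1 / 90, 1.0) == pytest.approx(90.0)

    def test_ka_one_is_identity(self):
        for n in (0.5, 1.0, 2.0, 3.7):
            assert half_point(1.0, n) == pytest.approx(1.0)

    def test_hand_computed(self):
        assert half_point(4.0, 2.0) == pytest.approx(0.5)  # (1/4)^(1/2)

    def test_domain_errors(self):
        with pytest.raises(InputError):
            half_point(0.0, 1.0)
        with pytest.raises(InputError):
            half_point(1.0, 0.0)
        with pytest.raises(InputError):
            half_point(-2.0, 1.0)


class TestCurve:
    def test_sorted_on_ingestion(self):
        curve = TitrationCurve(np.array([10.0, 1.0, 100.0]),
                               np.array([0.3, 0.2, 0.5]))
        assert list(curve.concentrations) == [1.0, 10.0, 100.0]
        assert list(curve.efret) == [0.2, 0.3, 0.5]

    def test_negative_concentration_rejected(self):
        with pytest.raises(InputError):
            TitrationCurve(np.array([-1.0, 1.0]), np.array([0.2, 0.3]))

    def test_efret_out_of_range_rejected(self):
        with pytest.raises(InputError):
            TitrationCurve(np.array([1.0, 2.0]), np.array([0.2, 1.5]))

    def test_unit_conversion(self):
        curve = make_curve()
        mm = curve.converted("mM")
        assert mm.unit == "mM"
        np.testing.assert_allclose(mm.concentrations * 1000, curve.concentrations)


class TestFit:
    def test_noise_free_round_trip(self):
        # generating values mimic the best-folding titration: 0.2 → 0.56
        curve = make_curve(E0=0.2, dE=0.36, KA=1 / 70.0, n=1.0)
        fit = fit_titration(curve)
        assert fit.E0 == pytest.approx(0.2, rel=1e-6)
        assert fit.dE == pytest.approx(0.36, rel=1e-6)
        assert fit.KA == pytest.approx(1 / 70.0, rel=1e-6)
        assert fit.n == pytest.approx(1.0, rel=1e-6)
        assert fit.half_point == pytest.approx(70.0, rel=1e-6)

    def test_noise_free_cooperative(self):
        curve = make_curve(KA=(1 / 200.0) ** 1.8, n=1.8)
        fit = fit_titration(curve)
        assert fit.half_point == pytest.approx(200.0, rel=1e-5)
        assert fit.n == pytest.approx(1.8, rel=1e-5)

    def test_half_point_identity_on_fit(self):
        curve = make_curve(noise_sd=0.02, seed=7)
        fit = fit_titration(curve)
        assert model_efret(fit.E0, fit.dE, fit.KA, fit.n, fit.half_point) == (
            pytest.approx(fit.E0 + fit.dE / 2, abs=1e-12)
        )

    def test_fitted_curve_monotone_over_data_range(self):
        curve = make_curve(noise_sd=0.02, seed=3)
        fit = fit_titration(curve)
        if fit.dE > 0:
            grid = np.linspace(curve.concentrations.min(),
                               curve.concentrations.max(), 200)
            assert np.all(np.diff(fit.predict(grid)) >= -1e-12)

    def test_noisy_recovery_small_study(self):
        # steep generating curve; the full 200-seed study lives in the
        # acceptance suite
        hits = 0
        for seed in range(30):
            curve = make_curve(dE=0.6, KA=(1 / 70.0) ** 3, n=3.0, noise_sd=0.02,
                               seed=seed, conc_min=7.0, conc_max=700.0)
            fit = fit_titration(curve)
            if abs(fit.half_point - 70.0) / 70.0 <= 0.10:
                hits += 1
        assert hits >= 28

    def test_four_points_rejected(self):
        with pytest.raises(InputError):
            fit_titration(TitrationCurve(np.logspace(0, 3, 4),
                                         np.array([0.2, 0.3, 0.4, 0.5])))

    def test_narrow_range_rejected(self):
        with pytest.raises(InputError):
            fit_titration(TitrationCurve(np.linspace(50, 90, 6),
                                         np.linspace(0.2, 0.5, 6)))

    def test_flat_curve_flagged_no_transition(self):
        rng = np.random.default_rng(0)
        conc = np.logspace(0, 3, 10)
        efret = 0.25 + rng.normal(0, 0.005, size=10)
        fit = fit_titration(TitrationCurve(conc, efret))
        assert abs(fit.dE) < 0.05
        assert "no transition" in fit.flags

    def test_fix_n(self):
        curve = make_curve(noise_sd=0.01, seed=5)
        fit = fit_titration(curve, fix_n=1.0)
        assert fit.n == 1.0

    def test_unit_equivariance(self):
        curve = make_curve()
        fit_um = fit_titration(curve)
        fit_mm = fit_titration(curve.converted("mM"))
        assert fit_mm.KA == pytest.approx(fit_um.KA * 1000 ** fit_mm.n, rel=1e-4)
        assert fit_mm.half_point * 1000 == pytest.approx(fit_um.half_point, rel=1e-5)

    def test_protein_ligand_same_model(self):
        curve = make_curve(ligand_name="L7Ae", unit="uM", KA=1 / 5.0)
        fit = fit_titration(curve)
        assert fit.ligand_name == "L7Ae"
        assert fit.half_point == pytest.approx(5.0, rel=1e-6)


class TestBootstrap:
    def test_noise_free_intervals_near_zero_width(self):
        curve = make_curve()
        fit = fit_titration(curve)
        ci = bootstrap_ci(curve, fit, n_boot=60, seed=1)
        lo, hi = ci["half_point"]
        assert hi - lo < 1e-5

    def test_deterministic_given_seed(self):
        curve = make_curve(noise_sd=0.02, seed=11)
        fit1 = fit_titration(curve)
        ci1 = bootstrap_ci(curve, fit1, n_boot=60, seed=42)
        fit2 = fit_titration(curve)
        ci2 = bootstrap_ci(curve, fit2, n_boot=60, seed=42)
        assert ci1 == ci2

    def test_small_n_boot_warns(self):
        curve = make_curve(noise_sd=0.02, seed=2)
        fit = fit_titration(curve)
        bootstrap_ci(curve, fit, n_boot=20, seed=0)
        assert any("n_boot" in f for f in fit.flags)

    def test_coverage(self):
        covered = 0
        reps = 40
        for seed in range(reps):
            curve = make_curve(dE=0.6, KA=(1 / 70.0) ** 3, n=3.0, noise_sd=0.02,
                               seed=seed, conc_min=7.0, conc_max=700.0)
            fit = fit_titration(curve)
            ci = bootstrap_ci(curve, fit, n_boot=120, seed=seed + 1000)
            lo, hi = ci["half_point"]
            if lo <= 70.0 <= hi:
                covered += 1
        assert covered >= math.floor(0.9 * reps)


class TestTableIO:
    def test_round_trip(self, tmp_path):
        curve = make_curve(noise_sd=0.02, seed=4, ligand_name="Na+", unit="mM")
        path = tmp_path / "titration.tsv"
        write_titration_table(curve, path)
        back = read_titration_table(path)
        assert back.ligand_name == "Na+"
        assert back.unit == "mM"
        np.testing.assert_allclose(back.concentrations, curve.concentrations,
                                   rtol=1e-9)
        np.testing.assert_allclose(back.efret, curve.efret, rtol=1e-9)

    def test_comma_separated_accepted(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("# ligand=Mg2+ unit=uM\nconcentration,efret\n"
                        + "\n".join(f"{c},{0.2 + 0.01 * i}" for i, c in
                                    enumerate([1, 10, 100, 1000, 10000])))
        curve = read_titration_table(path)
        assert len(curve) == 5

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("conc\tsignal\n1\t0.2\n")
        with pytest.raises(InputError):
            read_titration_table(path)

    def test_report_text(self):
        curve = make_curve()
        fit = fit_titration(curve)
        report = fit_report_text(fit)
        assert "half_point=" in report
        assert "hill_n=" in report
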