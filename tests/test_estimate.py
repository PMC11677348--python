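"""Permeability estimation, grid prediction and RMSE validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdmcell import (
    Conditions,
    ExperimentRecord,
    FeedState,
    Membrane,
    fit_Ls,
    fit_Lv,
    fit_membrane,
    invert_Ls,
    predict_rejection_grid,
    rmse,
    study_emulation_suite,
    validate,
)
from sdmcell import fixtures
from sdmcell.transport import (
    mass_transfer_coefficient,
    observed_rejection_closed_form,
    solve_local_transport,
)
from sdmcell.units import bar_to_pa, m_s_to_lmh, rpm_to_rad_s


class TestRmse:
    def test_identical_vectors_give_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_residuals_give_one(self):
        assert rmse([1.0, 1.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_single_pair(self):
        assert rmse([3.0], [0.0]) == pytest.approx(3.0)

    def test_frozen_five_pair_hand_oracle(self):
        pred = [0.2, 1.5, 3.0, 0.7, 2.2]
        obs = [0.0, 1.0, 2.5, 1.0, 2.0]
        assert rmse(pred, obs) == pytest.approx(0.36606010435446257, rel=1e-12)

    @given(
        data=st.lists(
            st.tuples(st.floats(-10, 10), st.floats(-10, 10)), min_size=1, max_size=20
        ),
        scale=st.floats(0.1, 10),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=50, deadline=None)
    def test_order_invariance_and_residual_scaling(self, data, scale, seed):
        pred, obs = map(np.array, zip(*data))
        base = rmse(pred, obs)
        perm = np.random.default_rng(seed).permutation(len(pred))
        assert rmse(pred[perm], obs[perm]) == pytest.approx(base, rel=1e-9, abs=1e-12)
        assert rmse(obs + scale * (pred - obs), obs) == pytest.approx(
            scale * base, rel=1e-9, abs=1e-12
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([], [])


class TestInvertLs:
    def test_full_rejection_gives_zero_permeability(self):
        assert invert_Ls(1.0, 1e-5, 1e-4) == 0.0

    def test_half_rejection_without_polarization_gives_jv(self):
        assert invert_Ls(0.5, 1e-5, 1e9) == pytest.approx(1e-5, rel=1e-9)

    def test_zero_rejection_rejected(self):
        with pytest.raises(ValueError):
            invert_Ls(0.0, 1e-5, 1e-4)

    def test_round_trip_through_local_solver(self, solutes, geometry, salt_membrane):
        for ls_true in (1e-7, 1e-6, 3e-6):
            mem = salt_membrane.with_Ls("Caffeine", ls_true)
            feed = FeedState(300e-6, {"NaCl": 0.5, "Caffeine": 50e-9})
            cond = Conditions(delta_p=1e6, stirring_speed=rpm_to_rad_s(300))
            state = solve_local_transport(feed, mem, cond, geometry, solutes)
            r_obs = state.rejection("Caffeine", 50e-9)
            recovered = invert_Ls(r_obs, state.Jv, state.solutes["Caffeine"].k)
            assert recovered == pytest.approx(ls_true, rel=1e-8)


def _single_point_record(solutes, geometry, jv, r_obs, cb=0.5, cp=0.13,
                         rpm=300.0, label="pt"):
    """Minimal one-sample record with given flux and rejection."""
    df = pd.DataFrame(
        {
            "vcf": [1.0],
            "permeate_volume_mL": [0.0],
            "water_flux_LMH": [m_s_to_lmh(jv)],
            "NaCl_feed_mg_L": [cb * 1e3],
            "NaCl_permeate_mg_L": [cp * 1e3],
        }
    )
    return ExperimentRecord(
        label=label,
        conditions=Conditions(delta_p=bar_to_pa(10), stirring_speed=rpm_to_rad_s(rpm)),
        geometry=geometry,
        feed=FeedState(geometry.initial_feed_volume, {"NaCl": cb}),
        flux_series=df,
        rejections={"Caffeine": r_obs},
    )


class TestFitLv:
    def test_noise_free_round_trip(self, solutes):
        truth, recs = study_emulation_suite(seed=0, membrane_class="NF", noise_cv=0.0)
        for rec in recs:
            assert fit_Lv(rec, solutes) == pytest.approx(truth.Lv, rel=1e-8)

    def test_pure_water_record_reduces_to_flux_over_pressure(self, solutes, geometry):
        jv = 1.4e-5
        rec = _single_point_record(solutes, geometry, jv, 0.8, cb=1e-12, cp=0.0)
        assert fit_Lv(rec, solutes) == pytest.approx(jv / bar_to_pa(10), rel=1e-9)

    def test_consistent_two_point_series_gives_single_lv(self, solutes, geometry):
        # two samples generated from one Lv must return exactly that Lv
        truth, recs = study_emulation_suite(seed=0, membrane_class="NF", noise_cv=0.0)
        rec = recs[0]
        two = rec.flux_series.iloc[[2, 7]].reset_index(drop=True)
        rec2 = ExperimentRecord(rec.label, rec.conditions, rec.geometry, rec.feed,
                                two, rec.rejections)
        assert fit_Lv(rec2, solutes) == pytest.approx(truth.Lv, rel=1e-8)


class TestFitLs:
    def test_single_sample_record_reduces_to_analytic_inversion(
        self, solutes, geometry
    ):
        jv, r_obs = 1.4e-5, 0.85
        rec = _single_point_record(solutes, geometry, jv, r_obs)
        k = mass_transfer_coefficient(solutes["Caffeine"], rec.conditions, geometry)
        fit = fit_Ls([rec], solutes["Caffeine"])
        assert fit.identifiable
        assert fit.value == pytest.approx(invert_Ls(r_obs, jv, k), rel=1e-10)

    def test_noise_free_two_record_recovery_is_exact(self, solutes):
        truth, recs = study_emulation_suite(seed=0, membrane_class="NF", noise_cv=0.0)
        fitted = fit_membrane(recs, solutes, "fit", "NF")
        for name, ls_true in truth.Ls_by_solute.items():
            assert fitted.Ls_by_solute[name] == pytest.approx(ls_true, rel=1e-8)

    def test_one_percent_noise_recovery_within_five_percent(self, solutes):
        # 10 seeded replicates, trace compounds: median relative error < 5 %
        errs = []
        name = "Caffeine"
        for seed in range(1, 11):
            truth, recs = study_emulation_suite(seed=seed, membrane_class="NF",
                                                noise_cv=0.01)
            fit = fit_Ls(recs, solutes[name])
            errs.append(abs(fit.value - truth.Ls_by_solute[name])
                        / truth.Ls_by_solute[name])
        assert np.median(errs) < 0.05

    def test_saturated_rejections_flagged_non_identifiable(self, solutes, geometry):
        rec = _single_point_record(solutes, geometry, 1.4e-5, 1.0)
        fit = fit_Ls([rec], solutes["Caffeine"])
        assert not fit.identifiable
        assert fit.value == 0.0


@pytest.fixture(scope="module")
def grid(solutes):
    mem = fixtures.reference_membrane("NF")
    feed = FeedState(300e-6, {"NaCl": 0.5, "Caffeine": 50e-9, "Iopromide": 50e-9})
    # pressures kept in the stirring-controlled regime (Jv < k), where
    # the closed form guarantees both monotonicities
    return predict_rejection_grid(
        mem, solutes, pressures_bar=[4.0, 6.0, 8.0], rpms=[250.0, 300.0, 450.0],
        feed=feed, geometry=fixtures.study_geometry(), stop_vcf=4.0,
    )


class TestPredictionGrid:
    def test_rejection_nondecreasing_in_rpm_and_pressure(self, grid):
        for name in ("Caffeine", "Iopromide"):
            sub = grid[grid["solute"] == name]
            for _, g in sub.groupby("pressure_bar"):
                assert np.all(np.diff(g.sort_values("rpm")["predicted_rejection_pct"]) >= 0)
            for _, g in sub.groupby("rpm"):
                assert np.all(
                    np.diff(g.sort_values("pressure_bar")["predicted_rejection_pct"]) >= 0
                )

    def test_larger_ls_predicts_smaller_rejection(self, grid, solutes):
        ls = fixtures.load_ls_values()["NF"]
        # Caffeine is more permeable than Iopromide on this membrane
        assert ls["Caffeine"] > ls["Iopromide"]
        for (_, _), g in grid.groupby(["pressure_bar", "rpm"]):
            caff = g[g["solute"] == "Caffeine"]["predicted_rejection_pct"].item()
            iop = g[g["solute"] == "Iopromide"]["predicted_rejection_pct"].item()
            assert caff < iop

    def test_zero_ls_row_rejects_everything(self, solutes):
        mem = Membrane("m", "NF", 1.45e-11, {"NaCl": 3.5e-6, "Caffeine": 0.0})
        feed = FeedState(300e-6, {"NaCl": 0.5, "Caffeine": 50e-9})
        grid = predict_rejection_grid(
            mem, solutes, [10.0], [300.0], feed, fixtures.study_geometry(),
            stop_vcf=3.0,
        )
        caff = grid[grid["solute"] == "Caffeine"]
        assert (caff["predicted_rejection_pct"] == 100.0).all()

    def test_infeasible_points_marked_not_dropped(self, solutes):
        mem = Membrane("m", "NF", 1.45e-11, {"NaCl": 0.0})
        feed = FeedState(300e-6, {"NaCl": 0.5})  # π ≈ 0.42 bar
        grid = predict_rejection_grid(
            mem, solutes, [0.1, 10.0], [300.0], feed, fixtures.study_geometry(),
            stop_vcf=2.0,
        )
        bad = grid[grid["pressure_bar"] == 0.1]
        assert len(bad) == 1 and not bad["feasible"].item()
        assert np.isnan(bad["predicted_rejection_pct"].item())

    def test_empty_grid_rejected(self, solutes):
        with pytest.raises(ValueError):
            predict_rejection_grid(
                fixtures.reference_membrane("NF"), solutes, [], [300.0],
                FeedState(300e-6, {"NaCl": 0.5}), fixtures.study_geometry(),
            )


class TestValidate:
    def test_noise_free_self_validation_has_zero_rmse(self, solutes):
        truth, recs = study_emulation_suite(seed=0, membrane_class="NF", noise_cv=0.0)
        report = validate(truth, recs, solutes)
        assert report.rmse == pytest.approx(0.0, abs=1e-10)
        assert report.n == sum(len(r.rejections) for r in recs)

    def test_held_out_conditions_rmse_below_noise_scale(self, solutes):
        from sdmcell.synth import NoiseModel, generate_experiment

        truth, recs = study_emulation_suite(seed=3, membrane_class="NF", noise_cv=0.01)
        fitted = fit_membrane(recs, solutes, "fit", "NF")
        held_out = generate_experiment(
            truth,
            Conditions(delta_p=bar_to_pa(8), stirring_speed=rpm_to_rad_s(250)),
            fixtures.study_geometry(),
            fixtures.study_feed(),
            solutes,
            NoiseModel(0.01, 0.01, seed=99),
            label="held-out 8 bar 250 rpm",
        )
        report = validate(fitted, [held_out], solutes)
        assert report.rmse < 0.01

    def test_empty_validation_set_rejected(self, solutes):
        with pytest.raises(ValueError):
            validate(fixtures.reference_membrane("NF"), [], solutes)
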