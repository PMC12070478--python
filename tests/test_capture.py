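"""Synthetic capture experiments and count-model inference: moment checks
against the generating process and parameter recovery at scale."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from acuitrap import capture as cap
from acuitrap.capture import (
    CountModelFit,
    SimConfig,
    fit_count_model,
    fit_quadratic_range_model,
    lr_test,
    paper_field_placements,
    paper_lab_config,
    paper_polytunnel_config,
    peak_range,
    read_dataset,
    simulate_lab_choice,
    simulate_polytunnel,
    write_dataset,
)


# ---------------------------------------------------------------- simulators


def test_lab_zero_pool_gives_zero_counts():
    cfg = SimConfig(n_thrips_per_trial=0, n_trials=3)
    data = simulate_lab_choice(cfg, seed=1)
    assert (data["count"] == 0).all()
    assert len(data) == 27  # 3 distances x 3 trials x 3 traps


def test_lab_cell_means_converge_to_configured_values():
    cfg = SimConfig(mean_matched=2.0, mean_mismatched=0.65, n_trials=5000)
    data = simulate_lab_choice(cfg, seed=3)
    matched = data[
        data.apply(
            lambda r: cap.LAB_DISTANCES[r.size_class] == r.distance_or_height_cm,
            axis=1,
        )
    ]
    mismatched = data.drop(matched.index)
    se_m = math.sqrt(2.0 / len(matched))
    se_mm = math.sqrt(0.65 / len(mismatched))
    assert abs(matched["count"].mean() - 2.0) < 3 * se_m
    assert abs(mismatched["count"].mean() - 0.65) < 3 * se_mm


def test_lab_matched_mean_at_study_replication():
    # at 15 trials per distance the matched-cell grand mean should usually
    # land near its configured value; audit across seeds
    cfg = SimConfig(mean_matched=2.0, mean_mismatched=0.65, n_trials=15)
    within = 0
    for seed in range(40):
        data = simulate_lab_choice(cfg, seed=seed)
        matched = data[
            [cap.LAB_DISTANCES[s] == d
             for s, d in zip(data.size_class, data.distance_or_height_cm)]
        ]
        within += 1.6 <= matched["count"].mean() <= 2.4
    assert within >= 32  # ~95% nominal, generous audit margin


def test_lab_pool_cap_error():
    with pytest.raises(ValueError, match="pool"):
        simulate_lab_choice(SimConfig(n_thrips_per_trial=50, mean_matched=20.0))


def test_lab_total_never_exceeds_pool():
    cfg = SimConfig(n_thrips_per_trial=8, mean_matched=2.5, mean_mismatched=2.5)
    data = simulate_lab_choice(cfg, seed=5)
    totals = data.groupby(["distance_or_height_cm", "trial"])["count"].sum()
    assert (totals <= 8).all()


def test_lab_multinomial_mode_means():
    cfg = SimConfig(
        mean_matched=2.0, mean_mismatched=0.65, n_trials=4000,
        allocation="multinomial",
    )
    data = simulate_lab_choice(cfg, seed=9)
    matched = data[
        [cap.LAB_DISTANCES[s] == d
         for s, d in zip(data.size_class, data.distance_or_height_cm)]
    ]
    assert matched["count"].mean() == pytest.approx(2.0, abs=0.07)


def test_lab_underdispersed_mode():
    cfg = SimConfig(mean_matched=2.0, mean_mismatched=2.0, dispersion=0.5,
                    n_trials=3000)
    data = simulate_lab_choice(cfg, seed=11)
    ratio = data["count"].var() / data["count"].mean()
    assert 0.4 < ratio < 0.7


def test_seed_determinism_byte_identical():
    cfg = paper_lab_config()
    a, b = io.StringIO(), io.StringIO()
    write_dataset(simulate_lab_choice(cfg, seed=42), a)
    write_dataset(simulate_lab_choice(cfg, seed=42), b)
    assert a.getvalue() == b.getvalue()
    assert a.getvalue() != ""
    c = io.StringIO()
    write_dataset(simulate_lab_choice(cfg, seed=43), c)
    assert a.getvalue() != c.getvalue()


def test_polytunnel_zero_inflation_one_gives_all_zeros():
    cfg = SimConfig(zero_inflation=1.0)
    data = simulate_polytunnel(cfg, seed=1)
    assert (data["count"] == 0).all()
    assert len(data) == 9 * 12


def test_polytunnel_poisson_limit_variance():
    cfg = SimConfig(
        dispersion=1.0, zero_inflation=0.0,
        random_effect_sd_tunnel=0.0, random_effect_sd_row=0.0,
        n_tunnels=2, n_rows_per_tunnel=600,
    )
    data = simulate_polytunnel(cfg, seed=2)
    for x, grp in data.groupby("max_resolvable_range_cm"):
        ratio = grp["count"].var() / grp["count"].mean()
        assert 0.85 < ratio < 1.15


def test_polytunnel_mean_peaks_at_configured_range():
    cfg = SimConfig(
        peak_range_cm=26.0, dispersion=1.0, zero_inflation=0.0,
        random_effect_sd_tunnel=0.0, random_effect_sd_row=0.0,
        n_tunnels=1, n_rows_per_tunnel=400,
    )
    data = simulate_polytunnel(cfg, seed=4)
    means = data.groupby("max_resolvable_range_cm")["count"].mean()
    assert means.idxmax() == pytest.approx(25.98, abs=0.005)


def test_polytunnel_requires_positive_curvature():
    with pytest.raises(ValueError, match="curvature"):
        simulate_polytunnel(SimConfig(curvature=0.0), seed=1)


def test_dataset_csv_round_trip(tmp_path):
    data = simulate_polytunnel(paper_polytunnel_config(), seed=6)
    path = tmp_path / "field.csv"
    write_dataset(data, path)
    back = read_dataset(path)
    assert (back["count"] == data["count"]).all()
    assert (back["tunnel_id"] == data["tunnel_id"]).all()


def test_field_placements_match_visibility_geometry():
    tbl = paper_field_placements()
    lookup = {
        (r.size_class, r.distance_or_height_cm): r.max_resolvable_range_cm
        for r in tbl.itertuples()
    }
    assert lookup[("medium", 15.0)] == pytest.approx(25.98, abs=0.005)
    assert lookup[("large", 30.0)] == pytest.approx(40.0, abs=0.005)
    assert lookup[("small", 30.0)] == 0.0
    assert lookup[("large", 50.0)] == 0.0  # resolvable only directly below


# ------------------------------------------------------------------- fitting


def test_intercept_only_fit_recovers_log_mean():
    fit = fit_count_model(pd.DataFrame({"count": [1, 2, 3]}), "1")
    assert fit.params.iloc[0] == pytest.approx(math.log(2.0), abs=1e-8)
    assert fit.converged


def test_constant_counts_give_zero_effects():
    data = simulate_lab_choice(SimConfig(n_thrips_per_trial=0, n_trials=5), seed=1)
    data["count"] = 2
    fit = fit_count_model(data)
    non_intercept = fit.params.iloc[1:]
    assert np.all(np.abs(non_intercept) < 1e-6)


def test_interaction_recovery_at_scale():
    cfg = SimConfig(mean_matched=2.0, mean_mismatched=0.65, n_trials=200)
    data = simulate_lab_choice(cfg, seed=8)
    data["matched"] = [
        cap.LAB_DISTANCES[s] == d
        for s, d in zip(data.size_class, data.distance_or_height_cm)
    ]
    fit = fit_count_model(data, "C(matched)")
    coef = fit.params["C(matched)[T.True]"]
    se = fit.bse["C(matched)[T.True]"]
    assert abs(coef - math.log(2.0 / 0.65)) < 3 * se


def test_dispersion_near_one_for_poisson_data():
    cfg = SimConfig(
        n_thrips_per_trial=10**6, n_trials=1000,
        mean_matched=2.0, mean_mismatched=0.65,
    )
    data = simulate_lab_choice(cfg, seed=10)
    fit = fit_count_model(data)
    assert 0.8 < fit.dispersion_phi < 1.2


def test_empty_cell_is_named():
    data = simulate_lab_choice(paper_lab_config(), seed=1)
    data = data[
        ~((data.size_class == "small") & (data.distance_or_height_cm == 5.0))
    ]
    with pytest.raises(ValueError, match="small"):
        fit_count_model(data)


def test_lr_identical_models():
    data = simulate_lab_choice(paper_lab_config(), seed=2)
    fit = fit_count_model(data)
    res = lr_test(fit, fit)
    assert res.statistic == 0.0 and res.pvalue == 1.0


def test_lr_non_nested_rejected():
    data = simulate_lab_choice(paper_lab_config(), seed=2)
    a = fit_count_model(data, "C(size_class)")
    b = fit_count_model(data, "C(distance_or_height_cm)")
    with pytest.raises(ValueError, match="nested|full"):
        lr_test(a, b)


def test_coefficient_rmse_shrinks_with_replication():
    truth = math.log(2.0 / 0.65)

    def rmse(n_trials, reps):
        errs = []
        for seed in range(reps):
            cfg = SimConfig(mean_matched=2.0, mean_mismatched=0.65, n_trials=n_trials)
            data = simulate_lab_choice(cfg, seed=seed)
            data["matched"] = [
                cap.LAB_DISTANCES[s] == d
                for s, d in zip(data.size_class, data.distance_or_height_cm)
            ]
            fit = fit_count_model(data, "C(matched)")
            errs.append(fit.params["C(matched)[T.True]"] - truth)
        return float(np.sqrt(np.mean(np.square(errs))))

    assert rmse(400, 15) < rmse(25, 15)


def test_quadratic_recovery_from_known_coefficients():
    # independent generation: direct Poisson draws from the log-quadratic
    b0, b1, b2 = 0.2, 0.10, -0.0019
    rng = np.random.default_rng(123)
    x = np.tile(np.array([0.0, 10.0, 26.0, 40.0, 50.0]), 100)
    mu = np.exp(b0 + b1 * x + b2 * x**2)
    data = pd.DataFrame(
        {
            "max_resolvable_range_cm": x,
            "count": rng.poisson(mu),
            "tunnel_id": "T1",
            "row_id": "R1",
        }
    )
    fit = fit_quadratic_range_model(data, group_offsets=False)
    for name, truth in [
        ("max_resolvable_range_cm", b1),
        ("I(max_resolvable_range_cm ** 2)", b2),
    ]:
        assert abs(fit.params[name] - truth) < 3 * fit.bse[name]


def test_quadratic_null_curvature_recovery():
    rng = np.random.default_rng(7)
    x = np.tile(np.array([0.0, 15.0, 30.0, 45.0]), 150)
    mu = np.exp(0.3 + 0.02 * x)  # no quadratic term
    data = pd.DataFrame(
        {
            "max_resolvable_range_cm": x,
            "count": rng.poisson(mu),
            "tunnel_id": "T1",
            "row_id": "R1",
        }
    )
    fit = fit_quadratic_range_model(data, group_offsets=False)
    name = "I(max_resolvable_range_cm ** 2)"
    assert abs(fit.params[name]) < 3 * fit.bse[name]


def test_quadratic_needs_three_distinct_ranges():
    data = pd.DataFrame(
        {"max_resolvable_range_cm": [5.0] * 10, "count": [1] * 10,
         "tunnel_id": "T1", "row_id": "R1"}
    )
    with pytest.raises(ValueError, match="distinct"):
        fit_quadratic_range_model(data)


def _manual_fit(b1, b2, var=None):
    names = ["Intercept", "max_resolvable_range_cm",
             "I(max_resolvable_range_cm ** 2)"]
    params = pd.Series([0.0, b1, b2], index=names)
    v = var if var is not None else [1e-4, 1e-6, 1e-10]
    cov = pd.DataFrame(np.diag(v), index=names, columns=names)
    return CountModelFit(
        params=params, cov=cov, dispersion_phi=1.0, loglik=0.0, deviance=0.0,
        df_resid=10, nobs=13, converged=True, quasi=False, formula="manual",
    )


def test_peak_location_closed_form():
    est = peak_range(_manual_fit(0.10, -0.0019231), n_boot=2000, seed=1)
    assert est.peak_cm == pytest.approx(26.0, abs=0.05)
    assert est.ci_low_cm < est.peak_cm < est.ci_high_cm


def test_peak_requires_concavity():
    with pytest.raises(ValueError, match="interior maximum"):
        peak_range(_manual_fit(0.10, 0.001))


def test_peak_of_symmetric_data():
    # counts symmetric about x = 26 force the fitted vertex there
    x = np.repeat([20.0, 26.0, 32.0], 40)
    count = np.repeat([2, 5, 2], 40)
    data = pd.DataFrame(
        {"max_resolvable_range_cm": x, "count": count,
         "tunnel_id": "T1", "row_id": "R1"}
    )
    fit = fit_quadratic_range_model(data, group_offsets=False)
    est = peak_range(fit, n_boot=1000, seed=3)
    assert est.peak_cm == pytest.approx(26.0, abs=1e-6)


def test_peak_recovery_on_simulated_field_data():
    cfg = paper_polytunnel_config()
    data = simulate_polytunnel(cfg, seed=0)
    fit = fit_quadratic_range_model(data)
    est = peak_range(fit, n_boot=4000, seed=0)
    assert 10 < est.peak_cm < 45
    assert est.ci_low_cm < est.ci_high_cm


def test_sim_config_validation():
    with pytest.raises(ValueError):
        SimConfig(dispersion=0.0)
    with pytest.raises(ValueError):
        SimConfig(zero_inflation=1.5)
    with pytest.raises(ValueError):
        SimConfig(allocation="magic")
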