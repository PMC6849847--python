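"""Objective, optimizer, derived kinetics and protocol comparison."""

import numpy as np
import pandas as pd
import pytest

from trlkin import default_parameters
from trlkin.fitting import (
    FASTED_FREE_NAMES,
    FitConfig,
    ObservationWeights,
    TTestResult,
    _fraction_rates,
    compare_protocols,
    derive_kinetics,
    fit_subject,
    objective,
    residuals,
)
from trlkin.io import TracerStudyDataset
from trlkin.model import TRACEE_INDEX
from trlkin.params import ConfigurationError
from trlkin.synth import NoiseModel, generate_dataset, sample_parameters


def test_objective_zero_on_noise_free_data(truth_normal, noisefree_fed):
    assert objective(truth_normal.params, noisefree_fed) < 1e-16


def test_doubling_weights_doubles_cost(truth_normal, noisy_fed):
    base = objective(truth_normal.params, noisy_fed)
    scale = {sid: 2.0 for sid in noisy_fed.series_ids}
    doubled = objective(truth_normal.params, noisy_fed,
                        ObservationWeights(series_scale=scale))
    assert doubled == pytest.approx(2.0 * base, rel=1e-12)


def test_objective_invariant_under_series_permutation(truth_normal, noisy_fed):
    table = noisy_fed.table
    reordered = TracerStudyDataset(
        noisy_fed.subject_id, noisy_fed.body_weight, noisy_fed.protocol,
        pd.concat([table[table.series_id == s]
                   for s in reversed(noisy_fed.series_ids)],
                  ignore_index=True))
    assert objective(truth_normal.params, reordered) == pytest.approx(
        objective(truth_normal.params, noisy_fed), rel=1e-12)


def test_cost_matches_hand_summed_residual_table(truth_normal, noisy_fed):
    # independent arithmetic: recompute the weighted SSE point by point
    from trlkin.fitting import _SeriesCache
    w = ObservationWeights()
    model = _SeriesCache(noisy_fed, w).model_series(truth_normal.params)
    total = 0.0
    for sid in noisy_fed.series_ids:
        _, values = noisy_fed.series(sid)
        floor = w.floor_frac * np.max(np.abs(values))
        for m, v in zip(model[sid], values):
            total += ((m - v) / max(abs(v), floor)) ** 2
    assert objective(truth_normal.params, noisy_fed, w) == pytest.approx(
        total, rel=1e-10)


def test_empty_dataset_rejected(truth_normal, noisy_fed):
    empty = TracerStudyDataset(
        "x", 90.0, "fed", noisy_fed.table.iloc[0:0])
    with pytest.raises(ConfigurationError):
        objective(truth_normal.params, empty)


def test_noise_free_fit_from_truth_stays_at_truth(truth_normal, noisefree_fed):
    cfg = FitConfig(n_starts=1, seed=0, max_nfev=5, init=truth_normal.params)
    res = fit_subject(noisefree_fed, cfg)
    assert res.cost < 1e-12
    for name in ("basal_apob48", "pr_apob100_vldl1", "k_13_14"):
        assert res.estimate[name] == pytest.approx(
            truth_normal.params[name], rel=1e-3)


def test_fasted_fit_estimates_basal_secretion_only(truth_normal):
    ds = generate_dataset(truth_normal, "fasted", noise=NoiseModel(seed=5))
    res = fit_subject(ds, FitConfig(n_starts=1, seed=2, max_nfev=15))
    default = default_parameters()
    # meal-timing parameters were never touched (structurally inactive)
    for name in ("k_gut", "k_stage_fast", "k_stage_slow", "ratio_cm_new"):
        assert res.estimate[name] == default[name]
    assert np.isfinite(res.cost)
    assert res.estimate["basal_apob48"] > 0.0


# --- derived kinetics --------------------------------------------------------

def test_steady_one_compartment_fraction_fcr_equals_loss_constant(params):
    integral = np.zeros(len(TRACEE_INDEX))
    integral[TRACEE_INDEX[18]] = 5.0
    p = params.with_values(k_18_19=0.0)
    fdc, ftr = _fraction_rates(p, [18], [], [(18, 0)], integral)
    assert ftr == 0.0
    assert fdc == pytest.approx(p["k_18_0"])


def test_two_compartment_fraction_fcr_arithmetic(params):
    # pools (3, 1), loss constants (2, 0.5): FCR = (3*2 + 1*0.5)/4 = 1.625
    integral = np.zeros(len(TRACEE_INDEX))
    integral[TRACEE_INDEX[18]] = 3.0
    integral[TRACEE_INDEX[19]] = 1.0
    p = params.with_values(k_18_0=2.0, k_19_0=0.5, k_18_19=0.0)
    fdc, ftr = _fraction_rates(p, [18, 19], [], [(18, 0), (19, 0)], integral)
    assert fdc + ftr == pytest.approx(1.625)


def test_fcr_decomposes_into_fdc_plus_ftr_exactly():
    for seed, tier in ((0, "low"), (1, "normal"), (2, "high")):
        ks = derive_kinetics(sample_parameters(seed, tier).params)
        assert ks.apob100_vldl1_fcr == pytest.approx(
            ks.apob100_vldl1_fdc + ks.apob100_vldl1_ftr, abs=1e-12)
        assert ks.tg_apob100_vldl1_fcr == pytest.approx(
            ks.tg_apob100_vldl1_fdc + ks.tg_apob100_vldl1_ftr, abs=1e-12)
        assert ks.apob48_total_prod == pytest.approx(
            ks.apob48_basal_prod + ks.apob48_pp_prod, rel=1e-12)


def test_zero_pool_fcr_flagged(params):
    integral = np.zeros(len(TRACEE_INDEX))
    with pytest.raises(ZeroDivisionError):
        _fraction_rates(params, [18, 19], [], [(18, 0)], integral)


def test_fasted_protocol_has_no_postprandial_production(truth_normal):
    ks = derive_kinetics(truth_normal.params, "fasted")
    assert ks.apob48_pp_prod == 0.0
    assert ks.apob48_total_prod == ks.apob48_basal_prod


def test_tg_fcr_exceeds_protein_fcr_in_cm(truth_normal):
    # lipolytic shedding removes TG faster than particles are removed
    ks = derive_kinetics(truth_normal.params)
    assert ks.tg_apob48_cm_fcr > ks.apob48_cm_fcr


# --- protocol comparison -----------------------------------------------------

def test_identical_protocols_give_p_one():
    vals = [27.8, 27.3, 57.4, 101.0]
    res = compare_protocols(vals, vals)
    assert res.p_value == 1.0
    assert res.t_statistic == 0.0


def test_equal_means_give_t_near_zero():
    fed = [27.8, 27.3, 57.4, 101.0]
    shift = [10.0, -10.0, 5.0, -5.0]
    fasted = [f + s for f, s in zip(fed, shift)]  # same mean
    res = compare_protocols(fed, fasted)
    assert abs(res.t_statistic) < 1e-12
    assert res.mean_difference == pytest.approx(0.0, abs=1e-12)


def test_paired_t_matches_textbook_formula():
    a = [50.0, 60.0, 70.0, 80.0]
    b = [45.0, 66.0, 64.0, 77.0]
    d = np.array(a) - np.array(b)
    t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(4))
    from scipy import stats
    p_expected = 2 * stats.t.sf(abs(t_expected), df=3)
    res = compare_protocols(a, b)
    assert res.t_statistic == pytest.approx(t_expected, rel=1e-12)
    assert res.p_value == pytest.approx(p_expected, rel=1e-12)
    assert res.n == 4


def test_mismatched_lists_rejected():
    with pytest.raises(ConfigurationError):
        compare_protocols([1.0, 2.0], [1.0])
    with pytest.raises(ConfigurationError):
        compare_protocols([1.0], [1.0])
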