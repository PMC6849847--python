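"""Ground-truth sampling and synthetic dataset generation."""

import numpy as np
import pytest

from trlkin.fitting import derive_kinetics
from trlkin.io import FASTED_SERIES, FED_SERIES
from trlkin.params import ConfigurationError
from trlkin.synth import (
    TIER_TG_RANGES,
    GroundTruth,
    NoiseModel,
    SamplingSchedule,
    generate_dataset,
    sample_parameters,
)


def test_sampling_schedule_matches_protocol_times():
    s = SamplingSchedule()
    assert s.leucine_times[:4] == (0.0, 2 / 60, 4 / 60, 6 / 60)
    assert s.leucine_times[-1] == 24
    assert s.enrichment_times[1] == 0.5
    assert len(s.leucine_times) == 19
    assert len(s.enrichment_times) == 15
    with pytest.raises(ValueError):
        SamplingSchedule(leucine_times=(0.0, 0.0, 1.0))


def test_sampler_is_deterministic_per_seed():
    a = sample_parameters(7, "normal")
    b = sample_parameters(7, "normal")
    assert a.params.values == b.params.values
    assert a.body_weight == b.body_weight
    c = sample_parameters(8, "normal")
    assert c.params.values != a.params.values


def test_sampled_basal_production_within_cohort_envelope():
    for seed in range(25):
        gt = sample_parameters(seed, ("low", "normal", "high")[seed % 3])
        assert 27.3 <= gt.params["basal_apob48"] <= 101.0


def test_implied_fasting_tg_falls_in_tier_range():
    for tier in ("low", "normal", "high"):
        lo, hi = TIER_TG_RANGES[tier]
        for seed in (0, 1, 2, 3):
            gt = sample_parameters(seed, tier)
            assert lo <= gt.fasting_tg <= hi


def test_high_tier_draws_slower_cm_fcr_than_low_tier():
    # Monte-Carlo check of the tier ordering rule over 100 seeds
    def fcrs(tier):
        return [derive_kinetics(sample_parameters(s, tier).params).apob48_cm_fcr
                for s in range(100)]
    assert np.median(fcrs("high")) < np.median(fcrs("low"))


def test_unknown_tier_rejected():
    with pytest.raises(ConfigurationError):
        sample_parameters(0, "very-high")


def test_zero_noise_dataset_equals_model_output(truth_normal, noisefree_fed):
    from trlkin.fitting import _model_series
    model = _model_series(truth_normal.params, noisefree_fed)
    for sid in noisefree_fed.series_ids:
        _, values = noisefree_fed.series(sid)
        np.testing.assert_allclose(values, model[sid], rtol=1e-12)


def test_fed_dataset_contains_all_panel_series(noisefree_fed):
    assert noisefree_fed.series_ids == list(FED_SERIES)
    assert len(noisefree_fed.series_ids) == 19


def test_fasted_dataset_has_plasma_series_only(truth_normal):
    ds = generate_dataset(truth_normal, "fasted", noise=NoiseModel(0, 0, 0))
    assert ds.series_ids == list(FASTED_SERIES)


def test_noise_replicate_mean_converges_to_clean_value(truth_normal,
                                                       noisefree_fed):
    t_clean, clean = noisefree_fed.series("apob48_plasma")
    noise_cfg = NoiseModel(cv_mass=0.05, cv_enrichment=0.05, floor_frac=0.0)
    reps = []
    for s in range(200):
        ds = generate_dataset(truth_normal, "fed",
                              noise=NoiseModel(0.05, 0.05, 0.0, seed=s))
        reps.append(ds.series("apob48_plasma")[1])
    reps = np.asarray(reps)
    mean = reps.mean(axis=0)
    sem = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
    assert np.all(np.abs(mean - clean) <= 3.0 * sem + 1e-12)


def test_noise_is_reproducible_and_clipped_at_zero(truth_normal):
    a = generate_dataset(truth_normal, "fed", noise=NoiseModel(seed=9))
    b = generate_dataset(truth_normal, "fed", noise=NoiseModel(seed=9))
    assert a.table.value.equals(b.table.value)
    assert (a.table.value >= 0).all()
    assert a.n_clipped >= 0


def test_fed_shapes_cm_tg_rises_postprandially(truth_normal, noisefree_fed):
    t, v = noisefree_fed.series("tg_cm")
    pre = v[t <= 2.0].max()
    assert v[t > 2.0].max() > 3.0 * max(pre, 1e-9)
    assert t[np.argmax(v)] < 24.0
    t, v = noisefree_fed.series("apob48_vldl1")
    assert v[t > 2.0].max() > v[0]


def test_fasted_cm_tg_shows_no_postprandial_rise(truth_normal):
    cv = 0.05
    ds = generate_dataset(truth_normal, "fasted",
                          noise=NoiseModel(cv, cv, 0.0, seed=2))
    # no CM series is measured when fasting; total plasma apoB48 must not
    # rise above its 0 h value beyond noise
    t, v = ds.series("apob48_plasma")
    assert v.max() <= v[0] * (1 + 3 * cv)


def test_high_tier_fasted_plasma_apob48_declines():
    gt = sample_parameters(3, "high")
    ds = generate_dataset(gt, "fasted", noise=NoiseModel(0, 0, 0))
    t, v = ds.series("apob48_plasma")
    assert v[-1] < v[0]


def test_ground_truth_sidecar_round_trip(tmp_path, truth_normal):
    p = tmp_path / "truth.json"
    truth_normal.to_json(p)
    back = GroundTruth.from_json(p)
    assert back.params.values == truth_normal.params.values
    assert back.tier == truth_normal.tier
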