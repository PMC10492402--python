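"""Synthetic herd generator: pedigree structure, genetic covariance,
visit scheduling and the BP4 observation process."""

import numpy as np
import pandas as pd
import pytest

from agep4 import (
    SimulationConfig,
    generate_pedigree,
    observe_bp4,
    schedule_visits,
    simulate_population,
    simulate_study,
)


def test_generate_pedigree_forced_full_sibs():
    ped = generate_pedigree(1, 1, 2, seed=0)
    assert len(ped) == 4
    assert ped.sire[2] == ped.sire[3] == 0
    assert ped.dam[2] == ped.dam[3] == 1


def test_generate_pedigree_counts_and_determinism():
    ped1 = generate_pedigree(10, 150, 300, seed=3)
    ped2 = generate_pedigree(10, 150, 300, seed=3)
    assert ped1.ids == ped2.ids
    assert (ped1.sire == ped2.sire).all() and (ped1.dam == ped2.dam).all()
    offspring = ped1.sire != -1
    # conservation: daughters per sire average offspring/sires
    counts = np.bincount(ped1.sire[offspring], minlength=10)
    assert counts.sum() == 300 and counts.mean() == 30.0
    # dam capacity respected
    dams = np.bincount(ped1.dam[offspring])
    assert dams.max() <= 2
    ped3 = generate_pedigree(10, 150, 300, seed=4)
    assert not (ped3.sire == ped1.sire).all()


def test_generate_pedigree_invalid_configs():
    with pytest.raises(ValueError):
        generate_pedigree(0, 5, 5, seed=0)
    with pytest.raises(ValueError):
        generate_pedigree(5, 2, 5, seed=0, max_dam_uses=2)


def test_degenerate_variances_collapse_to_mean():
    cfg = SimulationConfig(
        n_herds=2, herd_size_mean=10, herd_size_sd=0, n_sires=4,
        sigma2_a=0.0, sigma2_e=0.0, herd_effect_sd=0.0, jersey_effect=0.0,
        global_mean=340.0, seed=1,
    )
    study = simulate_study(cfg)
    onset = study.truth["true_agep4"].dropna()
    assert np.allclose(onset, 340.0)


def test_parent_offspring_breeding_value_covariance():
    """Over independent trios, cov(a_sire, a_offspring) estimates the
    relationship-matrix entry times sigma2_a: 0.5 sigma2_a."""
    from agep4.pedigree import Pedigree
    from agep4.simulate import _breeding_values

    n_trios, sigma2_a = 10_000, 270.0
    ids, sire, dam = [], [], []
    for k in range(n_trios):
        base = 3 * k
        ids += [f"s{k}", f"d{k}", f"o{k}"]
        sire += [-1, -1, base]
        dam += [-1, -1, base + 1]
    ped = Pedigree(ids, np.array(sire), np.array(dam))
    a = _breeding_values(ped, sigma2_a, np.random.default_rng(5))
    trios = a.reshape(n_trios, 3)
    cov = np.cov(trios[:, 0], trios[:, 2])[0, 1]
    se = sigma2_a * np.sqrt(2.0 / n_trios)
    assert abs(cov - 0.5 * sigma2_a) < 3 * se


def test_founder_additive_variance_matches_config():
    cfg = SimulationConfig(n_herds=2, herd_size_mean=2500, herd_size_sd=0,
                           n_sires=100, seed=9)
    study = simulate_study(cfg)
    ped = study.pedigree
    founders = (ped.sire == -1) & (ped.dam == -1)
    a = study.truth["breeding_value_a"].to_numpy()[founders]
    se = cfg.sigma2_a * np.sqrt(2.0 / len(a))
    assert abs(a.var(ddof=1) - cfg.sigma2_a) < 3 * se


def test_schedule_visits_targets_and_ordering(small_study):
    visits = small_study.visits
    means = visits.groupby("visit_index")["age_at_visit"].mean()
    assert abs(means["M"] - 327) < 6
    assert abs((means["M"] - means["E"]) - 28) < 4
    assert abs((means["L"] - means["M"]) - 27) < 4
    wide = visits.pivot(index="animal_id", columns="visit_index", values="age_at_visit")
    assert ((wide["E"] < wide["M"]) & (wide["M"] < wide["L"])).all()


def test_schedule_visits_zero_sd_shares_herd_ages():
    cfg = SimulationConfig(
        n_herds=3, herd_size_mean=12, herd_size_sd=0, n_sires=4,
        age_sd=0.0, herd_date_jitter_sd=0.0, seed=2,
    )
    study = simulate_study(cfg)
    per_herd = study.visits.merge(study.animals, on="animal_id").groupby(
        ["herd_id", "visit_index"]
    )["age_at_visit"].nunique()
    assert (per_herd == 1).all()
    assert sorted(study.visits["age_at_visit"].unique()) == [299, 327, 354]


def _mini_truth_and_ages(onsets):
    truth = pd.DataFrame(
        {"animal_id": list(onsets), "breeding_value_a": 0.0, "true_agep4": list(onsets.values())}
    )
    rows = [
        (a, v, age)
        for a in onsets
        for v, age in zip("EML", (300, 330, 360))
    ]
    ages = pd.DataFrame(rows, columns=["animal_id", "visit_index", "age_at_visit"])
    return truth, ages


def test_observe_bp4_monotone_and_limits():
    truth, ages = _mini_truth_and_ages({"a": 290.0, "b": 400.0, "c": 345.0})
    obs = observe_bp4(truth, ages, p_false_negative=0.0, seed=0)
    wide = obs.pivot(index="animal_id", columns="visit_index", values="bp4_elevated")[
        ["E", "M", "L"]
    ]
    assert wide.loc["a"].tolist() == [True, True, True]
    assert wide.loc["b"].tolist() == [False, False, False]
    assert wide.loc["c"].tolist() == [False, False, True]
    # monotone once elevated under no false negatives
    seq = obs.sort_values(["animal_id", "age_at_visit"]).groupby("animal_id")["bp4_elevated"]
    for _, s in seq:
        arr = s.to_numpy()
        assert (np.diff(arr.astype(int)) >= 0).all()
    # p_fn = 1: every post-pubertal visit suppressed
    none = observe_bp4(truth, ages, p_false_negative=1.0, seed=0)
    assert not none["bp4_elevated"].any()


def test_observe_bp4_cycle_constraint_caps_consecutive_misses():
    truth, ages = _mini_truth_and_ages({"a": 250.0})
    obs = observe_bp4(truth, ages, p_false_negative=1.0, seed=0, cycle_constraint=True)
    seq = obs.sort_values("age_at_visit")["bp4_elevated"].tolist()
    assert seq == [False, True, False]  # never two misses in a row


def test_simulate_study_deterministic_and_seed_sensitive():
    cfg = SimulationConfig(n_herds=3, herd_size_mean=15, herd_size_sd=3, n_sires=5, seed=21)
    s1, s2 = simulate_study(cfg), simulate_study(cfg)
    pd.testing.assert_frame_equal(s1.visits, s2.visits)
    pd.testing.assert_frame_equal(s1.truth, s2.truth)
    s3 = simulate_study(cfg.model_copy(update={"seed": 22}))
    assert not s1.visits.equals(s3.visits)


def test_mid_visit_post_pubertal_fraction_near_design_target(small_study):
    mid = small_study.visits[small_study.visits["visit_index"] == "M"]
    assert 0.3 < mid["bp4_elevated"].mean() < 0.6


def test_unsorted_pedigree_rejected():
    from agep4.pedigree import Pedigree, PedigreeOrderError

    with pytest.raises(PedigreeOrderError):
        Pedigree(["x", "y"], np.array([1, -1]), np.array([-1, -1]))
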