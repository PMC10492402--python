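"""Gibbs engine: truncated-normal sampler, design assembly, single-site
updates against closed-form oracles, and chain-level invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agep4 import (
    MCMCConfig,
    ModelSpec,
    build_design,
    run_chain,
    sample_truncated_normal,
    solve_mme,
)
from agep4.gibbs import initial_state, update_location, update_response, update_variances
from agep4.pedigree import Pedigree
from agep4.summaries import mc_standard_error

from conftest import random_pedigree

RNG = np.random.default_rng


# ---------------------------------------------------------------- truncnorm

def test_truncnorm_support_and_errors():
    rng = RNG(0)
    x = sample_truncated_normal(0.0, 1.0, np.full(1000, 5.0), np.full(1000, 6.0), rng)
    assert ((x >= 5.0) & (x <= 6.0)).all()
    with pytest.raises(ValueError):
        sample_truncated_normal(0.0, 1.0, 2.0, 2.0, rng)
    with pytest.raises(ValueError):
        sample_truncated_normal(0.0, -1.0, 0.0, 1.0, rng)


def test_truncnorm_far_tail_is_stable():
    """Intervals 6+ SD from the mean still give in-bounds finite draws."""
    rng = RNG(1)
    for lo in (6.0, 10.0, 30.0):
        x = sample_truncated_normal(0.0, 1.0, np.full(200, lo), np.full(200, lo + 0.5), rng)
        assert np.isfinite(x).all() and ((x >= lo) & (x <= lo + 0.5)).all()
    x = sample_truncated_normal(0.0, 1.0, np.full(200, -12.5), np.full(200, -12.0), rng)
    assert ((x >= -12.5) & (x <= -12.0)).all()


def test_truncnorm_unrestricted_matches_normal_moments():
    rng = RNG(2)
    n = 100_000
    x = sample_truncated_normal(3.0, 2.0, np.full(n, -np.inf), np.full(n, np.inf), rng)
    assert abs(x.mean() - 3.0) < 3 * 2.0 / np.sqrt(n)
    assert abs(x.std() - 2.0) < 3 * 2.0 / np.sqrt(2 * n)


def test_truncnorm_symmetric_interval_closed_form_moments():
    """[-1, 1] truncation of a standard normal: SD = 0.53956 (phi/Phi form)."""
    rng = RNG(3)
    n = 100_000
    x = sample_truncated_normal(0.0, 1.0, np.full(n, -1.0), np.full(n, 1.0), rng)
    d = stats.truncnorm(-1.0, 1.0)
    assert abs(x.mean() - 0.0) < 3 * d.std() / np.sqrt(n)
    assert abs(x.std() - d.std()) < 3 * d.std() / np.sqrt(2 * n)
    assert d.std() == pytest.approx(0.53956, abs=1e-4)


# ---------------------------------------------------------------- design

def _toy_inputs(n_animals=6, records_per_animal=1, seed=0, mode="continuous"):
    rng = RNG(seed)
    ped = Pedigree(
        [f"A{i}" for i in range(n_animals)],
        np.full(n_animals, -1),
        np.full(n_animals, -1),
    )
    ids = [f"A{i}" for i in range(n_animals)] * records_per_animal
    animals = pd.DataFrame(
        {
            "animal_id": [f"A{i}" for i in range(n_animals)],
            "herd_id": ["H1" if i < n_animals // 2 else "H2" for i in range(n_animals)],
            "jersey_fraction": rng.uniform(0, 1, n_animals),
        }
    )
    y = rng.normal(330, 10, len(ids))
    if mode == "continuous":
        phen = pd.DataFrame({"animal_id": ids, "agevisit_days": y})
    else:
        phen = pd.DataFrame(
            {
                "animal_id": ids,
                "lower_bound_days": y - 0.5,
                "upper_bound_days": y + 0.5,
            }
        )
    return phen, animals, ped, y


def test_build_design_incidence_properties():
    phen, animals, ped, _ = _toy_inputs()
    design = build_design(phen, animals, ped, ModelSpec())
    counts = np.diff(design.herd_indptr)
    assert counts.sum() == design.n_records  # each record in exactly one herd
    assert design.jersey.min() >= 0 and design.jersey.max() <= 1
    jf = dict(zip(animals["animal_id"], animals["jersey_fraction"]))
    for rid, j in zip(design.record_ids, design.jersey):
        assert j == jf[rid]


def test_build_design_sire_mode_shares_columns():
    ped = Pedigree(
        ["S1", "D1", "D2", "A1", "A2"],
        np.array([-1, -1, -1, 0, 0]),
        np.array([-1, -1, -1, 1, 2]),
    )
    animals = pd.DataFrame(
        {"animal_id": ["A1", "A2"], "herd_id": "H1", "jersey_fraction": [0.0, 0.5]}
    )
    phen = pd.DataFrame({"animal_id": ["A1", "A2"], "cat_score": [1, 2]})
    design = build_design(phen, animals, ped, ModelSpec(response_mode="ordinal", random_effect="sire"))
    assert design.level_ids == ["S1"]
    assert (design.rec_level == 0).all()


def test_build_design_unknown_herd_errors():
    phen, animals, ped, _ = _toy_inputs()
    design_ok = build_design(phen, animals, ped, ModelSpec())
    with pytest.raises(ValueError):
        build_design(phen, animals.iloc[:-1], ped, ModelSpec())


# ---------------------------------------------------------------- updates

def _run(phen, animals, ped, spec, mcmc):
    return run_chain(phen, animals, ped, spec, mcmc)


def test_sampler_matches_least_squares_fixed_effects_only():
    """With known variances and one founder per record, the stationary
    mean of the fixed effects is the GLS/BLUP solution."""
    phen, animals, ped, y = _toy_inputs(n_animals=10, records_per_animal=2, seed=4)
    spec = ModelSpec(estimate_variances=False, prior_h2=0.5, prior_phenotypic_variance=200.0)
    mcmc = MCMCConfig(n_iterations=4000, burn_in=500, seed=5)
    chain = _run(phen, animals, ped, spec, mcmc)
    design = build_design(phen, animals, ped, spec)
    b_hat, u_hat = solve_mme(design, design.y_obs, 100.0, 100.0)
    for j in range(design.n_fixed):
        se = mc_standard_error(chain.b[:, j])
        assert abs(chain.b[:, j].mean() - b_hat[j]) < 3 * se + 1e-9
    for i in range(len(design.level_ids)):
        se = mc_standard_error(chain.u[:, i])
        assert abs(chain.u[:, i].mean() - u_hat[i]) < 3 * se + 1e-9


def test_random_effects_shrink_to_zero_as_prior_tightens():
    phen, animals, ped, _ = _toy_inputs(n_animals=8, seed=6)
    spec = ModelSpec(estimate_variances=False, prior_h2=1e-7, prior_phenotypic_variance=100.0)
    chain = _run(phen, animals, ped, spec, MCMCConfig(n_iterations=500, burn_in=100, seed=1))
    assert np.abs(chain.u).max() < 1.0  # lambda ~ 1e7 crushes the draws


def test_variance_update_conjugate_mean():
    """With u pinned so u'A^-1 u = q, repeated draws of sigma2_u match the
    scaled-inverse-chi-square posterior mean (q + nu S)/(nu + q - 2)."""
    phen, animals, ped, _ = _toy_inputs(n_animals=12, seed=7)
    spec = ModelSpec(prior_h2=0.5, prior_phenotypic_variance=2.0)  # S_u = 1
    design = build_design(phen, animals, ped, spec)
    state = initial_state(design, spec)
    state.u = np.ones(len(design.level_ids))  # founders: u'A^-1 u = q
    rng = RNG(8)
    q, nu, s = 12, spec.nu_genetic, 1.0
    draws = []
    for _ in range(20000):
        update_variances(state, design, spec, rng)
        draws.append(state.sigma2_u)
        state.u = np.ones(q)  # hold u fixed between draws
    expected = (q + nu * s) / (nu + q - 2)
    assert np.mean(draws) == pytest.approx(expected, rel=0.05)


def test_residual_variance_collapses_with_zero_residuals():
    phen, animals, ped, _ = _toy_inputs(n_animals=10, records_per_animal=40, seed=9)
    spec = ModelSpec()
    design = build_design(phen, animals, ped, spec)
    state = initial_state(design, spec)
    state.e = np.zeros(design.n_records)
    rng = RNG(10)
    draws = [
        (update_variances(state, design, spec, rng), state.sigma2_e)[1] for _ in range(200)
    ]
    n, nu, s = design.n_records, spec.nu_residual, 0.75 * 900.0
    assert np.mean(draws) == pytest.approx(nu * s / (nu + n - 2), rel=0.2)


def test_interval_draws_respect_bounds_and_narrow_limit():
    """Augmented responses never leave their bounds; with near-point
    intervals the fit agrees with the continuous model."""
    phen_i, animals, ped, y = _toy_inputs(n_animals=20, seed=11, mode="interval")
    phen_c = pd.DataFrame({"animal_id": phen_i["animal_id"], "agevisit_days": y})
    spec_i = ModelSpec(response_mode="interval", estimate_variances=False,
                       prior_h2=0.5, prior_phenotypic_variance=200.0)
    spec_c = ModelSpec(estimate_variances=False, prior_h2=0.5, prior_phenotypic_variance=200.0)
    mcmc = MCMCConfig(n_iterations=4000, burn_in=1000, seed=12, store_responses=True)
    ch_i = _run(phen_i, animals, ped, spec_i, mcmc)
    ch_c = _run(phen_c, animals, ped, spec_c, mcmc)
    design = build_design(phen_i, animals, ped, spec_i)
    assert (ch_i.y >= design.lower).all() and (ch_i.y <= design.upper).all()
    for j in range(ch_i.b.shape[1]):
        tol = 3 * (mc_standard_error(ch_i.b[:, j]) + mc_standard_error(ch_c.b[:, j])) + 0.3
        assert abs(ch_i.b[:, j].mean() - ch_c.b[:, j].mean()) < tol


def test_ordinal_liabilities_respect_thresholds():
    rng = RNG(13)
    n = 40
    ped = Pedigree([f"A{i}" for i in range(n)], np.full(n, -1), np.full(n, -1))
    animals = pd.DataFrame(
        {
            "animal_id": [f"A{i}" for i in range(n)],
            "herd_id": ["H1"] * (n // 2) + ["H2"] * (n // 2),
            "jersey_fraction": rng.uniform(0, 1, n),
        }
    )
    phen = pd.DataFrame({"animal_id": animals["animal_id"], "cat_score": rng.integers(1, 5, n)})
    spec = ModelSpec(response_mode="ordinal")
    chain = run_chain(phen, animals, ped, spec,
                      MCMCConfig(n_iterations=800, burn_in=200, seed=14, store_responses=True))
    t = np.concatenate([[-np.inf], [0.0, 1.0, 2.0], [np.inf]])
    cats = phen.sort_values("animal_id")["cat_score"].to_numpy()
    design_order = np.argsort(phen["animal_id"].to_numpy(), kind="stable")
    for s in range(0, chain.y.shape[0], 100):
        y = chain.y[s]
        assert ((y >= t[cats - 1]) & (y <= t[cats])).all()
    # category-1 liabilities stay below the first threshold
    assert (chain.y[:, cats == 1] <= 0.0).all()


def test_chain_determinism_and_record_order_invariance():
    phen, animals, ped, _ = _toy_inputs(n_animals=10, seed=15)
    spec = ModelSpec()
    mcmc = MCMCConfig(n_iterations=300, burn_in=100, seed=16)
    c1 = _run(phen, animals, ped, spec, mcmc)
    c2 = _run(phen, animals, ped, spec, mcmc)
    assert (c1.b == c2.b).all() and (c1.u == c2.u).all()
    assert (c1.sigma2_u == c2.sigma2_u).all()
    shuffled = phen.sample(frac=1.0, random_state=0).reset_index(drop=True)
    c3 = _run(shuffled, animals, ped, spec, mcmc)
    assert (c1.b == c3.b).all() and (c1.u == c3.u).all()


def test_heritability_draws_live_in_unit_interval(small_study):
    from agep4.comparison import fit_method
    from agep4.summaries import heritability_chain

    chain = fit_method(
        small_study.visits, small_study.animals, small_study.pedigree,
        "AUG", MCMCConfig(n_iterations=400, burn_in=100, seed=17),
    )
    h2 = heritability_chain(chain)
    assert (chain.sigma2_u > 0).all() and (chain.sigma2_e > 0).all()
    assert ((h2 > 0) & (h2 < 1)).all()
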