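"""Synthetic seasonal-calving herd study generator.

Emulates the data-generating process the downstream analysis assumes: a
sire-structured pedigree, herds of heifers with Holstein–Friesian ×
Jersey admixture, a latent true age at first blood-progesterone (BP4)
elevation (AGEP4) built from herd, breed, additive-genetic and residual
components, three herd visits at ~30-day intervals, and binary
BP4-elevated observations per visit. An optional false-negative
mechanism emulates the luteal-phase BP4 dip of post-pubertal heifers.

The latent trait is generated on the true-age scale as

    AGEP4_i = mu + herd_h(i) + beta_J * jersey_i + a_i + e_i

with a ~ N(0, A sigma2_a) realised by founder sampling plus Mendelian
sampling down the pedigree, matching the covariance structure the
animal model later fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .pedigree import UNKNOWN, Pedigree, inbreeding_coefficients

__all__ = [
    "StudyData",
    "generate_pedigree",
    "simulate_population",
    "schedule_visits",
    "observe_bp4",
    "simulate_study",
]

VISIT_LABELS = ("E", "M", "L")


@dataclass
class StudyData:
    """One simulated herd study: pedigree, animals, truth and visit records."""

    pedigree: Pedigree
    animals: pd.DataFrame  # animal_id, herd_id, jersey_fraction, birth_offset_days
    truth: pd.DataFrame    # animal_id, breeding_value_a, true_agep4 (NaN for founders)
    visits: pd.DataFrame   # animal_id, visit_index, age_at_visit, bp4_elevated


def generate_pedigree(
    n_sires: int,
    n_dams: int,
    n_offspring: int,
    seed: int,
    max_dam_uses: int = 2,
) -> Pedigree:
    """Founder sires and dams plus offspring under random mating.

    Each offspring draws its sire uniformly and its dam uniformly among
    dams with remaining capacity (a dam bears at most ``max_dam_uses``
    calves). Deterministic given ``seed``.
    """
    if n_offspring > 0 and n_sires < 1:
        raise ValueError("offspring require at least one sire")
    if n_offspring > 0 and n_dams < 1:
        raise ValueError("offspring require at least one dam")
    if n_offspring > n_dams * max_dam_uses:
        raise ValueError(
            f"{n_offspring} offspring exceed dam capacity {n_dams} x {max_dam_uses}"
        )
    rng = np.random.default_rng(seed)
    ids = [f"S{i+1:04d}" for i in range(n_sires)] + [f"D{i+1:05d}" for i in range(n_dams)]
    sire = [UNKNOWN] * (n_sires + n_dams)
    dam = [UNKNOWN] * (n_sires + n_dams)
    uses = np.zeros(n_dams, dtype=np.int64)
    for k in range(n_offspring):
        ids.append(f"A{k+1:05d}")
        sire.append(int(rng.integers(n_sires)))
        open_dams = np.flatnonzero(uses < max_dam_uses)
        d = int(open_dams[rng.integers(len(open_dams))])
        uses[d] += 1
        dam.append(n_sires + d)
    return Pedigree(ids, np.array(sire), np.array(dam))


def _breeding_values(pedigree: Pedigree, sigma2_a: float, rng: np.random.Generator) -> np.ndarray:
    """Sample a ~ N(0, A sigma2_a) by Mendelian descent through the pedigree."""
    n = len(pedigree)
    F = inbreeding_coefficients(pedigree)
    a = np.zeros(n)
    z = rng.standard_normal(n)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            var = sigma2_a
            mid = 0.0
        elif s != UNKNOWN and d != UNKNOWN:
            var = sigma2_a * (0.5 - 0.25 * (F[s] + F[d]))
            mid = 0.5 * (a[s] + a[d])
        else:
            p = s if s != UNKNOWN else d
            var = sigma2_a * (0.75 - 0.25 * F[p])
            mid = 0.5 * a[p]
        a[i] = mid + np.sqrt(var) * z[i]
    return a


def _herd_sizes(config: SimulationConfig, n_offspring: int, rng: np.random.Generator) -> np.ndarray:
    """Herd sizes ~ Normal(mean, sd), clipped and rescaled to the total."""
    raw = rng.normal(config.herd_size_mean, config.herd_size_sd, config.n_herds)
    raw = np.clip(raw, config.min_herd_size, None)
    sizes = np.maximum(config.min_herd_size, np.round(raw * n_offspring / raw.sum()).astype(int))
    # distribute the rounding remainder over the largest herds
    diff = n_offspring - sizes.sum()
    order = np.argsort(-sizes)
    for k in range(abs(diff)):
        sizes[order[k % config.n_herds]] += 1 if diff > 0 else -1
    return sizes


def _jersey_fractions(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([w for w, _, _ in config.breed_mixture])
    cls = rng.choice(len(weights), size=n, p=weights / weights.sum())
    lo = np.array([lo for _, lo, _ in config.breed_mixture])[cls]
    hi = np.array([hi for _, _, hi in config.breed_mixture])[cls]
    return rng.uniform(lo, hi)


def simulate_population(
    config: SimulationConfig, pedigree: Pedigree
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign herds, breed fractions and latent true AGEP4 to the offspring.

    Offspring are the pedigree entries with both parents known; founders
    carry breeding values (for pedigree consistency) but no phenotype.
    Returns ``(animals, truth)`` frames; ``truth`` covers every pedigree
    entry with ``true_agep4`` NaN for founders.
    """
    order_ok = (pedigree.sire < np.arange(len(pedigree))).all() and (
        pedigree.dam < np.arange(len(pedigree))
    ).all()
    if not order_ok:  # Pedigree construction already enforces this
        raise ValueError("pedigree must be sorted parents-first")

    rng = np.random.default_rng(config.seed)
    bv = _breeding_values(pedigree, config.sigma2_a, rng)

    is_offspring = (pedigree.sire != UNKNOWN) & (pedigree.dam != UNKNOWN)
    offspring = np.flatnonzero(is_offspring)
    n = len(offspring)

    sizes = _herd_sizes(config, n, rng)
    herd_of = np.repeat(np.arange(config.n_herds), sizes)
    rng.shuffle(herd_of)
    herd_ids = [f"H{h+1:03d}" for h in herd_of]
    herd_effects = rng.normal(0.0, config.herd_effect_sd, config.n_herds)

    jersey = _jersey_fractions(config, n, rng)
    birth_offset = np.round(rng.normal(0.0, config.age_sd, n)).astype(int)
    resid = rng.normal(0.0, np.sqrt(config.sigma2_e), n)

    true_agep4 = (
        config.global_mean
        + herd_effects[herd_of]
        + config.jersey_effect * jersey
        + bv[offspring]
        + resid
    )

    animals = pd.DataFrame(
        {
            "animal_id": [pedigree.ids[i] for i in offspring],
            "herd_id": herd_ids,
            "jersey_fraction": jersey,
            "birth_offset_days": birth_offset,
        }
    )
    truth = pd.DataFrame(
        {
            "animal_id": pedigree.ids,
            "breeding_value_a": bv,
            "true_agep4": np.nan,
        }
    )
    truth.loc[offspring, "true_agep4"] = true_agep4
    return animals, truth


def schedule_visits(
    animals: pd.DataFrame, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Three visit ages per animal: herd schedule plus birth offset.

    Each herd gets one scheduling jitter per visit around the target
    ages; an animal's age at a visit is the jittered herd target plus
    its own birth offset, so within-herd age SD ≈ ``config.age_sd`` and
    population means ≈ the targets. Ages increase strictly per animal.
    """
    rng = np.random.default_rng(seed)
    herds = sorted(animals["herd_id"].unique())
    targets = np.array(config.visit_target_ages)
    herd_visit_age: dict[str, np.ndarray] = {}
    for h in herds:
        jittered = np.round(targets + rng.normal(0.0, config.herd_date_jitter_sd, 3)).astype(int)
        for v in range(1, 3):  # enforce strictly increasing herd schedule
            jittered[v] = max(jittered[v], jittered[v - 1] + 1)
        herd_visit_age[h] = jittered
    rows = []
    for aid, herd, off in zip(
        animals["animal_id"], animals["herd_id"], animals["birth_offset_days"]
    ):
        ages = herd_visit_age[herd] + int(off)
        for label, age in zip(VISIT_LABELS, ages):
            rows.append((aid, label, int(age)))
    return pd.DataFrame(rows, columns=["animal_id", "visit_index", "age_at_visit"])


def observe_bp4(
    truth: pd.DataFrame,
    visit_ages: pd.DataFrame,
    p_false_negative: float,
    seed: int,
    cycle_constraint: bool = False,
) -> pd.DataFrame:
    """Binary BP4 status per visit from the latent true AGEP4.

    A visit reads elevated iff the animal's age has reached its true
    AGEP4 and the visit is not a false negative. False negatives occur
    independently per post-pubertal visit with probability
    ``p_false_negative``; with ``cycle_constraint`` two consecutive
    false negatives are disallowed (the ~3-week estrous cycle against a
    ~4-week visit interval caps misses at one per animal).
    """
    if not (0.0 <= p_false_negative <= 1.0):
        raise ValueError("p_false_negative must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    agep4 = dict(zip(truth["animal_id"], truth["true_agep4"]))
    order = {v: k for k, v in enumerate(VISIT_LABELS)}
    vis = visit_ages.sort_values(
        ["animal_id", "visit_index"], key=lambda s: s.map(order) if s.name == "visit_index" else s
    )
    out = []
    prev_animal, prev_fn = None, False
    for aid, label, age in zip(vis["animal_id"], vis["visit_index"], vis["age_at_visit"]):
        if aid != prev_animal:
            prev_animal, prev_fn = aid, False
        post = age >= agep4[aid]
        elevated = post
        if post and p_false_negative > 0.0:
            fn = rng.random() < p_false_negative
            if cycle_constraint and prev_fn:
                fn = False
            if fn:
                elevated = False
            prev_fn = fn
        else:
            prev_fn = False
        out.append((aid, label, int(age), bool(elevated)))
    frame = pd.DataFrame(out, columns=["animal_id", "visit_index", "age_at_visit", "bp4_elevated"])
    return frame.reset_index(drop=True)


def simulate_study(config: SimulationConfig) -> StudyData:
    """Run the full generator: pedigree → population → visits → observations.

    Per-stage seeds are derived from ``config.seed`` so the whole study
    is reproducible from one integer.
    """
    root = np.random.default_rng(config.seed)
    stage_seeds = root.integers(2**31, size=5)

    # herd sizes determine the offspring count before the pedigree exists
    size_rng = np.random.default_rng(int(stage_seeds[0]))
    raw = np.clip(
        size_rng.normal(config.herd_size_mean, config.herd_size_sd, config.n_herds),
        config.min_herd_size,
        None,
    )
    n_offspring = int(np.round(raw).sum())

    pedigree = generate_pedigree(
        config.n_sires,
        n_dams=n_offspring,
        n_offspring=n_offspring,
        seed=int(stage_seeds[1]),
        max_dam_uses=config.max_dam_uses,
    )
    animals, truth = simulate_population(
        config.model_copy(update={"seed": int(stage_seeds[4])}), pedigree
    )
    ages = schedule_visits(animals, config, seed=int(stage_seeds[2]))
    visits = observe_bp4(
        truth,
        ages,
        config.p_false_negative,
        seed=int(stage_seeds[3]),
        cycle_constraint=config.cycle_constraint,
    )
    return StudyData(pedigree=pedigree, animals=animals, truth=truth, visits=visits)
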