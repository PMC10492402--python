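"""Single-site Gibbs sampler for the animal/sire mixed model.

The model is ``y = X b + Z u + e`` with herd as a fixed class effect
(absorbing the intercept), jersey fraction as a fixed covariate, and a
random genetic effect per animal (covariance ``A sigma2_u``) or per
sire. Three response modes share one sampler:

* ``continuous`` — y observed (AGEVISIT phenotypes);
* ``interval`` — y latent within per-record [lower, upper] bounds,
  redrawn every iteration from its truncated-normal full conditional
  (AUG data augmentation);
* ``ordinal`` — y a latent liability constrained to the threshold
  interval of its category (CAT threshold model, fixed thresholds).

Variances get scaled-inverse-chi-square updates; location effects are
drawn single-site from their normal full conditionals with flat priors
on the fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import ndtr, ndtri

from ._kernels import location_sweep
from .config import MCMCConfig, ModelSpec
from .pedigree import Pedigree, henderson_a_inverse, sire_covariance

__all__ = [
    "Design",
    "ChainState",
    "ChainResults",
    "build_design",
    "sample_truncated_normal",
    "update_location",
    "update_variances",
    "update_response",
    "run_chain",
    "solve_mme",
]


def sample_truncated_normal(mean, sd, lower, upper, rng: np.random.Generator):
    """Draw from Normal(mean, sd^2) restricted to [lower, upper].

    Vectorized inverse-CDF sampling carried out in whichever tail is
    better conditioned, so draws stay accurate when the interval sits
    far (6+ SD) from the mean. Bounds may be infinite.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(lower >= upper):
        raise ValueError("require lower < upper for every record")
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    shape = np.broadcast_shapes(a.shape, b.shape)
    a, b = np.broadcast_to(a, shape).copy(), np.broadcast_to(b, shape).copy()
    u = rng.random(shape)

    # mirror intervals wholly in the left tail into the right tail
    flip = b <= 0
    a[flip], b[flip] = -b[flip], -a[flip]

    right = a >= 0  # interval in the right tail: interpolate survival probs
    sf_a = ndtr(-np.where(right, a, 0.0))
    sf_b = ndtr(-np.where(right, b, 0.0))
    sf_x = sf_a + u * (sf_b - sf_a)
    x_right = -ndtri(np.maximum(sf_x, np.nextafter(0, 1)))

    cdf_a = ndtr(np.where(right, 0.0, a))
    cdf_b = ndtr(np.where(right, 0.0, b))
    x_mid = ndtri(cdf_a + u * (cdf_b - cdf_a))

    x = np.where(right, x_right, x_mid)
    x[flip] = -x[flip]
    # guard floating point escapes at extreme truncation
    a0 = (lower - mean) / sd
    b0 = (upper - mean) / sd
    x = np.clip(x, a0, b0)
    out = mean + sd * x
    return out if out.shape else float(out)


@dataclass
class Design:
    """Preprocessed model structure shared by every update."""

    record_ids: list[str]
    herd_labels: list[str]
    herd_code: np.ndarray
    jersey: np.ndarray
    level_ids: list[str]
    rec_level: np.ndarray
    ainv: sparse.csr_matrix
    response_mode: str
    y_obs: Optional[np.ndarray] = None        # continuous
    lower: Optional[np.ndarray] = None        # interval / ordinal bounds
    upper: Optional[np.ndarray] = None
    category: Optional[np.ndarray] = None     # ordinal 1..K
    n_categories: int = 0
    # CSR maps built once for the compiled sweep
    herd_indptr: np.ndarray = field(default=None, repr=False)
    herd_recs: np.ndarray = field(default=None, repr=False)
    lvl_indptr: np.ndarray = field(default=None, repr=False)
    lvl_recs: np.ndarray = field(default=None, repr=False)

    @property
    def n_records(self) -> int:
        return len(self.record_ids)

    @property
    def n_fixed(self) -> int:
        return len(self.herd_labels) + 1

    @property
    def fixed_labels(self) -> list[str]:
        return [f"herd:{h}" for h in self.herd_labels] + ["jersey_fraction"]


def _csr_groups(codes: np.ndarray, n_groups: int) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(codes, kind="stable").astype(np.int64)
    counts = np.bincount(codes, minlength=n_groups)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return indptr, order


def build_design(
    phenotypes: pd.DataFrame,
    animals: pd.DataFrame,
    pedigree: Pedigree,
    model_spec: ModelSpec,
) -> Design:
    """Assemble incidence structure and response payload for one fit.

    In animal mode ``u`` spans the whole pedigree (parents without
    records are connected through A^-1); in sire mode ``u`` spans the
    sires of the phenotyped animals with identity or pedigree
    covariance.
    """
    merged = phenotypes.merge(animals, on="animal_id", how="left", validate="many_to_one")
    if merged["herd_id"].isna().any() or merged["jersey_fraction"].isna().any():
        bad = merged.loc[merged["herd_id"].isna(), "animal_id"].tolist()[:5]
        raise ValueError(f"records with unknown herd/breed, e.g. {bad}")
    merged = merged.sort_values("animal_id").reset_index(drop=True)

    herd_labels = sorted(merged["herd_id"].unique())
    herd_index = {h: j for j, h in enumerate(herd_labels)}
    herd_code = merged["herd_id"].map(herd_index).to_numpy(dtype=np.int64)
    jersey = merged["jersey_fraction"].to_numpy(dtype=float)

    if model_spec.random_effect == "animal":
        level_ids = list(pedigree.ids)
        rec_level = np.array(
            [pedigree.index[a] for a in merged["animal_id"]], dtype=np.int64
        )
        ainv = henderson_a_inverse(pedigree)
    else:
        sire_of = {
            pedigree.ids[i]: pedigree.sire[i] for i in range(len(pedigree))
        }
        rec_sires = []
        for a in merged["animal_id"]:
            s = sire_of.get(a, -1)
            if s < 0:
                raise ValueError(f"animal {a} has no known sire for the sire model")
            rec_sires.append(pedigree.ids[s])
        level_ids = sorted(set(rec_sires))
        lvl_index = {s: i for i, s in enumerate(level_ids)}
        rec_level = np.array([lvl_index[s] for s in rec_sires], dtype=np.int64)
        cov = sire_covariance(pedigree, level_ids, model_spec.sire_covariance)
        ainv = sparse.csr_matrix(np.linalg.inv(cov))

    design = Design(
        record_ids=merged["animal_id"].tolist(),
        herd_labels=herd_labels,
        herd_code=herd_code,
        jersey=jersey,
        level_ids=level_ids,
        rec_level=rec_level,
        ainv=ainv,
        response_mode=model_spec.response_mode,
    )
    design.herd_indptr, design.herd_recs = _csr_groups(herd_code, len(herd_labels))
    design.lvl_indptr, design.lvl_recs = _csr_groups(rec_level, len(level_ids))
    if (np.diff(design.herd_indptr) == 0).any():
        warnings.warn("fixed herd level with zero observations is skipped in updates")

    mode = model_spec.response_mode
    if mode == "continuous":
        design.y_obs = merged["agevisit_days"].to_numpy(dtype=float)
    elif mode == "interval":
        design.lower = merged["lower_bound_days"].to_numpy(dtype=float)
        design.upper = merged["upper_bound_days"].to_numpy(dtype=float)
        if np.any(design.lower >= design.upper):
            raise ValueError("interval records require lower < upper")
    elif mode == "ordinal":
        design.category = merged["cat_score"].to_numpy(dtype=np.int64)
        design.n_categories = int(design.category.max())
        if design.category.min() < 1:
            raise ValueError("ordinal scores must be 1-based")
    else:
        raise ValueError(f"unknown response mode {mode!r}")
    return design


def _threshold_bounds(
    category: np.ndarray, thresholds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    t = np.concatenate([[-np.inf], thresholds, [np.inf]])
    return t[category - 1], t[category]


@dataclass
class ChainState:
    """Mutable sampler state for one iteration."""

    b: np.ndarray
    u: np.ndarray
    y: np.ndarray
    e: np.ndarray  # y - Xb - Zu, kept in sync by every update
    sigma2_u: float
    sigma2_e: float
    thresholds: Optional[np.ndarray] = None

    def fitted(self) -> np.ndarray:
        return self.y - self.e


def _prior_scales(model_spec: ModelSpec) -> tuple[float, float]:
    vp = model_spec.default_phenotypic_variance()
    genetic = model_spec.prior_h2 * vp
    if model_spec.random_effect == "sire":
        genetic /= 4.0
    return genetic, (1.0 - model_spec.prior_h2) * vp


def initial_state(design: Design, model_spec: ModelSpec) -> ChainState:
    """Start at herd means of a working response with zero genetic effects."""
    if design.response_mode == "continuous":
        y = design.y_obs.copy()
    elif design.response_mode == "interval":
        y = 0.5 * (design.lower + design.upper)
    else:
        thresholds = _fixed_thresholds(design, model_spec)
        t = np.concatenate([[thresholds[0] - 1.0], thresholds, [thresholds[-1] + 1.0]])
        y = 0.5 * (t[design.category - 1] + t[design.category])
    b = np.zeros(design.n_fixed)
    for j in range(len(design.herd_labels)):
        recs = design.herd_recs[design.herd_indptr[j] : design.herd_indptr[j + 1]]
        if len(recs):
            b[j] = y[recs].mean()
    u = np.zeros(len(design.level_ids))
    e = y - b[design.herd_code] - b[-1] * design.jersey
    s_u, s_e = _prior_scales(model_spec)
    state = ChainState(b=b, u=u, y=y, e=e, sigma2_u=s_u, sigma2_e=s_e)
    if design.response_mode == "ordinal":
        state.thresholds = _fixed_thresholds(design, model_spec)
        if _residual_fixed(design, model_spec):
            state.sigma2_e = 1.0
    return state


def _residual_fixed(design: Design, model_spec: ModelSpec) -> bool:
    """Liability models identified by fixing sigma2_e = 1: the
    threshold-sampling variant, and binary responses (no interior
    category to pin the scale, so fixed thresholds cannot identify it)."""
    return design.response_mode == "ordinal" and (
        model_spec.estimate_thresholds or design.n_categories <= 2
    )


def _fixed_thresholds(design: Design, model_spec: ModelSpec) -> np.ndarray:
    k = design.n_categories
    if model_spec.thresholds is not None:
        t = np.asarray(model_spec.thresholds, dtype=float)
        if len(t) != k - 1:
            raise ValueError(f"{k} categories need {k - 1} thresholds, got {len(t)}")
        return t
    return np.arange(k - 1, dtype=float)


def update_response(
    state: ChainState, design: Design, model_spec: ModelSpec, rng: np.random.Generator
) -> None:
    """Redraw latent responses (interval/ordinal); no-op for continuous."""
    if design.response_mode == "continuous":
        return
    if design.response_mode == "interval":
        lo, hi = design.lower, design.upper
    else:
        lo, hi = _threshold_bounds(design.category, state.thresholds)
    mu = state.fitted()
    y_new = sample_truncated_normal(mu, np.sqrt(state.sigma2_e), lo, hi, rng)
    state.e += y_new - state.y
    state.y = np.asarray(y_new)


def update_location(
    state: ChainState, design: Design, model_spec: ModelSpec, rng: np.random.Generator
) -> None:
    """Single-site draws of every fixed and random location effect."""
    z_b = rng.standard_normal(design.n_fixed)
    z_u = rng.standard_normal(len(design.level_ids))
    lam = state.sigma2_e / state.sigma2_u
    location_sweep(
        state.e,
        state.b,
        state.u,
        z_b,
        z_u,
        design.herd_indptr,
        design.herd_recs,
        design.jersey,
        float(design.jersey @ design.jersey),
        design.lvl_indptr,
        design.lvl_recs,
        design.ainv.indptr.astype(np.int64),
        design.ainv.indices.astype(np.int64),
        design.ainv.data,
        lam,
        state.sigma2_e,
    )


def update_variances(
    state: ChainState, design: Design, model_spec: ModelSpec, rng: np.random.Generator
) -> None:
    """Scaled-inverse-chi-square draws for sigma2_u and sigma2_e."""
    if not model_spec.estimate_variances:
        return
    s_u, s_e = _prior_scales(model_spec)
    q = len(design.level_ids)
    uau = float(state.u @ (design.ainv @ state.u))
    df_u = model_spec.nu_genetic + q
    state.sigma2_u = (uau + model_spec.nu_genetic * s_u) / rng.chisquare(df_u)
    if _residual_fixed(design, model_spec):
        state.sigma2_e = 1.0  # residual fixed for identification
    else:
        n = design.n_records
        df_e = model_spec.nu_residual + n
        sse = float(state.e @ state.e)
        state.sigma2_e = (sse + model_spec.nu_residual * s_e) / rng.chisquare(df_e)


def _update_thresholds(
    state: ChainState, design: Design, rng: np.random.Generator
) -> None:
    """Albert–Chib uniform threshold draws (first threshold pinned)."""
    t = state.thresholds
    k = design.n_categories
    for j in range(1, k - 1):  # thresholds t_2 .. t_{K-1}
        cat_below = design.category == j + 1
        cat_above = design.category == j + 2
        lo = state.y[cat_below].max() if cat_below.any() else t[j - 1]
        hi = state.y[cat_above].min() if cat_above.any() else t[j] + 1.0
        lo = max(lo, t[j - 1])
        if j + 1 < len(t):
            hi = min(hi, t[j + 1])
        t[j] = rng.uniform(lo, hi) if hi > lo else lo


@dataclass
class ChainResults:
    """Post-burn-in thinned posterior samples of one chain."""

    fixed_labels: list[str]
    level_ids: list[str]
    b: np.ndarray            # (S, n_fixed)
    u: np.ndarray            # (S, n_levels)
    sigma2_u: np.ndarray     # (S,)
    sigma2_e: np.ndarray     # (S,)
    response_mode: str
    random_effect: str
    thresholds: Optional[np.ndarray] = None  # (S, K-1) when sampled/fixed
    y: Optional[np.ndarray] = None           # (S, n_records) when stored
    record_ids: Optional[list[str]] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.b.shape[0]


def run_chain(
    phenotypes: pd.DataFrame,
    animals: pd.DataFrame,
    pedigree: Pedigree,
    model_spec: ModelSpec,
    mcmc: MCMCConfig,
) -> ChainResults:
    """Run the full Gibbs chain; bit-reproducible from ``mcmc.seed``.

    The scan order within an iteration is response → location →
    variances (→ thresholds when sampled), pinned for reproducibility.
    """
    design = build_design(phenotypes, animals, pedigree, model_spec)
    state = initial_state(design, model_spec)
    rng = np.random.default_rng(mcmc.seed)

    n_store = (mcmc.n_iterations - mcmc.burn_in + mcmc.thin - 1) // mcmc.thin
    b_s = np.empty((n_store, design.n_fixed))
    u_s = np.empty((n_store, len(design.level_ids)))
    s2u_s = np.empty(n_store)
    s2e_s = np.empty(n_store)
    t_s = (
        np.empty((n_store, design.n_categories - 1))
        if design.response_mode == "ordinal"
        else None
    )
    y_s = np.empty((n_store, design.n_records)) if mcmc.store_responses else None

    cap = 1e12 * max(1.0, model_spec.default_phenotypic_variance())
    k = 0
    for it in range(mcmc.n_iterations):
        update_response(state, design, model_spec, rng)
        update_location(state, design, model_spec, rng)
        update_variances(state, design, model_spec, rng)
        if design.response_mode == "ordinal" and model_spec.estimate_thresholds:
            _update_thresholds(state, design, rng)
        if not (np.isfinite(state.sigma2_u) and np.isfinite(state.sigma2_e)) or (
            state.sigma2_u > cap or state.sigma2_e > cap
        ):
            raise RuntimeError(
                f"divergent variance at iteration {it}: "
                f"sigma2_u={state.sigma2_u:.3g}, sigma2_e={state.sigma2_e:.3g}"
            )
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            b_s[k] = state.b
            u_s[k] = state.u
            s2u_s[k] = state.sigma2_u
            s2e_s[k] = state.sigma2_e
            if t_s is not None:
                t_s[k] = state.thresholds
            if y_s is not None:
                y_s[k] = state.y
            k += 1

    return ChainResults(
        fixed_labels=design.fixed_labels,
        level_ids=list(design.level_ids),
        b=b_s[:k],
        u=u_s[:k],
        sigma2_u=s2u_s[:k],
        sigma2_e=s2e_s[:k],
        response_mode=design.response_mode,
        random_effect=model_spec.random_effect,
        thresholds=t_s[:k] if t_s is not None else None,
        y=y_s[:k] if y_s is not None else None,
        record_ids=design.record_ids if y_s is not None else None,
        meta={
            "seed": mcmc.seed,
            "n_iterations": mcmc.n_iterations,
            "burn_in": mcmc.burn_in,
            "thin": mcmc.thin,
        },
    )


def solve_mme(design: Design, y: np.ndarray, sigma2_u: float, sigma2_e: float):
    """Direct dense solve of the mixed-model equations (small-problem oracle).

    Returns ``(b_hat, u_hat)`` for known variance components — the
    posterior mean of the location effects under flat fixed-effect
    priors, used to validate the sampler.
    """
    n, q = design.n_records, len(design.level_ids)
    nf = design.n_fixed
    X = np.zeros((n, nf))
    X[np.arange(n), design.herd_code] = 1.0
    X[:, -1] = design.jersey
    Z = np.zeros((n, q))
    Z[np.arange(n), design.rec_level] = 1.0
    lam = sigma2_e / sigma2_u
    lhs = np.block(
        [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * design.ainv.toarray()]]
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[:nf], sol[nf:]
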