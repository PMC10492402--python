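"""Compiled inner loop of the single-site Gibbs sampler.

The location sweep is the only hot sequential part of an iteration
(every other update is vectorizable), so it alone is JIT-compiled. All
randomness enters through pre-generated standard-normal deviates, so
the sweep is a pure function of its inputs and the chain stays
reproducible from a single numpy Generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def location_sweep(
    e: np.ndarray,          # residual y - Xb - Zu, updated in place
    b: np.ndarray,          # fixed effects: herd levels then covariate slope
    u: np.ndarray,          # random-effect levels, updated in place
    z_b: np.ndarray,        # standard-normal deviates for b
    z_u: np.ndarray,        # standard-normal deviates for u
    herd_indptr: np.ndarray,
    herd_recs: np.ndarray,  # CSR: records of each herd
    cov: np.ndarray,        # covariate value per record
    cov_w: float,           # sum of squared covariate values
    lvl_indptr: np.ndarray,
    lvl_recs: np.ndarray,   # CSR: records of each random level
    ainv_indptr: np.ndarray,
    ainv_indices: np.ndarray,
    ainv_data: np.ndarray,  # CSR of the relationship-matrix inverse
    lam: float,             # sigma2_e / sigma2_u
    sigma2_e: float,
) -> None:
    n_herds = herd_indptr.shape[0] - 1
    # herd class effects (flat prior); a herd with no records is skipped
    for j in range(n_herds):
        lo, hi = herd_indptr[j], herd_indptr[j + 1]
        w = float(hi - lo)
        if w == 0.0:
            continue
        r = w * b[j]
        for k in range(lo, hi):
            r += e[herd_recs[k]]
        new = r / w + np.sqrt(sigma2_e / w) * z_b[j]
        delta = new - b[j]
        b[j] = new
        for k in range(lo, hi):
            e[herd_recs[k]] -= delta

    # covariate slope (flat prior)
    if cov_w > 0.0:
        j = n_herds
        r = cov_w * b[j]
        for i in range(e.shape[0]):
            r += cov[i] * e[i]
        new = r / cov_w + np.sqrt(sigma2_e / cov_w) * z_b[j]
        delta = new - b[j]
        b[j] = new
        for i in range(e.shape[0]):
            e[i] -= delta * cov[i]

    # random levels: data term plus pedigree prior lam * A^-1
    n_levels = lvl_indptr.shape[0] - 1
    for i in range(n_levels):
        lo, hi = lvl_indptr[i], lvl_indptr[i + 1]
        wz = float(hi - lo)
        r = wz * u[i]
        for k in range(lo, hi):
            r += e[lvl_recs[k]]
        dii = 0.0
        for k in range(ainv_indptr[i], ainv_indptr[i + 1]):
            col = ainv_indices[k]
            if col == i:
                dii = ainv_data[k]
            else:
                r -= lam * ainv_data[k] * u[col]
        wtot = wz + lam * dii
        new = r / wtot + np.sqrt(sigma2_e / wtot) * z_u[i]
        delta = new - u[i]
        u[i] = new
        for k in range(lo, hi):
            e[lvl_recs[k]] -= delta
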