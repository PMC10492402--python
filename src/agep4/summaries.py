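"""Posterior summaries: means, 95% credibility intervals, heritability,
EBVs, Monte-Carlo standard errors and the batch-overlap convergence rule.

Credibility intervals are empirical central 95% intervals (2.5th and
97.5th percentiles, linear-interpolation definition). Convergence is
judged the way practitioners eyeball long single chains: split the
post-burn-in samples into consecutive batches of 10,000 and require the
95% CrIs of every pair of batches to overlap for all monitored
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gibbs import ChainResults

__all__ = [
    "PosteriorSummary",
    "summarize",
    "heritability_chain",
    "mc_standard_error",
    "convergence_check",
    "extract_ebvs",
    "summarize_chain",
]

CRI_LEVELS = (2.5, 97.5)


@dataclass(frozen=True)
class PosteriorSummary:
    parameter: str
    posterior_mean: float
    cri_lower: float
    cri_upper: float

    def covers(self, value: float) -> bool:
        return self.cri_lower <= value <= self.cri_upper


def summarize(samples: Sequence[float], parameter: str = "") -> PosteriorSummary:
    """Posterior mean and central 95% credibility interval."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 samples to summarize")
    lo, hi = np.percentile(arr, CRI_LEVELS)
    return PosteriorSummary(parameter, float(arr.mean()), float(lo), float(hi))


def heritability_chain(chain: ChainResults) -> np.ndarray:
    """Per-draw heritability: sigma2_u/(sigma2_u + sigma2_e) for the
    animal model, 4 sigma2_s/(sigma2_s + sigma2_e) for the sire model.

    Computed draw-by-draw (never as a ratio of posterior means) so the
    CrI reflects the joint posterior of the variance components.
    """
    s2u, s2e = chain.sigma2_u, chain.sigma2_e
    if chain.random_effect == "sire":
        return 4.0 * s2u / (s2u + s2e)
    return s2u / (s2u + s2e)


def mc_standard_error(samples: Sequence[float], n_batches: int = 30) -> float:
    """Batch-means Monte-Carlo SE of a (possibly autocorrelated) chain mean."""
    arr = np.asarray(samples, dtype=float)
    n_batches = min(n_batches, max(2, arr.size // 10))
    size = arr.size // n_batches
    means = arr[: size * n_batches].reshape(n_batches, size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def _monitored(chain: ChainResults) -> dict[str, np.ndarray]:
    out = {
        "sigma2_u": chain.sigma2_u,
        "sigma2_e": chain.sigma2_e,
        "h2": heritability_chain(chain),
        "jersey_fraction": chain.b[:, -1],
    }
    return out


def convergence_check(
    chain: ChainResults | Mapping[str, np.ndarray],
    batch_size: int = 10_000,
) -> tuple[bool, pd.DataFrame]:
    """Batch-overlap convergence rule on the monitored parameters.

    Post-burn-in samples are grouped consecutively in lots of
    ``batch_size``; the chain passes iff, for every monitored parameter,
    the 95% CrIs of all batch pairs overlap. Returns the verdict and a
    per-parameter × batch summary table (with an ``overlaps_all``
    column).
    """
    params = chain if isinstance(chain, Mapping) else _monitored(chain)
    rows = []
    ok = True
    for name, samples in params.items():
        arr = np.asarray(samples, dtype=float)
        n_batches = arr.size // batch_size
        if n_batches < 2:
            raise ValueError(
                f"need >= 2 batches of {batch_size} samples, have {arr.size}"
            )
        intervals = []
        for g in range(n_batches):
            lo, hi = np.percentile(arr[g * batch_size : (g + 1) * batch_size], CRI_LEVELS)
            intervals.append((float(lo), float(hi)))
        param_ok = all(
            intervals[i][0] <= intervals[j][1] and intervals[j][0] <= intervals[i][1]
            for i in range(n_batches)
            for j in range(i + 1, n_batches)
        )
        ok = ok and param_ok
        for g, (lo, hi) in enumerate(intervals):
            rows.append((name, g, lo, hi, param_ok))
    table = pd.DataFrame(
        rows, columns=["parameter", "batch", "cri_lower", "cri_upper", "overlaps_all"]
    )
    return ok, table


def extract_ebvs(chain: ChainResults) -> pd.DataFrame:
    """Posterior-mean EBV per random-effect level (animal or sire)."""
    if chain.u.size == 0:
        raise ValueError("chain holds no random-effect samples")
    return pd.DataFrame({"id": chain.level_ids, "ebv": chain.u.mean(axis=0)})


def summarize_chain(chain: ChainResults) -> pd.DataFrame:
    """One summary row per scalar parameter of interest."""
    entries = {
        "sigma2_u": chain.sigma2_u,
        "sigma2_e": chain.sigma2_e,
        "h2": heritability_chain(chain),
        "jersey_fraction": chain.b[:, -1],
    }
    rows = [summarize(v, k) for k, v in entries.items()]
    for j, label in enumerate(chain.fixed_labels[:-1]):
        rows.append(summarize(chain.b[:, j], label))
    return pd.DataFrame(
        [(r.parameter, r.posterior_mean, r.cri_lower, r.cri_upper) for r in rows],
        columns=["parameter", "mean", "cri_lower", "cri_upper"],
    )
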