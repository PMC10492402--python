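"""Full factorial experiment: 3 derivation methods × 8 visit scenarios.

One simulated population is shared by every cell (scenarios are views
of the same observations). Per cell the matching mixed model is fitted
(CAT: ordinal sire model; AGEVISIT: continuous animal model; AUG:
interval-censored animal model) and the comparison criteria against the
three-visit EML control are computed: Pearson correlations of sire EBVs
(sires with enough phenotyped daughters) and of posterior-mean herd
effects, plus heritability and Jersey breed-effect summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import MCMCConfig, ModelSpec, PhenotypeConfig, SimulationConfig
from .gibbs import ChainResults, run_chain
from .pedigree import Pedigree
from .phenotypes import SCENARIOS, apply_scenario, derive_phenotypes
from .simulate import StudyData, simulate_study
from .summaries import PosteriorSummary, extract_ebvs, heritability_chain, summarize

__all__ = [
    "METHOD_MODELS",
    "ComparisonReport",
    "sire_ebv_correlation",
    "herd_effect_correlation",
    "breed_effect_solution",
    "fit_method",
    "run_experiment",
]

CONTROL = "EML"

#: response/random-effect pairing per derivation method
METHOD_MODELS: dict[str, dict] = {
    "CAT": {"response_mode": "ordinal", "random_effect": "sire"},
    "AGEVISIT": {"response_mode": "continuous", "random_effect": "animal"},
    "AUG": {"response_mode": "interval", "random_effect": "animal"},
}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def sire_ebv_correlation(
    ebvs_control: pd.DataFrame,
    ebvs_test: pd.DataFrame,
    daughter_counts: Mapping[str, int],
    min_daughters: int = 5,
) -> float:
    """Pearson r between control and test EBVs over well-proven sires.

    Sires qualify on their control-scenario daughter count (the study's
    "at least 5 daughters with a phenotype" rule).
    """
    qualified = {s for s, n in daughter_counts.items() if n >= min_daughters}
    a = ebvs_control.set_index("id")["ebv"]
    b = ebvs_test.set_index("id")["ebv"]
    shared = sorted(qualified & set(a.index) & set(b.index))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} sires pass the daughter filter")
    return _pearson(a.loc[shared].to_numpy(), b.loc[shared].to_numpy())


def herd_effect_correlation(
    b_control: Mapping[str, float], b_test: Mapping[str, float]
) -> float:
    """Pearson r between posterior-mean herd solutions of two fits."""
    herds = sorted(set(b_control) & set(b_test))
    if len(herds) < 3:
        raise ValueError(f"only {len(herds)} shared herds")
    return _pearson(
        np.array([b_control[h] for h in herds]), np.array([b_test[h] for h in herds])
    )


def breed_effect_solution(chain: ChainResults) -> PosteriorSummary:
    """Summary of the Jersey-fraction covariate: the expected difference
    between a pure Jersey and a pure Holstein–Friesian (negative means
    Jersey reaches BP4 elevation earlier)."""
    return summarize(chain.b[:, -1], "jersey_fraction")


def _herd_solutions(chain: ChainResults) -> dict[str, float]:
    means = chain.b.mean(axis=0)
    return {
        lbl.removeprefix("herd:"): float(means[j])
        for j, lbl in enumerate(chain.fixed_labels[:-1])
    }


def fit_method(
    visits: pd.DataFrame,
    animals: pd.DataFrame,
    pedigree: Pedigree,
    method: str,
    mcmc: MCMCConfig,
    phen_config: Optional[PhenotypeConfig] = None,
    model_overrides: Optional[dict] = None,
) -> ChainResults:
    """Derive one method's phenotypes from (scenario-reduced) visits and
    run the matching Gibbs chain."""
    phen = derive_phenotypes(visits, method, phen_config)
    spec = ModelSpec(**{**METHOD_MODELS[method], **(model_overrides or {})})
    return run_chain(phen, animals, pedigree, spec, mcmc)


@dataclass
class ComparisonReport:
    """Per method × scenario comparison tables plus run metadata."""

    heritability: pd.DataFrame      # scenario, method, mean, cri_lower, cri_upper
    breed_effect: pd.DataFrame      # scenario, method, mean, cri_lower, cri_upper
    ebv_correlation: pd.DataFrame   # scenario, method, r
    herd_correlation: pd.DataFrame  # scenario, method, r
    meta: dict = field(default_factory=dict)

    def table(self, which: str) -> pd.DataFrame:
        """Wide scenario × method rendering of one criterion table."""
        frame = getattr(self, which)
        value = "r" if "r" in frame.columns else "mean"
        return frame.pivot(index="scenario", columns="method", values=value)


def run_experiment(
    sim_config: SimulationConfig,
    mcmc: MCMCConfig,
    scenarios: Sequence[str] = tuple(SCENARIOS),
    methods: Sequence[str] = ("CAT", "AGEVISIT", "AUG"),
    seed: int = 1,
    min_daughters: int = 5,
    phen_config: Optional[PhenotypeConfig] = None,
    model_overrides: Optional[dict] = None,
    study: Optional[StudyData] = None,
) -> ComparisonReport:
    """Simulate one population and fill the method × scenario grid.

    ``seed`` drives the population (unless a pre-simulated ``study`` is
    supplied), the RANDOM1 herd assignment and every chain. The control
    scenario is always fitted (it anchors the correlations) even if not
    requested, but only requested scenarios appear in the report.
    """
    unknown = [m for m in methods if m not in METHOD_MODELS]
    if unknown:
        raise ValueError(f"unknown methods {unknown}")
    root = np.random.default_rng(seed)
    if study is None:
        study = simulate_study(sim_config.model_copy(update={"seed": int(root.integers(2**31))}))
    scenario_seed = int(root.integers(2**31))

    wanted = list(dict.fromkeys(scenarios))
    fit_list = wanted if CONTROL in wanted else [CONTROL] + wanted
    chain_seeds = {
        (m, s): int(root.integers(2**31)) for m in methods for s in fit_list
    }

    # daughters per sire among phenotyped animals (control retains everyone)
    sire_of = {
        study.pedigree.ids[i]: study.pedigree.ids[study.pedigree.sire[i]]
        for i in range(len(study.pedigree))
        if study.pedigree.sire[i] >= 0
    }
    phenotyped = set(study.animals["animal_id"])
    counts: dict[str, int] = {}
    for a in phenotyped:
        s = sire_of.get(a)
        if s is not None:
            counts[s] = counts.get(s, 0) + 1

    herit, breed, ebv_corr, herd_corr = [], [], [], []
    for method in methods:
        results: dict[str, ChainResults] = {}
        for scen in fit_list:
            reduced = apply_scenario(
                study.visits, scen, seed=scenario_seed, animals=study.animals
            )
            results[scen] = fit_method(
                reduced,
                study.animals,
                study.pedigree,
                method,
                mcmc.model_copy(update={"seed": chain_seeds[(method, scen)]}),
                phen_config,
                model_overrides,
            )
        control = results[CONTROL]
        ebv_control = extract_ebvs(control)
        if control.random_effect == "animal":
            ebv_control = ebv_control[ebv_control["id"].isin(counts)].reset_index(drop=True)
        herd_control = _herd_solutions(control)
        for scen in wanted:
            chain = results[scen]
            h2 = summarize(heritability_chain(chain), "h2")
            be = breed_effect_solution(chain)
            herit.append((scen, method, h2.posterior_mean, h2.cri_lower, h2.cri_upper))
            breed.append((scen, method, be.posterior_mean, be.cri_lower, be.cri_upper))
            ebv_test = extract_ebvs(chain)
            r_ebv = sire_ebv_correlation(ebv_control, ebv_test, counts, min_daughters)
            ebv_corr.append((scen, method, r_ebv))
            r_herd = herd_effect_correlation(herd_control, _herd_solutions(chain)) if len(
                herd_control
            ) >= 3 else np.nan
            herd_corr.append((scen, method, r_herd))

    cri_cols = ["scenario", "method", "mean", "cri_lower", "cri_upper"]
    return ComparisonReport(
        heritability=pd.DataFrame(herit, columns=cri_cols),
        breed_effect=pd.DataFrame(breed, columns=cri_cols),
        ebv_correlation=pd.DataFrame(ebv_corr, columns=["scenario", "method", "r"]),
        herd_correlation=pd.DataFrame(herd_corr, columns=["scenario", "method", "r"]),
        meta={
            "seed": seed,
            "scenarios": wanted,
            "methods": list(methods),
            "min_daughters": min_daughters,
            "n_animals": len(study.animals),
            "mcmc": {"n_iterations": mcmc.n_iterations, "burn_in": mcmc.burn_in},
        },
    )
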