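"""Visit-censoring scenarios and the three phenotype-derivation methods.

From (possibly reduced) binary BP4 visit records each animal receives:

* CAT — the ordinal index of the first elevated visit among those
  retained, with never-elevated animals in the top category
  (n_retained + 1); analysed later as a threshold (liability) model.
* AGEVISIT — age at the first elevated visit, with right-censored
  animals penalized to ``last visit age + penalty`` (default 31 d).
* AUG — a [lower, upper] age interval: upper is the first elevated
  visit age (or a fixed ceiling, default 500 d, if never elevated);
  lower is the preceding non-elevated visit age (or a fixed floor,
  default 200 d, if elevated at the first retained visit).

Eight visit scenarios reduce the records before derivation: the
three-visit control (EML), every one- and two-visit subset, and one
randomly assigned visit per herd (RANDOM1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import PhenotypeConfig
from .pedigree import UNKNOWN, Pedigree
from .simulate import VISIT_LABELS

__all__ = [
    "Scenario",
    "SCENARIOS",
    "apply_scenario",
    "derive_cat",
    "derive_agevisit",
    "derive_aug_bounds",
    "derive_phenotypes",
    "exclusion_filter",
]


@dataclass(frozen=True)
class Scenario:
    """A visit-retention rule. ``retained`` is a subset of E/M/L, or
    None for the one-random-visit-per-herd design."""

    code: str
    retained: Optional[tuple[str, ...]]

    @property
    def n_visits(self) -> int:
        return 1 if self.retained is None else len(self.retained)


SCENARIOS: dict[str, Scenario] = {
    "EML": Scenario("EML", ("E", "M", "L")),
    "RANDOM1": Scenario("RANDOM1", None),
    "E": Scenario("E", ("E",)),
    "M": Scenario("M", ("M",)),
    "L": Scenario("L", ("L",)),
    "EM": Scenario("EM", ("E", "M")),
    "ML": Scenario("ML", ("M", "L")),
    "EL": Scenario("EL", ("E", "L")),
}


def apply_scenario(
    records: pd.DataFrame,
    scenario: Scenario | str,
    seed: int = 0,
    animals: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Drop visit records according to a scenario.

    RANDOM1 assigns each herd one visit label uniformly at random
    (seeded, per herd — not per animal) and therefore needs ``animals``
    to map animal to herd.
    """
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise ValueError(f"unknown scenario code {scenario!r}") from None
    if scenario.retained is not None:
        keep = records["visit_index"].isin(scenario.retained)
        return records.loc[keep].reset_index(drop=True)
    if animals is None:
        raise ValueError("RANDOM1 requires the animals table to resolve herds")
    rng = np.random.default_rng(seed)
    herds = sorted(animals["herd_id"].unique())
    pick = {h: VISIT_LABELS[rng.integers(3)] for h in herds}
    herd_of = dict(zip(animals["animal_id"], animals["herd_id"]))
    keep = [
        v == pick[herd_of[a]] for a, v in zip(records["animal_id"], records["visit_index"])
    ]
    return records.loc[keep].reset_index(drop=True)


def _first_elevated(elevated: Sequence[bool]) -> Optional[int]:
    for k, e in enumerate(elevated):
        if e:
            return k
    return None


def derive_cat(ages: Sequence[int], elevated: Sequence[bool]) -> int:
    """Ordinal score: 1-based index of the first elevated retained visit;
    never-elevated animals score ``n_retained + 1``."""
    if len(ages) == 0:
        raise ValueError("no retained visits")
    k = _first_elevated(elevated)
    return len(ages) + 1 if k is None else k + 1


def derive_agevisit(
    ages: Sequence[int], elevated: Sequence[bool], penalty_days: int = 31
) -> int:
    """Age at the first elevated retained visit; right-censored animals
    get ``last retained visit age + penalty_days``."""
    if len(ages) == 0:
        raise ValueError("no retained visits")
    k = _first_elevated(elevated)
    return int(ages[-1]) + penalty_days if k is None else int(ages[k])


def derive_aug_bounds(
    ages: Sequence[int],
    elevated: Sequence[bool],
    floor_days: int = 200,
    ceiling_days: int = 500,
) -> tuple[int, int]:
    """[lower, upper] bounds on the true age at first BP4 elevation."""
    if len(ages) == 0:
        raise ValueError("no retained visits")
    if min(ages) <= floor_days or max(ages) >= ceiling_days:
        raise ValueError(
            f"visit ages must lie strictly inside ({floor_days}, {ceiling_days})"
        )
    k = _first_elevated(elevated)
    if k is None:
        return int(ages[-1]), ceiling_days
    upper = int(ages[k])
    lower = floor_days if k == 0 else int(ages[k - 1])
    return lower, upper


def _censor_class(elevated: Sequence[bool]) -> str:
    k = _first_elevated(elevated)
    if k is None:
        return "right"
    return "left" if k == 0 else "interval"


def derive_phenotypes(
    records: pd.DataFrame,
    method: str,
    config: PhenotypeConfig | None = None,
) -> pd.DataFrame:
    """Per-animal phenotypes from (already scenario-reduced) visit records.

    Returns one row per animal with the method's value columns plus
    ``censor_class``; visits are ordered by age within animal.
    """
    if method not in ("CAT", "AGEVISIT", "AUG"):
        raise ValueError(f"unknown method {method!r}")
    cfg = config or PhenotypeConfig()
    rows = []
    for aid, grp in records.sort_values(["animal_id", "age_at_visit"]).groupby(
        "animal_id", sort=True
    ):
        ages = grp["age_at_visit"].to_numpy()
        elev = grp["bp4_elevated"].to_numpy().astype(bool)
        cls = _censor_class(elev)
        if method == "CAT":
            rows.append((aid, derive_cat(ages, elev), cls))
        elif method == "AGEVISIT":
            rows.append((aid, derive_agevisit(ages, elev, cfg.penalty_days), cls))
        else:
            lo, hi = derive_aug_bounds(ages, elev, cfg.floor_days, cfg.ceiling_days)
            rows.append((aid, lo, hi, cls))
    if method == "CAT":
        cols = ["animal_id", "cat_score", "censor_class"]
    elif method == "AGEVISIT":
        cols = ["animal_id", "agevisit_days", "censor_class"]
    else:
        cols = ["animal_id", "lower_bound_days", "upper_bound_days", "censor_class"]
    return pd.DataFrame(rows, columns=cols)


def exclusion_filter(
    animals: pd.DataFrame,
    pedigree: Pedigree,
    records: pd.DataFrame,
    required_visits: Iterable[str] = VISIT_LABELS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study's record-exclusion rules.

    Drops, in order of precedence: animals with identification issues
    (duplicated id or absent from the pedigree), incomplete parentage
    (unknown sire or dam), and incomplete observation data (any
    required visit record missing). Returns the retained animals and a
    tally per exclusion reason.
    """
    required = list(required_visits)
    tally = {"identification": 0, "incomplete_parentage": 0, "incomplete_observations": 0}

    dup = animals["animal_id"].duplicated(keep=False)
    visits_of = records.groupby("animal_id")["visit_index"].apply(set)

    keep_rows = []
    for row, is_dup in zip(animals.itertuples(index=False), dup):
        aid = row.animal_id
        if is_dup or aid not in pedigree.index:
            tally["identification"] += 1
            continue
        i = pedigree.index[aid]
        if pedigree.sire[i] == UNKNOWN or pedigree.dam[i] == UNKNOWN:
            tally["incomplete_parentage"] += 1
            continue
        have = visits_of.get(aid, set())
        if any(v not in have for v in required):
            tally["incomplete_observations"] += 1
            continue
        keep_rows.append(row)
    retained = pd.DataFrame(keep_rows, columns=animals.columns)
    return retained.reset_index(drop=True), tally
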