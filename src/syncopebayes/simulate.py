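"""Synthetic multi-centre syncope cohorts.

Cohorts are generated exactly under the model's assumptions: a
patient's diagnosis class is drawn from the centre's prior prevalence
of cardiac syncope, and each predictor the centre collects is then
drawn independently from its class-conditional level distribution.
Predictors a centre never collected are entirely missing; collected
predictors additionally carry class-independent patient-level
missingness at the centre's observed rate. Real cohorts violate the
conditional-independence assumption (predictors are correlated given
the diagnosis), so performance measured on these cohorts is an upper
bound, not an estimate, of real-data performance.

:func:`PopulationSpec.from_published` parameterizes a generator from
the bundled per-centre class-conditional counts of the four test
cohorts (Calgary, Amsterdam, Milan, Rochester).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .cpt import CPTSet
from .derivation import StudyCounts
from .errors import DegenerateTableError
from .io import read_config, write_config
from .predictors import (
    CANDIDATE_PREDICTORS,
    CARDIAC,
    CLASSES,
    FULL_MODEL,
    MISSING,
    NONCARDIAC,
    get_predictor,
)

POPULATIONS = ("calgary", "amsterdam", "milan", "rochester")


@dataclass(frozen=True)
class PopulationSpec:
    """Generative description of one centre's cohort.

    ``class_conditional[predictor][class][level]`` are the per-class
    level probabilities of each collected predictor; ``missing_rate``
    is the class-independent probability that a collected predictor is
    nonetheless missing for a patient.
    """

    name: str
    n: int
    prior: float
    class_conditional: dict[str, dict[str, dict[str, float]]]
    missing_rate: dict[str, float] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("cohort size must be positive")
        if not 0.0 < self.prior < 1.0:
            raise ValueError(f"prior must be in (0,1), got {self.prior}")
        for pred, by_class in self.class_conditional.items():
            spec = get_predictor(pred)
            for cls in CLASSES:
                probs = by_class[cls]
                if set(probs) != set(spec.levels):
                    raise ValueError(f"{self.name}/{pred}/{cls}: levels mismatch")
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{self.name}/{pred}/{cls}: probabilities do not sum to 1")
        for pred, r in self.missing_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{self.name}/{pred}: missing rate {r} outside [0,1]")

    @property
    def observed(self) -> tuple[str, ...]:
        return tuple(self.class_conditional)

    # ---- construction from the published test-population tables ------
    @classmethod
    def from_published(
        cls,
        population: str,
        n: int | None = None,
        include_rochester_blurred_vision: bool = False,
    ) -> "PopulationSpec":
        """Spec parameterized by a published test cohort.

        Level probabilities are exact count ratios over the non-missing
        patients; per-predictor missing rates are the observed reporting
        shortfall relative to the class sizes. Rochester's blurred-vision
        variable was mined from free text rather than asked, so it is
        dropped by default. Milan's number of spells was recorded as
        "one spell" vs "more than one" and is used here, as published,
        as a proxy for the model's <=2 / >2 coding.
        """
        counts = datasets.load_population_counts()
        sizes = datasets.load_population_sizes()
        if population not in sizes.index:
            raise KeyError(f"unknown population {population!r}")
        sub = counts[counts["population"] == population]
        n_class = {
            CARDIAC: int(sizes.loc[population, "n_cardiac"]),
            NONCARDIAC: int(sizes.loc[population, "n_noncardiac"]),
        }
        n_total = n_class[CARDIAC] + n_class[NONCARDIAC]
        cc: dict[str, dict[str, dict[str, float]]] = {}
        missing_rate: dict[str, float] = {}
        for pred, grp in sub.groupby("predictor", sort=False):
            if (
                population == "rochester"
                and pred == "blurred_vision"
                and not include_rochester_blurred_vision
            ):
                continue
            spec = get_predictor(pred)
            by_class = {}
            reported = 0
            for c in CLASSES:
                cgrp = grp[grp["class"] == c]
                by_level = dict(zip(cgrp["level"], cgrp["count"]))
                total = sum(by_level.values())
                reported += total
                by_class[c] = {
                    l: by_level.get(l, 0) / total for l in spec.levels
                }
            cc[pred] = by_class
            missing_rate[pred] = max(0.0, 1.0 - reported / n_total)
        notes = ""
        if population == "milan":
            notes = (
                "number_of_spells uses the published one-spell vs more-than-one "
                "proxy for the <=2 / >2 coding"
            )
        return cls(
            population,
            n if n is not None else n_total,
            n_class[CARDIAC] / n_total,
            cc,
            missing_rate,
            notes,
        )

    # ---- persistence -------------------------------------------------
    def to_file(self, path) -> None:
        write_config(
            {
                "name": self.name,
                "n": self.n,
                "prior": self.prior,
                "class_conditional": self.class_conditional,
                "missing_rate": self.missing_rate,
                "notes": self.notes,
            },
            path,
        )

    @classmethod
    def from_file(cls, path) -> "PopulationSpec":
        payload = read_config(path)
        return cls(
            payload["name"],
            int(payload["n"]),
            float(payload["prior"]),
            payload["class_conditional"],
            {k: float(v) for k, v in payload.get("missing_rate", {}).items()},
            payload.get("notes", ""),
        )


def generate_cohort(spec: PopulationSpec, seed: int) -> pd.DataFrame:
    """Sample a cohort from a population spec; deterministic given seed.

    Returns the standard patient table: patient_id, population,
    true_class, and one column per modelled predictor (empty string
    where missing or never collected).
    """
    rng = np.random.default_rng(seed)
    n = spec.n
    is_cardiac = rng.random(n) < spec.prior
    cls = np.where(is_cardiac, CARDIAC, NONCARDIAC)
    data: dict[str, object] = {
        "patient_id": [f"{spec.name}-{i:06d}" for i in range(n)],
        "population": spec.name,
        "true_class": cls,
    }
    for pred in FULL_MODEL:
        if pred not in spec.class_conditional:
            data[pred] = [MISSING] * n
            continue
        levels = np.array(get_predictor(pred).levels, dtype=object)
        col = np.empty(n, dtype=object)
        for c in CLASSES:
            mask = cls == c
            probs = [spec.class_conditional[pred][c][l] for l in levels]
            col[mask] = rng.choice(levels, size=int(mask.sum()), p=probs)
        rate = spec.missing_rate.get(pred, 0.0)
        if rate > 0:
            col[rng.random(n) < rate] = MISSING
        data[pred] = col
    return pd.DataFrame(data)


def exact_cohort(spec: PopulationSpec, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Deterministic cohort reproducing a published centre's cell counts
    exactly (each predictor column is filled per class with the exact
    level counts, padded with missing values to the class size). Margins
    are exact per predictor; the joint distribution across predictors is
    arbitrary, which is irrelevant for per-predictor frequency checks.
    """
    if counts is None:
        counts = datasets.load_population_counts()
    sizes = datasets.load_population_sizes()
    n_class = {
        CARDIAC: int(sizes.loc[spec.name, "n_cardiac"]),
        NONCARDIAC: int(sizes.loc[spec.name, "n_noncardiac"]),
    }
    sub = counts[counts["population"] == spec.name]
    n = n_class[CARDIAC] + n_class[NONCARDIAC]
    cls = np.array([CARDIAC] * n_class[CARDIAC] + [NONCARDIAC] * n_class[NONCARDIAC])
    data: dict[str, object] = {
        "patient_id": [f"{spec.name}-x{i:06d}" for i in range(n)],
        "population": spec.name,
        "true_class": cls,
    }
    for pred, grp in sub.groupby("predictor", sort=False):
        col = []
        for c in CLASSES:
            cgrp = grp[grp["class"] == c]
            vals: list[str] = []
            for level, k in zip(cgrp["level"], cgrp["count"]):
                vals.extend([level] * int(k))
            vals.extend([MISSING] * (n_class[c] - len(vals)))
            col.extend(vals)
        data[pred] = col
    return pd.DataFrame(data)


# ---- parameter recovery ----------------------------------------------
def cohort_priors(cohort: pd.DataFrame) -> dict[str, float]:
    """Observed cardiac fraction per population."""
    if "true_class" not in cohort.columns:
        raise DegenerateTableError("cohort has no true_class column")
    out = {}
    for pop, grp in cohort.groupby("population", sort=False):
        n_car = int((grp["true_class"] == CARDIAC).sum())
        if n_car == 0 or n_car == len(grp):
            raise DegenerateTableError(f"{pop}: both diagnosis classes must be present")
        out[pop] = n_car / len(grp)
    return out


def cohort_study_counts(cohort: pd.DataFrame) -> dict[str, list[StudyCounts]]:
    """Class-conditional level counts over non-missing values, one
    pseudo-study per population per predictor."""
    cohort_priors(cohort)  # validates classes
    out: dict[str, list[StudyCounts]] = {}
    for pop, grp in cohort.groupby("population", sort=False):
        for pred in CANDIDATE_PREDICTORS:
            if pred not in grp.columns:
                continue
            spec = get_predictor(pred)
            col = grp[pred].astype(object)
            observed = col.map(lambda v: v not in (None, MISSING) and v == v and v != "")
            if not observed.any():
                continue
            counts: dict[str, tuple[int, ...]] = {}
            for c in CLASSES:
                vals = col[observed & (grp["true_class"] == c)]
                if len(vals) == 0:
                    continue
                vc = vals.value_counts()
                counts[c] = tuple(int(vc.get(l, 0)) for l in spec.levels)
            if counts:
                out.setdefault(pred, []).append(StudyCounts(str(pop), spec, counts))
    return out


def fit_cpts_from_cohort(cohort: pd.DataFrame) -> CPTSet:
    """Maximum-likelihood CPT estimates from a labelled cohort: observed
    class-conditional level frequencies over non-missing values, with
    the observed cardiac fraction per population as prior. Predictors
    must have observations in both classes."""
    from .derivation import derive_cpts, pool_counts

    grouped = cohort_study_counts(cohort)
    pooled = {}
    for pred, tabs in grouped.items():
        table = pool_counts(tabs)
        if any(t == 0 for t in table.row_totals):
            raise DegenerateTableError(f"{pred}: no observations in one class")
        pooled[pred] = table
    if not pooled:
        raise DegenerateTableError("no predictor has observations")
    return derive_cpts(pooled, cohort_priors(cohort))
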