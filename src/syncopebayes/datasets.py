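"""Bundled derivation and test-population fixtures.

``literature_counts.csv`` carries the per-study predictor-by-diagnosis
frequencies of the seven derivation studies in long format. Two rows of
the published pooled table are internally inconsistent between their
per-study cells and their printed totals:

* age — the per-study cells sum to (2, 65, 227 | 323, 427, 363) while
  the printed totals are (3, 65, 226 | 234, 427, 363); only the printed
  totals reproduce the published chi-square of 171.7 (the non-cardiac
  <40 total looks like a digit transposition of 323). The fixture
  carries the printed totals under the pseudo-study id ``table_totals``.
* diaphoresis — the per-study yes/no cells are swapped relative to the
  printed totals (86/382 cardiac, 753/1015 non-cardiac), which are
  self-consistent and reproduce the published chi-square (92.6) and
  likelihood ratio (1.42); the fixture carries the totals.

``study_significance_synthetic.csv`` is reconstructed (synthetic)
metadata: the source publications' per-study significance reports are
not individually tabulated, so the fixture records each of the eleven
candidate predictors as significant in at least three studies, matching
the published selection statement. It exists so the selection rule is
exercisable; it is not a primary data source.

``test_population_counts.csv`` / ``test_population_sizes.csv`` carry the
published per-centre class-conditional predictor counts and class sizes
of the four test cohorts (Calgary, Amsterdam, Milan, Rochester). Where a
predictor's cells sum to less than the class size, the shortfall is
patient-level missingness.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .derivation import PooledTable, StudyCounts, pool_counts
from .predictors import CANDIDATE_PREDICTORS, CARDIAC, CLASSES, NONCARDIAC, get_predictor

_DATA = resources.files("syncopebayes") / "data"


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, keep_default_na=False)


def load_literature_counts() -> pd.DataFrame:
    """Long-format per-study counts: study_id, predictor, class, level, count."""
    df = _read("literature_counts.csv")
    df["count"] = df["count"].astype(int)
    return df


def study_counts_from_long(df: pd.DataFrame) -> dict[str, list[StudyCounts]]:
    """Group a long-format count table into per-predictor StudyCounts lists."""
    out: dict[str, list[StudyCounts]] = {}
    for (pred, study), grp in df.groupby(["predictor", "study_id"], sort=False):
        spec = get_predictor(pred)
        counts: dict[str, tuple[int, ...]] = {}
        for cls, cgrp in grp.groupby("class", sort=False):
            by_level = dict(zip(cgrp["level"], cgrp["count"]))
            unknown = set(by_level) - set(spec.levels)
            if unknown:
                raise ValueError(f"{study}/{pred}: unknown levels {sorted(unknown)}")
            counts[cls] = tuple(int(by_level.get(l, 0)) for l in spec.levels)
        out.setdefault(pred, []).append(StudyCounts(study, spec, counts))
    return out


def load_study_counts() -> dict[str, list[StudyCounts]]:
    return study_counts_from_long(load_literature_counts())


def load_pooled_tables() -> dict[str, PooledTable]:
    """Pooled 2 x K tables for all candidate predictors, in registry order."""
    grouped = load_study_counts()
    return {
        name: pool_counts(grouped[name])
        for name in CANDIDATE_PREDICTORS
        if name in grouped
    }


def load_study_significance() -> dict[str, set[str]]:
    """Reconstructed per-predictor sets of studies reporting significance."""
    df = _read("study_significance_synthetic.csv")
    return {p: set(g["study_id"]) for p, g in df.groupby("predictor", sort=False)}


def load_population_counts() -> pd.DataFrame:
    """Per-centre class-conditional predictor counts of the test cohorts."""
    df = _read("test_population_counts.csv")
    df["count"] = df["count"].astype(int)
    return df


def load_population_sizes() -> pd.DataFrame:
    df = _read("test_population_sizes.csv")
    return df.set_index("population")


def test_population_priors() -> dict[str, float]:
    """Prevalence of cardiac syncope per test centre (prior probabilities):
    roughly 21% Calgary, 9% Amsterdam, 5% Milan, 11% Rochester."""
    sizes = load_population_sizes()
    total = sizes["n_cardiac"] + sizes["n_noncardiac"]
    return dict(sizes["n_cardiac"] / total)


def literature_age_spells_marginals() -> dict[str, dict[str, float]]:
    """Overall (both-class) pooled marginal distributions of age category
    and number of spells in the derivation literature; the basis of the
    default standardization plan for resampling."""
    pooled = load_pooled_tables()
    out = {}
    for name in ("age_category", "number_of_spells"):
        t = pooled[name]
        cols = t.col_totals
        out[name] = {
            level: c / t.grand_total for level, c in zip(t.predictor.levels, cols)
        }
    return out
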