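"""Pooling of literature count tables and derivation of model parameters.

The derivation sample is a set of published per-study cross-tabulations
of a predictor against the final diagnosis (cardiac vs. non-cardiac
syncope). Pooled tables are obtained by summing the reported frequencies
across studies; association is assessed with a Pearson chi-square test
(no continuity correction) and, for binary predictors, a diagnostic
likelihood ratio at the cardiac-pointing level. Conditional probability
tables are the raw pooled class-conditional frequencies — no smoothing
or pseudocounts are applied, so zero cells are legal and are handled at
inference time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cpt import CPTSet
from .errors import AlignmentError, DegenerateTableError, UndefinedRatioError
from .predictors import CARDIAC, CLASSES, NONCARDIAC, PredictorSpec, get_predictor


@dataclass(frozen=True)
class StudyCounts:
    """One study's predictor-by-diagnosis count table.

    ``counts[cls]`` is a tuple of non-negative integers aligned with
    ``predictor.levels``. A study that did not report the predictor for
    a class simply omits that class (``available`` reflects this).
    """

    study_id: str
    predictor: PredictorSpec
    counts: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        for cls, row in self.counts.items():
            if cls not in CLASSES:
                raise ValueError(f"{self.study_id}: unknown class {cls!r}")
            if len(row) != len(self.predictor.levels):
                raise AlignmentError(
                    f"{self.study_id}/{self.predictor.name}: "
                    f"{len(row)} counts for {len(self.predictor.levels)} levels"
                )
            if any(c < 0 for c in row):
                raise ValueError(f"{self.study_id}: negative count")
            if sum(row) == 0:
                raise ValueError(
                    f"{self.study_id}/{self.predictor.name}/{cls}: "
                    "reported class with all-zero counts"
                )

    def available(self, cls: str) -> bool:
        return cls in self.counts


@dataclass(frozen=True)
class PooledTable:
    """Summed diagnosis-by-level counts for one predictor (2 x K)."""

    predictor: PredictorSpec
    counts: tuple[tuple[int, ...], tuple[int, ...]]  # rows: cardiac, noncardiac

    @property
    def row_totals(self) -> tuple[int, int]:
        return tuple(sum(r) for r in self.counts)

    @property
    def col_totals(self) -> tuple[int, ...]:
        return tuple(int(c) for c in np.sum(self.counts, axis=0))

    @property
    def grand_total(self) -> int:
        return int(np.sum(self.counts))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    def row(self, cls: str) -> tuple[int, ...]:
        return self.counts[0] if cls == CARDIAC else self.counts[1]


@dataclass(frozen=True)
class AssociationResult:
    """Chi-square association and (binary predictors) likelihood ratio."""

    predictor: PredictorSpec
    chi2: float
    df: int
    p_value: float
    likelihood_ratio: float | None = None


def pool_counts(tables: list[StudyCounts]) -> PooledTable:
    """Sum per-study counts into one pooled table.

    Studies not reporting the predictor for a class contribute zero to
    that row. All tables must reference the same predictor (and hence
    the same ordered levels).
    """
    if not tables:
        raise AlignmentError("no study tables supplied")
    spec = tables[0].predictor
    if any(t.predictor != spec for t in tables[1:]):
        names = sorted({t.predictor.name for t in tables})
        raise AlignmentError(f"mixed predictors in pooling: {names}")
    k = len(spec.levels)
    pooled = {cls: np.zeros(k, dtype=int) for cls in CLASSES}
    for t in tables:
        for cls in CLASSES:
            if t.available(cls):
                pooled[cls] += np.asarray(t.counts[cls], dtype=int)
    return PooledTable(
        spec, (tuple(int(c) for c in pooled[CARDIAC]), tuple(int(c) for c in pooled[NONCARDIAC]))
    )


def chi_square(pooled: PooledTable) -> AssociationResult:
    """Pearson chi-square on the pooled 2 x K table, no continuity correction.

    df = K - 1 for the two diagnosis rows; p from the chi-square
    distribution. Raises :class:`DegenerateTableError` if any marginal
    is zero (an expected cell would be zero).
    """
    obs = pooled.as_array()
    if pooled.grand_total == 0:
        raise DegenerateTableError(f"{pooled.predictor.name}: empty table")
    if any(t == 0 for t in pooled.row_totals) or any(t == 0 for t in pooled.col_totals):
        raise DegenerateTableError(f"{pooled.predictor.name}: zero marginal")
    res = stats.chi2_contingency(obs, correction=False)
    return AssociationResult(
        pooled.predictor, float(res.statistic), int(res.dof), float(res.pvalue)
    )


def likelihood_ratio(pooled: PooledTable, level: str | None = None) -> float:
    """Diagnostic likelihood ratio P(level|cardiac) / P(level|noncardiac).

    Computed from the exact pooled counts, never from rounded
    percentages. By convention reported at the predictor's
    cardiac-pointing level (the default when ``level`` is omitted):
    presence for supine syncope, effort syncope, male sex and a low
    number of spells; absence for nausea, diaphoresis, prodrome and
    blurred vision.
    """
    spec = pooled.predictor
    if not spec.is_binary:
        raise UndefinedRatioError(f"{spec.name}: likelihood ratio needs a binary predictor")
    if level is None:
        level = spec.cardiac_level
    if level not in spec.levels:
        raise UndefinedRatioError(f"{spec.name}: unknown level {level!r}")
    j = spec.levels.index(level)
    n_car, n_non = pooled.row_totals
    if n_car == 0 or n_non == 0:
        raise DegenerateTableError(f"{spec.name}: empty class row")
    p_non = pooled.counts[1][j] / n_non
    if p_non == 0.0:
        raise UndefinedRatioError(
            f"{spec.name}: P({level}|noncardiac)=0, ratio undefined"
        )
    return (pooled.counts[0][j] / n_car) / p_non


def counts_from_mean_sd(
    n: int, mean: float, sd: float, bin_edges: tuple[float, ...]
) -> tuple[int, ...]:
    """Reconstruct per-bin patient counts from a reported mean and SD of age.

    Allocates ``n`` patients to the bins delimited by ``bin_edges``
    (open-ended on both sides) according to the normal CDF, rounds each
    bin to the nearest integer, and reconciles any rounding residual
    into the largest bin so the counts always sum to ``n``. With
    ``sd == 0`` the whole mass falls in the bin containing the mean
    (boundary values go to the upper bin).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    edges = tuple(float(e) for e in bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if sd == 0:
        cdf = np.array([1.0 if mean < e else 0.0 for e in edges])
    else:
        cdf = stats.norm.cdf(np.asarray(edges), loc=mean, scale=sd)
    probs = np.diff(np.concatenate(([0.0], cdf, [1.0])))
    counts = np.rint(probs * n).astype(int)
    counts[np.argmax(counts)] += n - counts.sum()
    return tuple(int(c) for c in counts)


def select_predictors(
    significant_studies: dict[str, set[str]],
    associations: dict[str, AssociationResult],
    min_studies: int = 3,
    alpha: float = 0.05,
) -> list[str]:
    """Apply the predictor-inclusion rule.

    A candidate is retained when (a) the source literature reports a
    statistically significant association in at least ``min_studies``
    studies and (b) the pooled association is significant at ``alpha``.
    The per-study significance sets are supplied as metadata — several
    source studies reported only multivariable significance, without a
    cross-tabulation, so they cannot be recomputed from count tables.
    Bystander-observed signs never enter the candidate list.
    """
    retained = []
    for name, assoc in associations.items():
        n_sig = len(significant_studies.get(name, ()))
        if n_sig >= min_studies and assoc.p_value < alpha:
            retained.append(name)
    return retained


def derive_cpts(
    pooled: dict[str, PooledTable], priors: dict[str, float]
) -> CPTSet:
    """Maximum-likelihood CPTs from pooled counts: P(level|class) =
    pooled count / class total. Priors are copied through unchanged."""
    tables: dict[str, dict[str, dict[str, float]]] = {}
    for name, table in pooled.items():
        spec = table.predictor
        by_class: dict[str, dict[str, float]] = {}
        for cls in CLASSES:
            row = table.row(cls)
            total = sum(row)
            if total == 0:
                raise DegenerateTableError(f"{name}/{cls}: zero class total")
            by_class[cls] = {
                level: count / total for level, count in zip(spec.levels, row)
            }
        tables[name] = by_class
    return CPTSet(tables, dict(priors))


def association_table(
    pooled: dict[str, PooledTable],
) -> pd.DataFrame:
    """Summary table mirroring the pooled-association report: one row
    per predictor with chi2, df, p and (binary predictors) the
    likelihood ratio at the cardiac-pointing level."""
    rows = []
    for name, table in pooled.items():
        assoc = chi_square(table)
        lr = None
        if table.predictor.is_binary:
            try:
                lr = likelihood_ratio(table)
            except UndefinedRatioError:
                lr = None
        rows.append(
            {
                "predictor": name,
                "chi2": assoc.chi2,
                "df": assoc.df,
                "p": assoc.p_value,
                "likelihood_ratio": lr,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
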