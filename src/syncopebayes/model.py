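"""The joint-probability (naive Bayes) diagnostic model.

The probability that a patient has cardiac syncope is the normalized
product of the class-conditional probabilities of the observed
historical criteria, multiplied by the population-specific prior
prevalence of cardiac syncope:

    P(cardiac | x) = pi * prod_j P(x_j|cardiac)
                     / [ pi * prod_j P(x_j|cardiac)
                         + (1-pi) * prod_j P(x_j|noncardiac) ]

with the product running over the observed, non-missing predictors.
Missing predictors are marginalized by omission, which is exact under
the model's conditional-independence assumption. Products are
accumulated in log space; zero-probability cells propagate as genuine
zeros, and a patient for whom both class likelihoods vanish raises
:class:`~syncopebayes.errors.UndefinedPosteriorError` rather than
silently returning 0/0.

:class:`CardiacSyncopeModel` is built from per-study literature count
tables (or refitted from a patient-level cohort); its :meth:`fit`
pools the tables, screens the candidate predictors, estimates the
conditional probability tables and returns a
:class:`CardiacSyncopeResults` that predicts, evaluates and summarizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import datasets, evaluation
from .cpt import CPTSet
from .derivation import (
    PooledTable,
    StudyCounts,
    association_table,
    derive_cpts,
    pool_counts,
    select_predictors,
)
from .errors import UndefinedPosteriorError
from .predictors import (
    CANDIDATE_PREDICTORS,
    CARDIAC,
    FULL_MODEL,
    MISSING,
    NONCARDIAC,
    PARSIMONIOUS_MODEL,
    get_predictor,
    parsimonious_subset,
)

DEFAULT_CUTOFF = 0.02


@dataclass(frozen=True)
class PredictionResult:
    """Posterior probability of cardiac syncope for one patient."""

    posterior: float
    prior: float
    used_predictors: tuple[str, ...]
    label_at_cutoff: str


def classify(posterior: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Label a posterior at the decision cutoff (default 0.02, chosen to
    favour sensitivity). A posterior exactly at the cutoff is classified
    cardiac — the sensitivity-favouring boundary convention."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0,1), got {cutoff}")
    return CARDIAC if posterior >= cutoff else NONCARDIAC


def _is_missing(value) -> bool:
    if value is None or value is MISSING:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return value == ""


def posterior(
    values: dict[str, str],
    cpts: CPTSet,
    population: str | None = None,
    prior: float | None = None,
    subset=None,
    cutoff: float = DEFAULT_CUTOFF,
) -> PredictionResult:
    """Posterior probability of cardiac syncope for one patient record.

    ``values`` maps predictor names to observed levels; missing entries
    (absent, ``None``, empty string or NaN) contribute nothing. Either a
    ``population`` with a prior in ``cpts`` or an explicit ``prior``
    must be supplied. ``subset`` restricts the evidence to the named
    predictors (e.g. the parsimonious five).
    """
    if prior is None:
        if population is None:
            raise ValueError("need a population or an explicit prior")
        try:
            prior = cpts.priors[population]
        except KeyError:
            raise KeyError(f"no prior for population {population!r}") from None
    names = tuple(subset) if subset is not None else cpts.predictors
    unknown = [n for n in names if n not in cpts.tables]
    if unknown:
        raise KeyError(f"predictors not in model: {unknown}")

    log_c = log_n = 0.0
    zero_c = zero_n = False
    used: list[str] = []
    for name in names:
        v = values.get(name)
        if _is_missing(v):
            continue
        spec = get_predictor(name)
        if v not in spec.levels:
            raise ValueError(f"{name}: illegal level {v!r}")
        p_c = cpts.prob(name, CARDIAC, v)
        p_n = cpts.prob(name, NONCARDIAC, v)
        if p_c == 0.0:
            zero_c = True
        else:
            log_c += np.log(p_c)
        if p_n == 0.0:
            zero_n = True
        else:
            log_n += np.log(p_n)
        used.append(name)

    if zero_c and zero_n:
        raise UndefinedPosteriorError(
            "both class likelihoods are zero for this record"
        )
    if zero_c:
        post = 0.0
    elif zero_n:
        post = 1.0
    else:
        post = float(expit(logit(prior) + log_c - log_n))
    return PredictionResult(post, prior, tuple(used), classify(post, cutoff))


class CardiacSyncopeModel:
    """Literature-based conditional-probabilities model of cardiac syncope.

    Parameters
    ----------
    study_counts : mapping predictor -> list of StudyCounts
        Per-study cross-tabulations of each candidate predictor against
        the diagnosis.
    priors : mapping population -> float
        Prior prevalence of cardiac syncope per patient population.
    significant_studies : mapping predictor -> set of study ids, optional
        Metadata naming the studies that reported a significant
        association for each candidate; used by the selection rule.
    """

    def __init__(
        self,
        study_counts: dict[str, list[StudyCounts]],
        priors: dict[str, float],
        significant_studies: dict[str, set[str]] | None = None,
    ):
        unknown = [n for n in study_counts if n not in CANDIDATE_PREDICTORS]
        if unknown:
            raise KeyError(f"unknown predictors: {unknown}")
        # keep registry order for stable reporting
        self.study_counts = {
            n: study_counts[n] for n in CANDIDATE_PREDICTORS if n in study_counts
        }
        self.priors = dict(priors)
        self.significant_studies = significant_studies

    @classmethod
    def from_literature(cls, priors: dict[str, float] | None = None) -> "CardiacSyncopeModel":
        """Model built from the bundled derivation-literature fixtures,
        with the four test-centre priors unless overridden."""
        return cls(
            datasets.load_study_counts(),
            priors if priors is not None else datasets.test_population_priors(),
            significant_studies=datasets.load_study_significance(),
        )

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame) -> "CardiacSyncopeModel":
        """Model refitted from a patient-level cohort with known diagnoses.

        Each population in the cohort becomes one pseudo-study per
        predictor (class-conditional counts over non-missing values),
        and its observed cardiac fraction becomes its prior.
        """
        from .simulate import cohort_study_counts, cohort_priors

        return cls(cohort_study_counts(cohort), cohort_priors(cohort))

    def pooled_tables(self) -> dict[str, PooledTable]:
        return {name: pool_counts(tabs) for name, tabs in self.study_counts.items()}

    def fit(
        self,
        select: bool = True,
        min_studies: int = 3,
        alpha: float = 0.05,
    ) -> "CardiacSyncopeResults":
        """Pool the study tables, screen candidates, estimate CPTs.

        With ``select=True`` (and significance metadata available) a
        candidate is retained only if significant in >= ``min_studies``
        source studies and in the pooled table at ``alpha``; otherwise
        every candidate with counts is retained.
        """
        pooled = self.pooled_tables()
        assoc = association_table(pooled)
        if select and self.significant_studies is not None:
            from .derivation import chi_square

            results = {name: chi_square(t) for name, t in pooled.items()}
            retained = select_predictors(
                self.significant_studies, results, min_studies=min_studies, alpha=alpha
            )
        else:
            retained = list(pooled)
        cpts = derive_cpts({n: pooled[n] for n in retained}, self.priors)
        return CardiacSyncopeResults(self, cpts, assoc, tuple(retained))


class CardiacSyncopeResults:
    """Fitted model: conditional probability tables, the pooled
    association table, and prediction / evaluation methods."""

    def __init__(
        self,
        model: CardiacSyncopeModel,
        cpts: CPTSet,
        association: pd.DataFrame,
        predictors: tuple[str, ...],
    ):
        self.model = model
        self.cpts = cpts
        self.association = association
        self.predictors = predictors

    # ---- prediction --------------------------------------------------
    def _resolve_subset(self, variant) -> tuple[str, ...]:
        if variant in (None, "full"):
            return self.predictors
        if variant == "parsimonious":
            subset = tuple(n for n in parsimonious_subset() if n in self.cpts.tables)
            if len(subset) != len(parsimonious_subset()):
                raise KeyError("parsimonious predictors missing from fitted model")
            return subset
        return tuple(variant)

    def predict_record(
        self, values, population=None, prior=None, variant=None,
        cutoff: float = DEFAULT_CUTOFF,
    ) -> PredictionResult:
        return posterior(
            values, self.cpts, population=population, prior=prior,
            subset=self._resolve_subset(variant), cutoff=cutoff,
        )

    def predict(
        self,
        cohort: pd.DataFrame,
        variant=None,
        cutoff: float = DEFAULT_CUTOFF,
    ) -> pd.DataFrame:
        """Posterior probabilities for a patient cohort table.

        ``cohort`` has one row per patient, a ``population`` column and
        one column per predictor (empty string = missing). Returns a
        frame with the posterior, the label at the cutoff and the number
        of predictors that contributed, preserving ``patient_id`` and
        ``true_class`` when present.
        """
        subset = self._resolve_subset(variant)
        n = len(cohort)
        if "population" not in cohort.columns:
            raise ValueError("cohort needs a 'population' column")
        pops = cohort["population"].astype(str)
        missing_prior = sorted(set(pops) - set(self.cpts.priors))
        if missing_prior:
            raise KeyError(f"no prior for populations {missing_prior}")
        pri = pops.map(self.cpts.priors).to_numpy(dtype=float)

        log_c = np.zeros(n)
        log_n = np.zeros(n)
        used = np.zeros(n, dtype=int)
        with np.errstate(divide="ignore"):
            for name in subset:
                if name not in cohort.columns:
                    continue
                spec = get_predictor(name)
                col = cohort[name].astype(object).to_numpy()
                observed = ~np.array([_is_missing(v) for v in col])
                if not observed.any():
                    continue
                levels = col[observed]
                bad = set(levels) - set(spec.levels)
                if bad:
                    raise ValueError(f"{name}: illegal levels {sorted(bad)}")
                lc = {l: np.log(self.cpts.prob(name, CARDIAC, l)) for l in spec.levels}
                ln = {l: np.log(self.cpts.prob(name, NONCARDIAC, l)) for l in spec.levels}
                log_c[observed] += np.array([lc[l] for l in levels])
                log_n[observed] += np.array([ln[l] for l in levels])
                used[observed] += 1

        both_zero = np.isneginf(log_c) & np.isneginf(log_n)
        if both_zero.any():
            raise UndefinedPosteriorError(
                f"both class likelihoods are zero for rows {np.flatnonzero(both_zero).tolist()}"
            )
        post = np.empty(n)
        zc = np.isneginf(log_c)
        zn = np.isneginf(log_n)
        ok = ~(zc | zn)
        post[zc] = 0.0
        post[zn] = 1.0
        post[ok] = expit(logit(pri[ok]) + log_c[ok] - log_n[ok])

        out = pd.DataFrame(
            {
                "population": pops.to_numpy(),
                "posterior": post,
                "label": np.where(post >= cutoff, CARDIAC, NONCARDIAC),
                "n_predictors_used": used,
            }
        )
        for extra in ("patient_id", "true_class"):
            if extra in cohort.columns:
                out.insert(0 if extra == "patient_id" else len(out.columns),
                           extra, cohort[extra].to_numpy())
        return out

    def evaluate(
        self,
        cohort: pd.DataFrame,
        variant=None,
        cutoff: float = DEFAULT_CUTOFF,
        by_population: bool = False,
    ) -> pd.DataFrame:
        """Discrimination metrics of the model on a labelled cohort:
        c-statistic plus sensitivity/specificity at the cutoff."""
        if "true_class" not in cohort.columns:
            raise ValueError("evaluation needs a 'true_class' column")
        preds = self.predict(cohort, variant=variant, cutoff=cutoff)
        groups = (
            preds.groupby("population", sort=False)
            if by_population
            else [("all", preds)]
        )
        rows = []
        for pop, grp in groups:
            c = evaluation.c_statistic(grp["posterior"], grp["true_class"])
            sens, spec = evaluation.sens_spec_at(
                grp["posterior"], grp["true_class"], cutoff=cutoff
            )
            rows.append(
                {
                    "population": pop,
                    "n": len(grp),
                    "c_statistic": c,
                    "sensitivity": sens,
                    "specificity": spec,
                    "cutoff": cutoff,
                }
            )
        return pd.DataFrame(rows)

    # ---- reporting ---------------------------------------------------
    def summary(self) -> str:
        """Text summary: retained predictors, pooled associations, priors."""
        lines = [
            "Cardiac syncope conditional-probabilities model",
            "=" * 63,
            f"Candidate predictors: {len(self.association)}   "
            f"retained: {len(self.predictors)}",
            "",
            f"{'predictor':<26}{'chi2':>8}{'df':>4}{'p':>10}{'LR':>7}  kept",
            "-" * 63,
        ]
        for name, row in self.association.iterrows():
            lr = f"{row['likelihood_ratio']:.2f}" if pd.notna(row["likelihood_ratio"]) else "-"
            p = "<0.0001" if row["p"] < 1e-4 else f"{row['p']:.4f}"
            kept = "yes" if name in self.predictors else "no"
            lines.append(
                f"{name:<26}{row['chi2']:>8.1f}{int(row['df']):>4}{p:>10}{lr:>7}  {kept}"
            )
        lines += ["-" * 63, "Priors P(cardiac):"]
        for pop, p in self.cpts.priors.items():
            lines.append(f"  {pop:<24}{p:.3f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<CardiacSyncopeResults: {len(self.predictors)} predictors, "
            f"{len(self.cpts.priors)} populations>"
        )
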