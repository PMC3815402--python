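"""Registry of the historical predictors of cardiac syncope.

Each predictor is a categorical clinical-history variable with two or
three ordered levels. One level is flagged as *cardiac-pointing*: the
level whose observation raises the probability of a cardiac cause
(presence of supine or effort syncope, male sex, a low number of prior
spells; absence of nausea, diaphoresis, prodrome or blurred vision).
Diagnostic likelihood ratios are reported at that level by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CARDIAC = "cardiac"
NONCARDIAC = "noncardiac"
CLASSES = (CARDIAC, NONCARDIAC)

#: Sentinel for a missing / not-collected categorical value.
MISSING = ""


@dataclass(frozen=True)
class PredictorSpec:
    """A named categorical predictor with ordered levels.

    Parameters
    ----------
    name : str
        Identifier used in count tables and cohort columns.
    levels : tuple of str
        Ordered category labels (2 or 3).
    cardiac_level : str
        The level reported as pointing toward cardiac syncope.
    """

    name: str
    levels: tuple[str, ...]
    cardiac_level: str

    def __post_init__(self) -> None:
        if not 2 <= len(self.levels) <= 3:
            raise ValueError(f"{self.name}: need 2 or 3 levels, got {len(self.levels)}")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"{self.name}: duplicate level labels")
        if self.cardiac_level not in self.levels:
            raise ValueError(
                f"{self.name}: cardiac level {self.cardiac_level!r} not in levels"
            )

    @property
    def is_binary(self) -> bool:
        return len(self.levels) == 2

    def other_level(self) -> str:
        """For a binary predictor, the non-cardiac-pointing level."""
        if not self.is_binary:
            raise ValueError(f"{self.name} is not binary")
        return next(l for l in self.levels if l != self.cardiac_level)


AGE_LEVELS = ("<40", "40-60", ">=60")

#: The eleven candidate predictors screened in the derivation literature.
CANDIDATE_PREDICTORS: dict[str, PredictorSpec] = {
    p.name: p
    for p in (
        PredictorSpec("age_category", AGE_LEVELS, ">=60"),
        PredictorSpec("gender", ("male", "female"), "male"),
        PredictorSpec("structural_heart_disease", ("yes", "no"), "yes"),
        PredictorSpec("number_of_spells", ("<=2", ">2"), "<=2"),
        PredictorSpec("nausea", ("yes", "no"), "no"),
        PredictorSpec("diaphoresis", ("yes", "no"), "no"),
        PredictorSpec("prodrome", ("yes", "no"), "no"),
        PredictorSpec("blurred_vision", ("yes", "no"), "no"),
        PredictorSpec("palpitations", ("yes", "no"), "no"),
        PredictorSpec("supine_syncope", ("yes", "no"), "yes"),
        PredictorSpec("effort_syncope", ("yes", "no"), "yes"),
    )
}

#: The ten predictors retained in the full model (palpitations is dropped:
#: its pooled association is not significant at the 0.05 level).
FULL_MODEL = (
    "age_category",
    "gender",
    "structural_heart_disease",
    "number_of_spells",
    "nausea",
    "diaphoresis",
    "prodrome",
    "blurred_vision",
    "supine_syncope",
    "effort_syncope",
)

#: The five predictors collected by every test centre.
PARSIMONIOUS_MODEL = (
    "age_category",
    "gender",
    "structural_heart_disease",
    "number_of_spells",
    "prodrome",
)


def parsimonious_subset() -> tuple[str, ...]:
    """Predictors common to all test datasets: age, gender, structural
    heart disease, number of spells, and prodromal symptoms."""
    return PARSIMONIOUS_MODEL


def get_predictor(name: str) -> PredictorSpec:
    try:
        return CANDIDATE_PREDICTORS[name]
    except KeyError:
        raise KeyError(f"unknown predictor {name!r}") from None
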