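"""Conditional probability tables and population priors.

A :class:`CPTSet` is the parameter set of the diagnostic model: for each
predictor, P(level | diagnosis class) for both classes, plus a prior
probability of cardiac syncope for each patient population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .predictors import CARDIAC, CLASSES, NONCARDIAC, PredictorSpec, get_predictor

_SUM_TOL = 1e-12


@dataclass
class CPTSet:
    """Class-conditional predictor probabilities plus population priors.

    Attributes
    ----------
    tables : dict
        ``tables[predictor][class][level]`` -> probability. For each
        predictor and class the level probabilities sum to one.
    priors : dict
        ``priors[population]`` -> prior probability of cardiac syncope,
        strictly inside (0, 1).
    """

    tables: dict[str, dict[str, dict[str, float]]]
    priors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, by_class in self.tables.items():
            spec = get_predictor(name)
            for cls in CLASSES:
                if cls not in by_class:
                    raise ValueError(f"{name}: missing class {cls!r}")
                probs = by_class[cls]
                if set(probs) != set(spec.levels):
                    raise ValueError(f"{name}/{cls}: levels do not match spec")
                for level, p in probs.items():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"{name}/{cls}/{level}: probability {p} outside [0,1]")
                total = sum(probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"{name}/{cls}: probabilities sum to {total}, not 1")
        for pop, prior in self.priors.items():
            if not 0.0 < prior < 1.0:
                raise ValueError(f"prior for {pop!r} must be in (0,1), got {prior}")

    @property
    def predictors(self) -> tuple[str, ...]:
        return tuple(self.tables)

    def prob(self, predictor: str, cls: str, level: str) -> float:
        return self.tables[predictor][cls][level]

    def subset(self, names) -> "CPTSet":
        """Restrict to the given predictors (priors kept)."""
        missing = [n for n in names if n not in self.tables]
        if missing:
            raise KeyError(f"predictors not in CPT set: {missing}")
        return CPTSet({n: self.tables[n] for n in names}, dict(self.priors))

    # ---- persistence -------------------------------------------------
    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"tables": self.tables, "priors": self.priors}, indent=2)
        )

    @classmethod
    def from_json(cls, path) -> "CPTSet":
        payload = json.loads(Path(path).read_text())
        return cls(payload["tables"], payload["priors"])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CPTSet):
            return NotImplemented
        if set(self.tables) != set(other.tables) or set(self.priors) != set(other.priors):
            return False
        for name, by_class in self.tables.items():
            for c, probs in by_class.items():
                ops = other.tables[name][c]
                if set(probs) != set(ops):
                    return False
                if any(abs(probs[l] - ops[l]) > _SUM_TOL for l in probs):
                    return False
        return all(abs(self.priors[p] - other.priors[p]) <= _SUM_TOL for p in self.priors)
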