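"""Core data containers shared across the pipeline.

The package analyses one symptom dimension at a time: occurrence (binary,
did the symptom occur), severity (ordinal, how bad it was), and distress
(ordinal, how bothersome it was).  Severity and distress carry category 0
for "symptom absent" plus the instrument's rating scale, so both live on
{0..4}.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

DIMENSIONS = ("occurrence", "severity", "distress")

#: inclusive category range per dimension; severity/distress use 0 = absent
#: plus the 4-point rating scale collapsed onto 1..4.
CATEGORY_RANGE = {
    "occurrence": (0, 1),
    "severity": (0, 4),
    "distress": (0, 4),
}


class ValidationError(ValueError):
    """Raised when input data violate a structural contract."""


@dataclass
class ItemResponseMatrix:
    """Respondents x symptoms categorical responses for one dimension.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Small non-negative integer categories, no missing entries.
    symptom_codes : list of str
        Unique short identifiers, one per column.
    dimension : {"occurrence", "severity", "distress"}
    """

    values: np.ndarray
    symptom_codes: list[str]
    dimension: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-d matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.round(self.values)):
                raise ValidationError("values must be integers")
            self.values = self.values.astype(np.int64)
        if self.dimension not in DIMENSIONS:
            raise ValidationError(
                f"dimension must be one of {DIMENSIONS}, got {self.dimension!r}"
            )
        lo, hi = CATEGORY_RANGE[self.dimension]
        if self.values.size and (self.values.min() < lo or self.values.max() > hi):
            raise ValidationError(
                f"{self.dimension} values must lie in [{lo}, {hi}]; "
                f"observed range [{self.values.min()}, {self.values.max()}]"
            )
        n, p = self.values.shape
        if p < 2:
            raise ValidationError("need at least two symptoms (p >= 2)")
        if len(self.symptom_codes) != p:
            raise ValidationError(
                f"{len(self.symptom_codes)} symptom codes for {p} columns"
            )
        if len(set(self.symptom_codes)) != p:
            raise ValidationError("symptom codes must be unique")
        if n < p:
            # Parameter-estimability heuristic: a p-node pairwise model has
            # p + p(p-1)/2 free parameters, so very small n is suspect.
            warnings.warn(
                f"n={n} respondents < p={p} symptoms; "
                "network parameters may not be reliably estimable",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class AnalysisConfig:
    """Tuning parameters for one dimension analysis.

    Defaults follow the analysis protocol: EBIC hyperparameter gamma = 0.25
    with the OR rule for nodewise Ising estimation, 1000 bootstrap
    iterations at alpha = 0.05, and a correlation-stability criterion of a
    0.7 correlation retained with 95% certainty.
    """

    gamma: float = 0.25
    rule: str = "OR"
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    bootstrap_B: int = 1000
    alpha: float = 0.05
    drop_proportions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
    cs_correlation: float = 0.7
    cs_certainty: float = 0.95
    walktrap_steps: int = 4
    seed: int = 0
    absent_policy: str = "zero"  # "zero" | "pairwise" handling of category 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValidationError("gamma must be non-negative")
        if self.rule not in ("AND", "OR"):
            raise ValidationError("rule must be 'AND' or 'OR'")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValidationError("lambda_min_ratio must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        self.drop_proportions = tuple(float(q) for q in self.drop_proportions)
        if any(not 0 < q < 1 for q in self.drop_proportions):
            raise ValidationError("drop proportions must lie strictly in (0, 1)")
        if list(self.drop_proportions) != sorted(set(self.drop_proportions)):
            raise ValidationError("drop proportions must be strictly increasing")
        if self.walktrap_steps < 1:
            raise ValidationError("walktrap_steps must be positive")
        if self.absent_policy not in ("zero", "pairwise"):
            raise ValidationError("absent_policy must be 'zero' or 'pairwise'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drop_proportions"] = list(self.drop_proportions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "drop_proportions" in d:
            d["drop_proportions"] = tuple(d["drop_proportions"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls.from_dict(json.loads(text))
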