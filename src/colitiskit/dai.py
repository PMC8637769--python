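"""Disease-activity-index (DAI) scoring for DSS-induced murine colitis.

The rubric combines four readouts per mouse: stool consistency (0-3), body
weight loss (0-4), fecal occult blood (0-3, a timed colorimetric test) and
histology (four 0-3 subscores: epithelial destruction, edema, crypt loss,
mucosal infiltration; summed to 0-12).  The total is the unweighted sum of
the four components, range 0-22.

Weight-loss bins are lower-inclusive: 0 -> 0, (0, 5) -> 1, [5, 10) -> 2,
[10, 20] -> 3, > 20 -> 4 (a loss of exactly 20% scores 3, matching the
strict "> 20%" wording of the top bin).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DAIObservation",
    "DAIScore",
    "STOOL_SCORES",
    "BLOOD_SCORES",
    "score_components",
    "weight_loss_score",
    "cohort_summary",
]

STOOL_SCORES: dict[str, int] = {
    "normal": 0,
    "soft": 1,
    "very_soft_semiformed": 2,
    "liquid_or_sticky": 3,
}

BLOOD_SCORES: dict[str, int] = {
    "negative_2min": 0,
    "purple_after_10s": 1,
    "light_purple_within_10s": 2,
    "heavy_purple_within_10s": 3,
}

HISTOLOGY_FIELDS = (
    "epithelial_destruction",
    "edema",
    "crypt_loss",
    "mucosa_infiltration",
)
HISTOLOGY_MAX = 3  # per-criterion scale, configurable at scoring time


@dataclass
class DAIObservation:
    """One mouse's readouts (categories from the closed vocabularies above)."""

    stool: str
    weight_loss: float  # percent body-weight loss, >= 0
    blood: str
    epithelial_destruction: int = 0
    edema: int = 0
    crypt_loss: int = 0
    mucosa_infiltration: int = 0

    def __post_init__(self) -> None:
        if self.stool not in STOOL_SCORES:
            raise ValueError(
                f"stool: unknown category {self.stool!r} "
                f"(expected one of {sorted(STOOL_SCORES)})"
            )
        if self.blood not in BLOOD_SCORES:
            raise ValueError(
                f"blood: unknown category {self.blood!r} "
                f"(expected one of {sorted(BLOOD_SCORES)})"
            )
        if self.weight_loss < 0:
            raise ValueError("weight_loss: must be >= 0 percent")
        for name in HISTOLOGY_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, int) and 0 <= v <= HISTOLOGY_MAX):
                raise ValueError(
                    f"{name}: subscore must be an integer in [0, {HISTOLOGY_MAX}], got {v!r}"
                )


@dataclass
class DAIScore:
    stool_score: int
    weight_score: int
    blood_score: int
    histology_score: int

    @property
    def total(self) -> int:
        return (
            self.stool_score
            + self.weight_score
            + self.blood_score
            + self.histology_score
        )


def weight_loss_score(pct: float) -> int:
    if pct < 0:
        raise ValueError("weight_loss: must be >= 0 percent")
    if pct == 0:
        return 0
    if pct < 5:
        return 1
    if pct < 10:
        return 2
    if pct <= 20:
        return 3
    return 4


def score_components(obs: DAIObservation) -> DAIScore:
    """Map one observation through the rubric (deterministic)."""
    return DAIScore(
        stool_score=STOOL_SCORES[obs.stool],
        weight_score=weight_loss_score(obs.weight_loss),
        blood_score=BLOOD_SCORES[obs.blood],
        histology_score=sum(getattr(obs, f) for f in HISTOLOGY_FIELDS),
    )


def cohort_summary(
    observations: Mapping[str, Iterable[DAIObservation]],
) -> pd.DataFrame:
    """Per-group mean +/- sd of the total and each component.

    ``observations`` maps group label -> iterable of observations; single-
    animal groups report sd 0.
    """
    rows = []
    for group, obs_list in observations.items():
        obs_list = list(obs_list)
        if not obs_list:
            raise ValueError(f"group {group!r} has no observations")
        scores = [score_components(o) for o in obs_list]
        df = pd.DataFrame(
            {
                "stool": [s.stool_score for s in scores],
                "weight": [s.weight_score for s in scores],
                "blood": [s.blood_score for s in scores],
                "histology": [s.histology_score for s in scores],
                "total": [s.total for s in scores],
            }
        )
        row = {"group": group, "n": len(scores)}
        for col in df.columns:
            row[f"{col}_mean"] = df[col].mean()
            row[f"{col}_sd"] = df[col].std(ddof=1) if len(df) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
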