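"""Published observed handedness proportions, for model-vs-data comparison.

These are meta-analytic and pooled literature values, packaged as immutable
fixtures so model predictions can be set beside what is actually observed in
families and twins.  The model reproduces the qualitative structure —
discordant MZ pairs, mostly right-handed offspring of two left-handers,
MZ concordance above DZ — while the observed discordance rates sit a few
points above the default-model predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .core import ParentPair, Zygosity
from .multilocus import (
    MultilocusModel,
    exact_family_prediction,
    exact_twin_distribution,
)

__all__ = ["ObservedFixture", "OBSERVED_FIXTURES", "compare_observed"]


@dataclass(frozen=True)
class ObservedFixture:
    key: str
    label: str
    value: float
    n: int | None  # count behind the proportion, where published
    source: str

    @property
    def se(self) -> float | None:
        """Binomial standard error, when the underlying count is published."""
        if self.n is None:
            return None
        return math.sqrt(self.value * (1 - self.value) / self.n)


OBSERVED_FIXTURES: tuple[ObservedFixture, ...] = (
    ObservedFixture(
        "mz_discordance",
        "MZ twin pairs discordant (R-L)",
        0.193,
        10_001,
        "meta-analysis of twin studies (10,001 MZ pairs)",
    ),
    ObservedFixture(
        "dz_discordance",
        "DZ twin pairs discordant (R-L)",
        0.203,
        None,
        "meta-analysis of twin studies (DZ pairs; count not published)",
    ),
    ObservedFixture(
        "mz_left_rate",
        "left-handedness among MZ twins",
        0.1274,
        None,
        "meta-analysis of twin studies",
    ),
    ObservedFixture(
        "lxl_offspring",
        "left-handed offspring of two left-handed parents",
        0.26,
        417,
        "pooled estimate across 25 family studies (417 offspring)",
    ),
)


def compare_observed(
    model: MultilocusModel | None = None,
    fixtures: tuple[ObservedFixture, ...] = OBSERVED_FIXTURES,
) -> pd.DataFrame:
    """Side-by-side table of model predictions and published observations.

    Predictions use the exact class-joint formulas; observed rows carry a
    binomial standard error where the published count allows one.
    """
    if model is None:
        model = MultilocusModel.for_prevalence(1, 0.10)
    predictions = {
        "mz_discordance": exact_twin_distribution(model, Zygosity.MZ).p_rl,
        "dz_discordance": exact_twin_distribution(model, Zygosity.DZ).p_rl,
        "mz_left_rate": model.population_left_rate(),
        "lxl_offspring": exact_family_prediction(model)[ParentPair.LxL],
    }
    rows = []
    for fx in fixtures:
        rows.append(
            {
                "quantity": fx.label,
                "predicted": predictions.get(fx.key, float("nan")),
                "observed": fx.value,
                "n_observed": fx.n,
                "se_observed": fx.se,
                "source": fx.source,
            }
        )
    return pd.DataFrame(rows)
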