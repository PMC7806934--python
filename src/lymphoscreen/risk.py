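"""Bayesian post-test risk of disease given a screening result.

Given a pre-test probability (prevalence), a cut-off's sensitivity and
specificity, and the observed result, the posterior probability of disease
follows Bayes' theorem. Internally the update runs in odds space —
post-test odds = pre-test odds x likelihood ratio — which is numerically
stable at the very small prevalences screening works with (e.g. 1 in 220
for women under 40).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["RiskInput", "posterior_probability", "risk_table", "parse_prevalence"]


@dataclass(frozen=True)
class RiskInput:
    """Prevalence, operating characteristics and the observed result."""

    prevalence: float
    sensitivity: float
    specificity: float
    result: str = "positive"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly inside (0, 1)")
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must lie in [0, 1]")
        if self.result not in ("positive", "negative"):
            raise ValueError("result must be 'positive' or 'negative'")


def parse_prevalence(text: str) -> float:
    """Parse a prevalence given as a fraction ('1/220') or decimal ('0.00455')."""
    text = text.strip()
    if "/" in text:
        num, den = text.split("/", 1)
        value = float(num) / float(den)
    else:
        value = float(text)
    if not 0.0 < value < 1.0:
        raise ValueError("prevalence must lie strictly inside (0, 1)")
    return value


def posterior_probability(risk: RiskInput) -> float:
    """Post-test probability of disease.

    Positive result: sens*pi / (sens*pi + (1-spec)*(1-pi)); negative:
    (1-sens)*pi / ((1-sens)*pi + spec*(1-pi)) — computed as pre-test odds
    times the likelihood ratio. A result with zero probability under both
    disease states (e.g. a positive result when sensitivity = 0 and
    specificity = 1) has no defined posterior and raises.
    """
    pi = risk.prevalence
    if risk.result == "positive":
        num_rate, den_rate = risk.sensitivity, 1.0 - risk.specificity
    else:
        num_rate, den_rate = 1.0 - risk.sensitivity, risk.specificity
    if num_rate == 0.0 and den_rate == 0.0:
        raise ValueError(
            f"a {risk.result} result is impossible under these operating "
            "characteristics"
        )
    if den_rate == 0.0:
        return 1.0
    pretest_odds = pi / (1.0 - pi)
    lr = num_rate / den_rate
    post_odds = pretest_odds * lr
    return post_odds / (1.0 + post_odds)


def risk_table(
    sensitivity: float,
    specificity: float,
    prevalences: Sequence[float],
) -> pd.DataFrame:
    """Posterior for positive and negative results at each prevalence.

    Returns a frame with columns ``prevalence``, ``pretest_pct``,
    ``posterior_positive``, ``posterior_negative`` (posteriors as
    probabilities); rows in the order given. Posteriors are monotone
    nondecreasing in prevalence.
    """
    prevalences = list(prevalences)
    if not prevalences:
        raise ValueError("at least one prevalence is required")
    rows = []
    for pi in prevalences:
        rows.append(
            {
                "prevalence": pi,
                "pretest_pct": 100.0 * pi,
                "posterior_positive": posterior_probability(
                    RiskInput(pi, sensitivity, specificity, "positive")
                ),
                "posterior_negative": posterior_probability(
                    RiskInput(pi, sensitivity, specificity, "negative")
                ),
            }
        )
    return pd.DataFrame(rows)
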