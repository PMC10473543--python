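"""Two-step MR mediation logic.

Three coefficients enter: beta0, the total effect of the exposure on the
outcome (IVW, log-odds for a binary outcome); beta1, the exposure's effect
on the mediator (two-sample MR); and beta2, the mediator's direct effect on
the outcome conditional on the exposure (multivariable MR). The indirect
effect is beta1·beta2 and the proportion mediated beta1·beta2/beta0.

Classification follows the significance decision table (two-sided p at
alpha, default 0.05):

=============  =============  ====================
beta0          beta1 & beta2  classification
=============  =============  ====================
significant    both           partial
not            both           full
significant    not both       none
not            not both       no_causal_path
=============  =============  ====================
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger("mrmediate")


@dataclass(frozen=True)
class EffectWithP:
    """A coefficient with its standard error and two-sided p-value."""

    beta: float
    se: float
    pval: float

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"se must be positive, got {self.se}")
        if not (0 <= self.pval <= 1):
            raise ValueError(f"pval must be in [0, 1], got {self.pval}")


@dataclass(frozen=True)
class MediationInput:
    beta0: EffectWithP  # total effect, exposure -> outcome
    beta1: EffectWithP  # exposure -> mediator
    beta2: EffectWithP  # mediator -> outcome (conditional on exposure)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass(frozen=True)
class MediationResult:
    classification: str  # partial | full | none | no_causal_path
    indirect_effect: float
    indirect_se: float
    proportion_mediated: float | None  # only for partial/full


def indirect_effect_se(m: MediationInput) -> float:
    """Delta-method SE of beta1·beta2: sqrt(beta2²·se1² + beta1²·se2²)."""
    b1, b2 = m.beta1.beta, m.beta2.beta
    return math.sqrt(b2**2 * m.beta1.se**2 + b1**2 * m.beta2.se**2)


def proportion_mediated(beta0: float, beta1: float, beta2: float) -> float:
    """beta1·beta2/beta0; values outside [0, 1] are returned with a warning."""
    if beta0 == 0:
        raise ValueError("beta0 is zero; proportion mediated undefined")
    prop = beta1 * beta2 / beta0
    if not (0 <= prop <= 1):
        logger.warning(
            "proportion mediated %.4f outside [0, 1]: inconsistent mediation "
            "(indirect and total effects of opposite sign, or indirect exceeds total)",
            prop,
        )
    return prop


def classify_mediation(m: MediationInput) -> MediationResult:
    """Apply the significance decision table and compute the proportion.

    The proportion mediated is reported only for partial or full mediation;
    for full mediation (beta0 not significant) it is still computed from the
    beta0 point estimate, so it can exceed 1.
    """
    sig0 = m.beta0.pval < m.alpha
    sig12 = (m.beta1.pval < m.alpha) and (m.beta2.pval < m.alpha)
    if sig12:
        classification = "partial" if sig0 else "full"
    else:
        classification = "none" if sig0 else "no_causal_path"
    indirect = m.beta1.beta * m.beta2.beta
    prop = None
    if classification in ("partial", "full") and m.beta0.beta != 0:
        prop = proportion_mediated(m.beta0.beta, m.beta1.beta, m.beta2.beta)
    return MediationResult(
        classification=classification,
        indirect_effect=indirect,
        indirect_se=indirect_effect_se(m),
        proportion_mediated=prop,
    )


__all__ = [
    "EffectWithP",
    "MediationInput",
    "MediationResult",
    "classify_mediation",
    "indirect_effect_se",
    "proportion_mediated",
]
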