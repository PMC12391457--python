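"""Sample-size calculation for an AUROC confidence interval.

Uses the Hanley–McNeil (1982) closed-form variance of an empirical
AUROC.  For AUROC ``A`` estimated from ``n_pos`` positives and
``n_neg`` negatives,

    SE(A) = sqrt( (A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2))
                  / (n_pos * n_neg) ),
    Q1 = A / (2-A),   Q2 = 2 A^2 / (1+A).

The minimum total sample size for a two-sided confidence interval of a
given width is the smallest integer n such that
``z * SE(A, prevalence*n, (1-prevalence)*n) <= width/2``, with fractional
group sizes (no rounding) and z the two-sided normal quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm


class PowerError(ValueError):
    pass


@dataclass
class PowerParams:
    auc: float
    prevalence: float
    ci_width: float
    confidence: float = 0.95

    def validate(self) -> None:
        if not 0.5 < self.auc < 1:
            raise PowerError("auc must be in (0.5, 1)")
        if not 0 < self.prevalence < 1:
            raise PowerError("prevalence must be in (0, 1)")
        if self.ci_width <= 0:
            raise PowerError("ci_width must be positive")
        if not 0 < self.confidence < 1:
            raise PowerError("confidence must be in (0, 1)")


def auroc_se(auc: float, n_pos: float, n_neg: float) -> float:
    """Hanley–McNeil standard error of an empirical AUROC.

    Group sizes may be fractional (expected counts under a prevalence).
    """
    if not 0 < auc < 1:
        raise PowerError("auc must be in (0, 1)")
    if n_pos <= 0 or n_neg <= 0:
        raise PowerError("group sizes must be positive")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1.0) * (q1 - auc * auc)
        + (n_neg - 1.0) * (q2 - auc * auc)
    ) / (n_pos * n_neg)
    return math.sqrt(var)


def min_sample_size(params: PowerParams, n_max: int = 10_000_000) -> int:
    """Smallest total n whose CI half-width meets ``ci_width / 2``."""
    params.validate()
    z = float(norm.ppf(0.5 + params.confidence / 2.0))
    half_width = params.ci_width / 2.0
    for n in range(2, n_max + 1):
        n_pos = params.prevalence * n
        n_neg = (1.0 - params.prevalence) * n
        if z * auroc_se(params.auc, n_pos, n_neg) <= half_width:
            return n
    raise PowerError(
        f"no n <= {n_max} reaches half-width {half_width}; widen the interval"
    )
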