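"""Responsibility functions, critical domains and three-state gene-expression calls.

This is the quality filter of the whole approach: instead of a crisp
threshold, a fitted mixture yields posterior responsibilities
r-(x), r+(x) and a *critical domain* [x_lower, x_upper] in which neither
responsibility reaches 1 - alpha.  Expression values inside the domain
are called undecidable (GE 0) and no receptor decision is made.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .core import TwoComponentModel
from .cutpoints import _logratio_slope, _posterior_logratio_roots, bayes_cutpoint
from .errors import InvalidInputError, NoCriticalDomainError


class GeneState(enum.Enum):
    """Three-state gene-expression receptor call."""

    GE_NEG = "GE-"
    GE_ZERO = "GE0"
    GE_POS = "GE+"


@dataclass(frozen=True)
class GeneCall:
    """One sample's three-state call with its posterior responsibility."""

    state: GeneState
    responsibility_neg: float
    expression: float


@dataclass(frozen=True)
class CriticalDomain:
    """Closed interval of undecidable expression values.

    Between ``x_lower`` and ``x_upper`` (inclusive) neither component's
    responsibility reaches 1 - alpha, so no receptor decision is made.
    """

    x_lower: float
    x_upper: float
    alpha: float

    def __post_init__(self):
        if not self.x_lower <= self.x_upper:
            raise InvalidInputError(
                f"x_lower={self.x_lower} > x_upper={self.x_upper}"
            )

    def __contains__(self, x: float) -> bool:
        return self.x_lower <= x <= self.x_upper


def responsibility(model: TwoComponentModel, x):
    """Posterior responsibilities (r_neg, r_pos) at expression value(s) x.

    r-(x) = w- f-(x) / (w- f-(x) + w+ f+(x)) with w- = 1 - pi+ and
    f-' the component densities; r+ = 1 - r-.  Computed through the
    log-ratio for numerical stability, so both are finite in [0, 1] for
    any finite x.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("expression values must be finite")
    log_ratio = (
        math.log(model.weight_neg / model.weight_pos)
        + model.neg.logpdf(x)
        - model.pos.logpdf(x)
    )
    # r_neg = 1 / (1 + exp(-log_ratio)), the logistic of the log-ratio
    with np.errstate(over="ignore"):
        r_neg = 1.0 / (1.0 + np.exp(-log_ratio))
    r_neg = np.clip(r_neg, 0.0, 1.0)
    if r_neg.ndim == 0:
        r_neg = float(r_neg)
        return r_neg, 1.0 - r_neg
    return r_neg, 1.0 - r_neg


def critical_domain(model: TwoComponentModel, alpha: float = 0.05) -> CriticalDomain:
    """Solve r-(x_lower) = r+(x_upper) = 1 - alpha for the fitted model.

    Writing g(x) = log[w- f-(x) / (w+ f+(x))] (so r- is the logistic of
    g), the two conditions become g(x) = log((1-alpha)/alpha) for the
    lower bound and g(x) = log(alpha/(1-alpha)) for the upper — shifted
    versions of the same quadratic that defines the Bayesian cut-point,
    solved in closed form.  Among the real roots only those inside
    (mu-, mu+) on the branch where r- is decreasing qualify; when the
    positive component is much wider than the negative one (the PGR
    situation) the quadratic has a second, spurious root on the rising
    branch which this rule rejects.  The returned bounds bracket the
    cut-point.
    """
    if not 0.0 < alpha <= 0.5:
        raise InvalidInputError(f"alpha={alpha} not in (0, 0.5]")
    cp = bayes_cutpoint(model).threshold
    lo, hi = model.neg.mu, model.pos.mu

    def solve(t: float, side: str) -> float:
        roots = [
            r
            for r in _posterior_logratio_roots(model, t)
            if lo < r < hi and _logratio_slope(model, r) < 0
        ]
        if side == "lower":
            roots = [r for r in roots if r <= cp + 1e-12]
            if roots:
                return max(roots)
        else:
            roots = [r for r in roots if r >= cp - 1e-12]
            if roots:
                return min(roots)
        raise NoCriticalDomainError(
            f"no responsibility root at level {1 - alpha:.3g} inside "
            f"({lo:.4g}, {hi:.4g}); components indistinguishable at alpha={alpha}"
        )

    x_lower = solve(math.log((1.0 - alpha) / alpha), "lower")
    x_upper = solve(math.log(alpha / (1.0 - alpha)), "upper")
    return CriticalDomain(x_lower=float(x_lower), x_upper=float(x_upper), alpha=alpha)


def call_sample(model: TwoComponentModel, domain: CriticalDomain, x: float) -> GeneCall:
    """Three-state receptor call for one expression value.

    GE- below the domain, GE+ above it, GE0 (undecidable) inside; the
    domain is closed, so values exactly on a boundary are undecidable.
    """
    if not (isinstance(x, (int, float, np.floating)) and math.isfinite(float(x))):
        raise InvalidInputError(f"expression value must be a finite number, got {x!r}")
    x = float(x)
    r_neg, _ = responsibility(model, x)
    if x < domain.x_lower:
        state = GeneState.GE_NEG
    elif x > domain.x_upper:
        state = GeneState.GE_POS
    else:
        state = GeneState.GE_ZERO
    return GeneCall(state=state, responsibility_neg=r_neg, expression=x)


def call_cohort(model: TwoComponentModel, domain: CriticalDomain, values) -> list:
    """Vector version of :func:`call_sample`."""
    return [call_sample(model, domain, float(v)) for v in np.asarray(values, dtype=float)]
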