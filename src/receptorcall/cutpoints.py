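"""Discrimination thresholds between receptor-negative and -positive expression.

Five estimators are supported.  Youden and LogReg work directly on the
IHC labels; ParEst, MaxLike and ExMax first fit the two-Gaussian model
(:mod:`receptorcall.mixture`) and then place the cut-point where the
posterior probabilities of the two components are equal
(:func:`bayes_cutpoint`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ExpressionVector, IHCStatus, TwoComponentModel
from .errors import InsufficientClassDataError, NoValidCutpointError


@dataclass(frozen=True)
class CutpointResult:
    """A method-tagged threshold on the log2-expression axis."""

    method: str
    threshold: float

    def __post_init__(self):
        if not math.isfinite(self.threshold):
            from .errors import InvalidInputError

            raise InvalidInputError(f"non-finite threshold {self.threshold}")


@dataclass(frozen=True)
class ROCCurve:
    """ROC of 'call positive iff expression >= threshold' against IHC.

    ``thresholds`` are sorted ascending; sensitivity is non-increasing
    along them.  ``auc`` is the Mann-Whitney statistic (ties get half
    credit).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def _labeled_values(expr: ExpressionVector, ihc: Sequence[IHCStatus]):
    from .errors import LengthMismatchError

    if len(ihc) != len(expr):
        raise LengthMismatchError(f"{len(expr)} values vs {len(ihc)} IHC labels")
    keep = np.array([s is not IHCStatus.MISSING for s in ihc])
    y = np.array([s is IHCStatus.POSITIVE for s in ihc])[keep]
    x = expr.values[keep]
    if y.sum() == 0 or (~y).sum() == 0:
        raise InsufficientClassDataError("both IHC classes must be present")
    return x, y


def candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct values, plus -inf/+inf sentinels."""
    v = np.unique(values)
    mids = 0.5 * (v[:-1] + v[1:])
    return np.concatenate([[-np.inf], mids, [np.inf]])


def roc_curve(expr: ExpressionVector, ihc: Sequence[IHCStatus]) -> ROCCurve:
    """ROC curve of expression against IHC status.

    Samples with missing IHC are excluded; a sample is called positive
    when its expression is at or above the running threshold.  The AUC is
    the probability that a random IHC-positive sample outranks a random
    IHC-negative one, with ties counted half.
    """
    from scipy.stats import rankdata

    x, y = _labeled_values(expr, ihc)
    thr = candidate_thresholds(x)
    calls = x[None, :] >= thr[:, None]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    sens = (calls & y[None, :]).sum(axis=1) / n_pos
    spec = (~calls & ~y[None, :]).sum(axis=1) / n_neg
    # Mann-Whitney AUC with half credit for ties, via midranks
    ranks = rankdata(x)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return ROCCurve(thresholds=thr, sensitivity=sens, specificity=spec, auc=float(auc))


def youden_cutpoint(roc: ROCCurve) -> CutpointResult:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the smallest qualifying threshold; the
    infinite sentinels are never returned when a finite threshold
    achieves the same J.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.max(j)
    qualifying = roc.thresholds[np.isclose(j, best, rtol=0, atol=1e-12)]
    finite = qualifying[np.isfinite(qualifying)]
    chosen = finite[0] if len(finite) else qualifying[0]
    return CutpointResult(method="Youden", threshold=float(chosen))


def logreg_cutpoint(expr: ExpressionVector, ihc: Sequence[IHCStatus]) -> CutpointResult:
    """Cut-point from unpenalized logistic regression of IHC on expression.

    The threshold is the expression value where the fitted probability of
    being receptor positive equals 0.5, i.e. -intercept/slope.  Complete
    separation has no finite MLE; the midpoint of the separating gap is
    returned with a warning.
    """
    import statsmodels.api as sm

    x, y = _labeled_values(expr, ihc)
    hi_neg, lo_pos = x[~y].max(), x[y].min()
    if hi_neg < lo_pos:  # complete separation: any threshold in the gap works
        warnings.warn(
            "IHC classes are completely separated in expression; "
            "returning the midpoint of the separating gap",
            stacklevel=2,
        )
        return CutpointResult(method="LogReg", threshold=float(0.5 * (hi_neg + lo_pos)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y.astype(float), sm.add_constant(x)).fit(disp=0)
    intercept, slope = fit.params
    if slope == 0:
        raise NoValidCutpointError("logistic slope is zero; expression carries no signal")
    return CutpointResult(method="LogReg", threshold=float(-intercept / slope))


def bayes_cutpoint(model: TwoComponentModel) -> CutpointResult:
    """Equal-posterior cut-point of a fitted two-Gaussian model.

    Solves Pr(+|x) = Pr(-|x) = 0.5, where the posterior weighs each
    component density by its mixing weight.  Taking logs yields a
    quadratic a x^2 + b x + c = 0 with

        a = 1/sigma-^2 - 1/sigma+^2
        b = -2 (mu-/sigma-^2 - mu+/sigma+^2)
        c = (mu-/sigma-)^2 - (mu+/sigma+)^2 + 2 log((sigma-/sigma+) (w+/w-))

    The root lying between the component means is returned (when the
    variances are equal the quadratic degenerates to the linear solution
    -c/b).  The result is tagged with the model's fitting method.
    """
    roots = _posterior_logratio_roots(model, t=0.0)
    lo, hi = model.neg.mu, model.pos.mu
    inside = [r for r in roots if lo < r < hi]
    if not inside:
        raise NoValidCutpointError(
            f"no equal-posterior root in ({lo:.4g}, {hi:.4g}); components overlap pathologically"
        )
    # at most one root of the posterior log-ratio lies strictly between the
    # means on the decreasing branch; prefer it
    decreasing = [r for r in inside if _logratio_slope(model, r) < 0]
    x = decreasing[0] if decreasing else inside[0]
    from .decision import responsibility

    r_neg, _ = responsibility(model, x)
    assert abs(r_neg - 0.5) < 1e-8, "cut-point does not satisfy r=0.5"
    return CutpointResult(method=model.method, threshold=float(x))


# ---------------------------------------------------------------------------
# shared quadratic machinery (also used for critical domains)
# ---------------------------------------------------------------------------

def _logratio_slope(model: TwoComponentModel, x: float) -> float:
    """d/dx of log[w- f-(x) / (w+ f+(x))]."""
    return -(x - model.neg.mu) / model.neg.sigma**2 + (x - model.pos.mu) / model.pos.sigma**2


def _posterior_logratio_roots(model: TwoComponentModel, t: float):
    """Real solutions of log[w- f-(x) / (w+ f+(x))] = t.

    Expanding the Gaussian densities gives A x^2 + B x + C = 0 with

        A = 1/sigma-^2 - 1/sigma+^2
        B = -2 (mu-/sigma-^2 - mu+/sigma+^2)
        C = (mu-/sigma-)^2 - (mu+/sigma+)^2
            + 2 log((sigma-/sigma+) (w+/w-)) + 2 t

    For |A| below 1e-12 (equal variances) the equation is linear.
    """
    mn, sn = model.neg.mu, model.neg.sigma
    mp, sp = model.pos.mu, model.pos.sigma
    wn, wp = model.weight_neg, model.weight_pos
    a = 1.0 / sn**2 - 1.0 / sp**2
    b = -2.0 * (mn / sn**2 - mp / sp**2)
    c = (mn / sn) ** 2 - (mp / sp) ** 2 + 2.0 * math.log((sn / sp) * (wp / wn)) + 2.0 * t
    if abs(a) < 1e-12:
        if b == 0:
            return []
        return [-c / b]
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return []
    sq = math.sqrt(disc)
    return [(-b + sq) / (2.0 * a), (-b - sq) / (2.0 * a)]


ALL_METHODS = ("Youden", "LogReg", "ParEst", "MaxLike", "ExMax")


def all_cutpoints(expr: ExpressionVector, ihc: Sequence[IHCStatus]) -> dict:
    """Convenience: run all five estimators on one labeled cohort.

    Returns a dict method -> :class:`CutpointResult`.  The model-based
    methods use ParEst as the initial guess for MaxLike and ExMax.
    """
    from .mixture import fit_exmax, fit_maxlike, fit_parest

    results = {}
    results["Youden"] = youden_cutpoint(roc_curve(expr, ihc))
    results["LogReg"] = logreg_cutpoint(expr, ihc)
    parest = fit_parest(expr, ihc)
    results["ParEst"] = bayes_cutpoint(parest)
    results["MaxLike"] = bayes_cutpoint(fit_maxlike(expr, parest.weight_pos, init=parest))
    results["ExMax"] = bayes_cutpoint(fit_exmax(expr, init=parest))
    return results
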