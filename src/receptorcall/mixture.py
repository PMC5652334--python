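"""Fitting the two-component Gaussian model of receptor-gene expression.

Three estimators are provided, differing in how much IHC information they
consume:

* :func:`fit_parest` (supervised) — plain moments of the IHC-negative and
  IHC-positive subsets; the mixing weight is the relative IHC abundance
  lambda+ = N+/(N+ + N-), never fitted.
* :func:`fit_maxlike` (semi-supervised) — maximizes the bimodal likelihood
  over the four distribution parameters with the mixing weight held fixed
  at the IHC abundance.
* :func:`fit_exmax` (unsupervised) — expectation-maximization over all
  five parameters including the mixing weight pi+; needs no IHC labels.

:func:`fisher_ci` turns a likelihood-based fit into Wald 95% confidence
intervals via the observed Fisher information.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .core import ExpressionVector, GaussianComponent, IHCStatus, ParameterCI, TwoComponentModel
from .errors import DegenerateFitError, InsufficientClassDataError, NonIdentifiableError

#: Lower bound on component standard deviations: guards against the
#: singular likelihood spikes a Gaussian mixture develops when one
#: component shrinks onto a single observation.
SIGMA_FLOOR = 1e-3

#: EM / optimizer convergence: absolute change in log-likelihood.
LOGLIK_TOL = 1e-8
MAX_ITER = 1000


def _split_by_ihc(expr: ExpressionVector, ihc: Sequence[IHCStatus]):
    if len(ihc) != len(expr):
        from .errors import LengthMismatchError

        raise LengthMismatchError(f"{len(expr)} expression values vs {len(ihc)} IHC labels")
    status = np.array([s is IHCStatus.POSITIVE for s in ihc])
    known = np.array([s is not IHCStatus.MISSING for s in ihc])
    x = expr.values
    return x[known & ~status], x[known & status]


def _ordered(mu_a, sigma_a, mu_b, sigma_b, weight_b):
    """Relabel so the returned (neg, pos) has neg.mu < pos.mu."""
    if mu_a <= mu_b:
        return GaussianComponent(mu_a, sigma_a), GaussianComponent(mu_b, sigma_b), weight_b
    return GaussianComponent(mu_b, sigma_b), GaussianComponent(mu_a, sigma_a), 1.0 - weight_b


def fit_parest(expr: ExpressionVector, ihc: Sequence[IHCStatus]) -> TwoComponentModel:
    """Moment estimation from the IHC-labeled subsets (method ParEst).

    Each component is the sample mean and unbiased standard deviation of
    the corresponding IHC class; samples with missing IHC are ignored.
    Requires at least two samples per class.
    """
    neg_x, pos_x = _split_by_ihc(expr, ihc)
    if len(neg_x) < 2 or len(pos_x) < 2:
        raise InsufficientClassDataError(
            f"need >=2 samples per IHC class, got {len(neg_x)} negative / {len(pos_x)} positive"
        )
    sd_neg, sd_pos = neg_x.std(ddof=1), pos_x.std(ddof=1)
    if sd_neg < SIGMA_FLOOR or sd_pos < SIGMA_FLOOR:
        raise DegenerateFitError("an IHC class has (near-)zero expression variance")
    weight_pos = len(pos_x) / (len(pos_x) + len(neg_x))
    neg, pos, weight_pos = _ordered(
        float(neg_x.mean()), float(sd_neg), float(pos_x.mean()), float(sd_pos), weight_pos
    )
    model = TwoComponentModel(
        neg=neg, pos=pos, weight_pos=weight_pos, method="ParEst", probe_id=expr.probe_id
    )
    return TwoComponentModel(
        neg=neg,
        pos=pos,
        weight_pos=weight_pos,
        method="ParEst",
        loglik=model.loglik_of(expr.values),
        n_iter=0,
        converged=True,
        probe_id=expr.probe_id,
    )


# ---------------------------------------------------------------------------
# MaxLike: 4-parameter likelihood maximization with fixed weights
# ---------------------------------------------------------------------------

def _mixture_nll_grad(theta, x, weight_pos):
    """Negative log-likelihood and its analytic gradient.

    theta = (mu_neg, mu_pos, sigma_neg, sigma_pos); the gradient follows
    from d/dtheta log f = sum_i gamma_ki d/dtheta log f_k with gamma the
    posterior responsibility of component k for sample i.
    """
    mu_n, mu_p, s_n, s_p = theta
    w_n, w_p = 1.0 - weight_pos, weight_pos
    log_n = np.log(w_n) - 0.5 * ((x - mu_n) / s_n) ** 2 - math.log(s_n * math.sqrt(2 * math.pi))
    log_p = np.log(w_p) - 0.5 * ((x - mu_p) / s_p) ** 2 - math.log(s_p * math.sqrt(2 * math.pi))
    ll_i = np.logaddexp(log_n, log_p)
    g_n = np.exp(log_n - ll_i)  # responsibility of the negative component
    g_p = 1.0 - g_n
    grad = np.array(
        [
            np.sum(g_n * (x - mu_n) / s_n**2),
            np.sum(g_p * (x - mu_p) / s_p**2),
            np.sum(g_n * ((x - mu_n) ** 2 / s_n**3 - 1.0 / s_n)),
            np.sum(g_p * ((x - mu_p) ** 2 / s_p**3 - 1.0 / s_p)),
        ]
    )
    return -float(ll_i.sum()), -grad


def fit_maxlike(
    expr: ExpressionVector,
    weight_pos: float,
    init: Optional[TwoComponentModel] = None,
) -> TwoComponentModel:
    """Maximum-likelihood fit of the four distribution parameters (MaxLike).

    The mixing weight is preset (typically the IHC abundance
    lambda+ = N+/(N+ + N-)) and held fixed; only (mu-, mu+, sigma-,
    sigma+) are optimized, by L-BFGS-B on the analytic gradient.

    Raises :class:`DegenerateFitError` when the data have (near-)zero
    spread or a sigma collapses to the floor.
    """
    if not 0.0 < weight_pos < 1.0:
        from .errors import InvalidInputError

        raise InvalidInputError(f"weight_pos={weight_pos} not in (0, 1)")
    x = expr.values
    if len(x) < 4:
        raise InsufficientClassDataError("MaxLike needs at least 4 samples")
    if x.std() < SIGMA_FLOOR:
        raise DegenerateFitError("all expression values are (nearly) identical")

    if init is not None:
        theta0 = np.array([init.neg.mu, init.pos.mu, init.neg.sigma, init.pos.sigma])
    else:
        lo, hi = _median_split_moments(x)
        theta0 = np.array([lo[0], hi[0], lo[1], hi[1]])

    res = minimize(
        _mixture_nll_grad,
        theta0,
        args=(x, weight_pos),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None), (None, None), (SIGMA_FLOOR, None), (SIGMA_FLOOR, None)],
        options={"maxiter": MAX_ITER, "ftol": 1e-12, "gtol": 1e-9},
    )
    mu_n, mu_p, s_n, s_p = res.x
    if s_n <= SIGMA_FLOOR * (1 + 1e-9) or s_p <= SIGMA_FLOOR * (1 + 1e-9):
        raise DegenerateFitError("component sigma collapsed to the floor")
    neg, pos, w = _ordered(float(mu_n), float(s_n), float(mu_p), float(s_p), weight_pos)
    return TwoComponentModel(
        neg=neg,
        pos=pos,
        weight_pos=w,
        method="MaxLike",
        loglik=-float(res.fun),
        n_iter=int(res.nit),
        converged=bool(res.success),
        probe_id=expr.probe_id,
    )


# ---------------------------------------------------------------------------
# ExMax: expectation-maximization over all five parameters
# ---------------------------------------------------------------------------

def _median_split_moments(x):
    """Half-sample moments used to initialize unsupervised fits."""
    med = np.median(x)
    lo = x[x <= med]
    hi = x[x > med]
    if len(hi) < 2:  # heavy ties at the median
        order = np.argsort(x, kind="stable")
        lo, hi = x[order[: len(x) // 2]], x[order[len(x) // 2 :]]
    return (
        (float(lo.mean()), max(float(lo.std()) or 1.0, SIGMA_FLOOR)),
        (float(hi.mean()), max(float(hi.std()) or 1.0, SIGMA_FLOOR)),
    )


def fit_exmax(
    expr: ExpressionVector,
    init: Optional[TwoComponentModel] = None,
    seed: Optional[int] = None,
) -> TwoComponentModel:
    """Unsupervised EM fit of the five-parameter mixture (method ExMax).

    The E-step computes, for every sample, the latent probability
    gamma_i of being receptor positive given the current parameters; the
    M-step re-estimates (mu-, sigma-, mu+, sigma+) and the mixing weight
    pi+ from those responsibilities.  The loop runs until the observed
    log-likelihood changes by less than ``LOGLIK_TOL`` (or ``MAX_ITER``
    sweeps, in which case ``converged`` is False).

    ``init`` may come from IHC data (e.g. a ParEst model) but the data
    themselves are fitted without labels.  Without ``init`` the cohort is
    split at its median and half-sample moments seed the loop.  ``seed``
    is accepted for interface symmetry; the algorithm is deterministic.
    """
    x = expr.values
    n = len(x)
    if n < 4:
        raise InsufficientClassDataError("ExMax needs at least 4 samples")
    if x.std() < SIGMA_FLOOR:
        raise DegenerateFitError("all expression values are (nearly) identical")

    if init is not None:
        mu = np.array([init.neg.mu, init.pos.mu])
        sigma = np.array([init.neg.sigma, init.pos.sigma])
        w = np.array([init.weight_neg, init.weight_pos])
    else:
        lo, hi = _median_split_moments(x)
        mu = np.array([lo[0], hi[0]])
        sigma = np.array([max(lo[1], SIGMA_FLOOR), max(hi[1], SIGMA_FLOOR)])
        w = np.array([0.5, 0.5])

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        # E-step: posterior responsibility of each component per sample
        log_comp = (
            np.log(w)[:, None]
            - 0.5 * ((x[None, :] - mu[:, None]) / sigma[:, None]) ** 2
            - np.log(sigma[:, None] * math.sqrt(2 * math.pi))
        )
        log_norm = logsumexp(log_comp, axis=0)
        gamma = np.exp(log_comp - log_norm[None, :])
        ll = float(log_norm.sum())

        mass = gamma.sum(axis=1)
        if mass.min() < 2.0:
            raise DegenerateFitError(
                f"component death: responsibility mass {mass.min():.3g} < 2 samples"
            )

        # M-step
        w = mass / n
        mu = gamma @ x / mass
        sigma = np.sqrt(np.maximum((gamma * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / mass,
                                   SIGMA_FLOOR**2))

        if abs(ll - prev_ll) < LOGLIK_TOL:
            converged = True
            break
        prev_ll = ll

    if sigma.min() <= SIGMA_FLOOR * (1 + 1e-9):
        raise DegenerateFitError("component sigma collapsed to the floor")

    neg, pos, w_pos = _ordered(float(mu[0]), float(sigma[0]), float(mu[1]), float(sigma[1]),
                               float(w[1]))
    model = TwoComponentModel(
        neg=neg,
        pos=pos,
        weight_pos=w_pos,
        method="ExMax",
        loglik=float("nan"),
        n_iter=n_iter,
        converged=converged,
        probe_id=expr.probe_id,
    )
    return TwoComponentModel(
        neg=neg,
        pos=pos,
        weight_pos=w_pos,
        method="ExMax",
        loglik=model.loglik_of(x),
        n_iter=n_iter,
        converged=converged,
        probe_id=expr.probe_id,
    )


def exmax_loglik_trace(expr: ExpressionVector, init: Optional[TwoComponentModel] = None,
                       max_iter: int = MAX_ITER):
    """Observed log-likelihood after each EM sweep (diagnostic).

    Runs the same update as :func:`fit_exmax` and records the
    log-likelihood sequence, which EM guarantees to be non-decreasing.
    """
    x = expr.values
    if init is not None:
        mu = np.array([init.neg.mu, init.pos.mu])
        sigma = np.array([init.neg.sigma, init.pos.sigma])
        w = np.array([init.weight_neg, init.weight_pos])
    else:
        lo, hi = _median_split_moments(x)
        mu = np.array([lo[0], hi[0]])
        sigma = np.array([max(lo[1], SIGMA_FLOOR), max(hi[1], SIGMA_FLOOR)])
        w = np.array([0.5, 0.5])
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        log_comp = (
            np.log(w)[:, None]
            - 0.5 * ((x[None, :] - mu[:, None]) / sigma[:, None]) ** 2
            - np.log(sigma[:, None] * math.sqrt(2 * math.pi))
        )
        log_norm = logsumexp(log_comp, axis=0)
        gamma = np.exp(log_comp - log_norm[None, :])
        ll = float(log_norm.sum())
        trace.append(ll)
        mass = gamma.sum(axis=1)
        if mass.min() < 2.0:
            break
        w = mass / len(x)
        mu = gamma @ x / mass
        sigma = np.sqrt(np.maximum((gamma * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / mass,
                                   SIGMA_FLOOR**2))
        if abs(ll - prev) < LOGLIK_TOL:
            break
        prev = ll
    return np.array(trace)


# ---------------------------------------------------------------------------
# Fisher-information confidence intervals
# ---------------------------------------------------------------------------

def fisher_ci(model: TwoComponentModel, expr: ExpressionVector, z: float = 1.96) -> ParameterCI:
    """Wald confidence intervals from the observed Fisher information.

    The observed information is the negative Hessian of the mixture
    log-likelihood evaluated at the fitted (mu-, mu+, sigma-, sigma+),
    with the mixing weight held fixed — the four-parameter convention.
    The Hessian is computed by central finite differences on the analytic
    gradient (step 1e-4 scaled per parameter); the information matrix is
    inverted and each interval is estimate +/- z * sqrt(diagonal).
    """
    x = expr.values
    theta = np.array([model.neg.mu, model.pos.mu, model.neg.sigma, model.pos.sigma])
    w_pos = model.weight_pos

    def grad(t):
        return _mixture_nll_grad(t, x, w_pos)[1]  # gradient of the NLL

    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    hess = np.empty((4, 4))
    for j in range(4):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        hess[:, j] = (grad(tp) - grad(tm)) / (2 * h[j])
    info = 0.5 * (hess + hess.T)  # observed information = Hessian of NLL

    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e12:
        raise NonIdentifiableError(
            f"observed information matrix is singular (condition number {cond:.3g})"
        )
    cov = np.linalg.inv(info)
    diag = np.diag(cov)
    if np.any(diag <= 0):
        raise NonIdentifiableError("observed information is not positive definite")
    half = z * np.sqrt(diag)
    names = ParameterCI.PARAMS
    return ParameterCI(
        intervals={name: (float(t - hw), float(t + hw)) for name, t, hw in zip(names, theta, half)}
    )
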