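"""Core containers shared across the package.

The central object is :class:`TwoComponentModel`: a two-component Gaussian
mixture of receptor-gene expression, with the receptor-negative component
always the lower-mean one.  Expression values are RMA-normalized log2
intensities of a single probe set, one per sample.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DuplicateSampleError, InvalidInputError, LengthMismatchError


class IHCStatus(enum.Enum):
    """Three-valued immunohistochemistry receptor status.

    IHC produces a dichotomized protein-level call; in cohort annotation
    tables the call may simply be absent, hence the explicit MISSING state.
    """

    NEGATIVE = "-"
    POSITIVE = "+"
    MISSING = "0"


#: Tokens accepted (case-insensitively) when parsing IHC annotation columns.
IHC_TOKENS = {
    "+": IHCStatus.POSITIVE,
    "pos": IHCStatus.POSITIVE,
    "positive": IHCStatus.POSITIVE,
    "-": IHCStatus.NEGATIVE,
    "neg": IHCStatus.NEGATIVE,
    "negative": IHCStatus.NEGATIVE,
    "na": IHCStatus.MISSING,
    "": IHCStatus.MISSING,
}


def parse_ihc(token) -> IHCStatus:
    """Parse one annotation cell into an :class:`IHCStatus`.

    Accepts ``+/-/pos/positive/neg/negative/NA/empty`` case-insensitively;
    ``None``/NaN count as missing.  Unknown tokens are rejected, never
    coerced.
    """
    from .errors import SchemaError

    if token is None or (isinstance(token, float) and math.isnan(token)):
        return IHCStatus.MISSING
    if isinstance(token, IHCStatus):
        return token
    key = str(token).strip().lower()
    if key not in IHC_TOKENS:
        raise SchemaError(f"unknown IHC status token: {token!r}")
    return IHC_TOKENS[key]


@dataclass(frozen=True)
class ExpressionVector:
    """Expression of one probe set across a cohort.

    Parameters
    ----------
    sample_ids
        Unique opaque identifiers, one per sample.
    values
        RMA-normalized log2 expression values, same order as ``sample_ids``.
    probe_id
        Affymetrix probe-set identifier, e.g. ``"205225_at"`` (ESR1).
    """

    sample_ids: tuple
    values: np.ndarray
    probe_id: str = ""

    def __init__(self, sample_ids: Sequence, values: Sequence[float], probe_id: str = ""):
        values = np.asarray(values, dtype=float)
        sample_ids = tuple(sample_ids)
        if len(sample_ids) != values.shape[0]:
            raise LengthMismatchError(
                f"{len(sample_ids)} sample ids vs {values.shape[0]} values"
            )
        if values.ndim != 1 or values.shape[0] < 2:
            raise InvalidInputError("need a 1-D vector with at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("expression values must be finite")
        if len(set(sample_ids)) != len(sample_ids):
            dupes = {s for s in sample_ids if sample_ids.count(s) > 1}
            raise DuplicateSampleError(f"duplicate sample ids: {sorted(dupes)!r}")
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "probe_id", probe_id)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian mode (mu, sigma) on the log2-expression axis."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not (self.sigma > 0 and math.isfinite(self.sigma) and math.isfinite(self.mu)):
            raise InvalidInputError(f"invalid component mu={self.mu}, sigma={self.sigma}")

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        return -0.5 * ((x - self.mu) / self.sigma) ** 2 - math.log(
            self.sigma * math.sqrt(2 * math.pi)
        )

    def pdf(self, x):
        return np.exp(self.logpdf(x))


@dataclass(frozen=True)
class TwoComponentModel:
    """Two-component Gaussian mixture of receptor-gene expression.

    ``neg`` is always the lower-mean component (receptor negative),
    ``pos`` the higher-mean one; fitters relabel before returning.
    ``weight_pos`` is the mixing weight of the positive component: the
    preset IHC abundance lambda+ for the supervised fits (ParEst, MaxLike)
    and the fitted prior pi+ for the unsupervised EM fit (ExMax).
    """

    neg: GaussianComponent
    pos: GaussianComponent
    weight_pos: float
    method: str = "ExMax"
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    probe_id: str = ""

    def __post_init__(self):
        if not 0.0 < self.weight_pos < 1.0:
            raise InvalidInputError(f"weight_pos={self.weight_pos} not in (0, 1)")
        if not self.neg.mu < self.pos.mu:
            raise InvalidInputError(
                f"components must satisfy neg.mu < pos.mu "
                f"(got {self.neg.mu} >= {self.pos.mu})"
            )
        if self.converged and not math.isnan(self.loglik) and not math.isfinite(self.loglik):
            raise InvalidInputError("log-likelihood must be finite when converged")

    @property
    def weight_neg(self) -> float:
        return 1.0 - self.weight_pos

    def pdf(self, x):
        """Mixture density (1 - pi+) f-(x) + pi+ f+(x)."""
        x = np.asarray(x, dtype=float)
        return self.weight_neg * self.neg.pdf(x) + self.weight_pos * self.pos.pdf(x)

    def loglik_of(self, values) -> float:
        """Observed-data log-likelihood of ``values`` under this model."""
        from scipy.special import logsumexp

        x = np.asarray(values, dtype=float)
        comps = np.stack(
            [
                np.log(self.weight_neg) + self.neg.logpdf(x),
                np.log(self.weight_pos) + self.pos.logpdf(x),
            ]
        )
        return float(logsumexp(comps, axis=0).sum())

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "probe_id": self.probe_id,
            "method": self.method,
            "mu_neg": self.neg.mu,
            "sigma_neg": self.neg.sigma,
            "mu_pos": self.pos.mu,
            "sigma_pos": self.pos.sigma,
            "weight_pos": self.weight_pos,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoComponentModel":
        return cls(
            neg=GaussianComponent(d["mu_neg"], d["sigma_neg"]),
            pos=GaussianComponent(d["mu_pos"], d["sigma_pos"]),
            weight_pos=d["weight_pos"],
            method=d.get("method", "ExMax"),
            loglik=d.get("loglik", float("nan")),
            n_iter=d.get("n_iter", 0),
            converged=d.get("converged", True),
            probe_id=d.get("probe_id", ""),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class ParameterCI:
    """95% confidence intervals for (mu-, mu+, sigma-, sigma+).

    Wald-type intervals from the observed Fisher information; ``intervals``
    maps parameter name to (lower, upper) in log2-expression units.
    """

    intervals: dict = field(default_factory=dict)

    PARAMS = ("mu_neg", "mu_pos", "sigma_neg", "sigma_pos")

    def half_width(self, name: str) -> float:
        lo, hi = self.intervals[name]
        return 0.5 * (hi - lo)

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.intervals.items()}
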