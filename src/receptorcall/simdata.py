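"""Synthetic cohorts with the bimodal receptor-expression structure.

Real receptor-gene expression in breast-cancer cohorts is strongly
bimodal: a receptor-negative and a receptor-positive Gaussian mode whose
published parameters (per receptor and estimation method) ship here as
:func:`preset` rows.  The generator draws a latent component per sample,
an expression value from that component, and an IHC label that may be
flipped (label noise) or blanked (missingness) — which is exactly the
generative model the estimators assume, no more.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .core import ExpressionVector, GaussianComponent, IHCStatus, TwoComponentModel
from .errors import InvalidConfigError

#: Published distribution parameters and cut-points per receptor and
#: method: (cutpoint, mu-, mu+, sigma-, sigma+, weight_pos).  For the
#: supervised rows the weight is the IHC abundance lambda+; for ExMax it
#: is the fitted prior pi+.  Youden/LogReg rows carry no distribution
#: parameters and therefore cannot seed a simulation.
TABLE_PRESETS = {
    ("ER", "MaxLike"): (9.453, 6.515, 11.624, 1.415, 0.947, 0.517),
    ("ER", "ParEst"): (9.099, 6.835, 11.300, 1.870, 1.580, 0.517),
    ("ER", "ExMax"): (9.363, 6.557, 11.472, 1.534, 1.013, 0.519),
    ("PGR", "MaxLike"): (4.046, 3.587, 5.560, 0.197, 1.483, 0.458),
    ("PGR", "ParEst"): (4.399, 3.647, 5.336, 0.409, 1.555, 0.458),
    ("PGR", "ExMax"): (4.164, 3.619, 5.722, 0.241, 1.486, 0.454),
    ("HER2", "MaxLike"): (11.680, 9.481, 12.982, 0.870, 0.585, 0.246),
    ("HER2", "ParEst"): (11.053, 9.396, 11.912, 0.867, 1.484, 0.246),
    ("HER2", "ExMax"): (12.304, 9.492, 13.209, 1.251, 0.538, 0.124),
}

RECEPTOR_PROBES = {"ER": "205225_at", "PGR": "208305_at", "HER2": "216836_s_at"}

#: Cohort size with full crisp IHC for ER in the published agreement
#: tables (943 + 130 + 112 + 1084).
N_ER_CRISP = 2269


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic cohort.

    ``ihc_error_rate`` is the probability that an IHC label contradicts
    the latent component (symmetric flip by default; pass
    ``ihc_error_rates=(neg_rate, pos_rate)`` for per-class rates);
    ``ihc_missing_rate`` the probability the label is then blanked.
    """

    n_samples: int
    model: TwoComponentModel
    ihc_error_rate: float = 0.0
    ihc_missing_rate: float = 0.0
    seed: int = 0
    ihc_error_rates: Optional[Tuple[float, float]] = None
    cutpoint: Optional[float] = field(default=None)  # published CP, if any

    def __post_init__(self):
        if self.n_samples < 1:
            raise InvalidConfigError(f"n_samples={self.n_samples} < 1")
        rates = self.ihc_error_rates or (self.ihc_error_rate, self.ihc_error_rate)
        for r in rates:
            if not 0.0 <= r < 0.5:
                raise InvalidConfigError(f"ihc error rate {r} not in [0, 0.5)")
        if not 0.0 <= self.ihc_missing_rate < 1.0:
            raise InvalidConfigError(
                f"ihc_missing_rate={self.ihc_missing_rate} not in [0, 1)"
            )


def preset(receptor: str, method_row: str = "ExMax") -> SimConfig:
    """Published parameter row as a ready-to-draw :class:`SimConfig`.

    ``receptor`` in {ER, PGR, HER2}; ``method_row`` in {ParEst, MaxLike,
    ExMax}.  Cut-point-only methods (Youden, LogReg) have no
    distribution parameters and raise.
    """
    key = (receptor, method_row)
    if key not in TABLE_PRESETS:
        raise InvalidConfigError(
            f"no distribution-parameter row for {receptor!r}/{method_row!r}"
        )
    cp, mu_n, mu_p, s_n, s_p, w = TABLE_PRESETS[key]
    model = TwoComponentModel(
        neg=GaussianComponent(mu_n, s_n),
        pos=GaussianComponent(mu_p, s_p),
        weight_pos=w,
        method=method_row,
        probe_id=RECEPTOR_PROBES[receptor],
    )
    return SimConfig(n_samples=N_ER_CRISP, model=model, seed=0, cutpoint=cp)


def with_options(cfg: SimConfig, **kwargs) -> SimConfig:
    """Functional update of a config (e.g. ``with_options(p, n_samples=500)``)."""
    return replace(cfg, **kwargs)


def simulate_cohort(cfg: SimConfig):
    """Draw one synthetic cohort.

    Returns ``(expr, ihc, latent)``: the expression vector, the possibly
    noisy/missing IHC labels, and the latent component indicator
    (True = receptor positive).  One named random stream derives from
    ``cfg.seed``; identical configs give identical cohorts.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    m = cfg.model
    latent = rng.random(n) < m.weight_pos
    mu = np.where(latent, m.pos.mu, m.neg.mu)
    sigma = np.where(latent, m.pos.sigma, m.neg.sigma)
    values = rng.normal(mu, sigma)

    rate_neg, rate_pos = cfg.ihc_error_rates or (cfg.ihc_error_rate, cfg.ihc_error_rate)
    flip_p = np.where(latent, rate_pos, rate_neg)
    flipped = latent ^ (rng.random(n) < flip_p)
    missing = rng.random(n) < cfg.ihc_missing_rate
    ihc = [
        IHCStatus.MISSING
        if miss
        else (IHCStatus.POSITIVE if lab else IHCStatus.NEGATIVE)
        for lab, miss in zip(flipped, missing)
    ]
    expr = ExpressionVector(
        sample_ids=[f"S{i:05d}" for i in range(n)],
        values=values,
        probe_id=m.probe_id,
    )
    return expr, ihc, latent


def simulate_probe_matrix(
    n_probes: int,
    n_samples: int,
    seed: int = 0,
    receptor_cfg: Optional[SimConfig] = None,
    background_mu: float = 7.0,
    background_sigma: float = 2.0,
) -> pd.DataFrame:
    """Synthetic whole-chip matrix (probes x samples) for look-up tests.

    Background probes draw i.i.d. Gaussian log2 intensities; when
    ``receptor_cfg`` is given, one row named after its probe carries
    bimodal receptor expression (n_samples overriding the config's).
    """
    if n_probes < 10 or n_samples < 1:
        raise InvalidConfigError("need n_probes >= 10 and n_samples >= 1")
    rng = np.random.default_rng(seed)
    mat = rng.normal(background_mu, background_sigma, size=(n_probes, n_samples))
    index = [f"bg_{i}_at" for i in range(n_probes)]
    df = pd.DataFrame(mat, index=index, columns=[f"S{j:04d}" for j in range(n_samples)])
    if receptor_cfg is not None:
        sub = with_options(receptor_cfg, n_samples=n_samples, seed=seed + 1)
        expr, _, _ = simulate_cohort(sub)
        probe = receptor_cfg.model.probe_id or "receptor_at"
        df.iloc[0] = expr.values
        df.index = [probe] + index[1:]
    return df
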