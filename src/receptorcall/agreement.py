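"""Agreement between IHC receptor status and gene-expression calls.

Concordance of the two assays is summarized on contingency tables:
2x2 when both assays give crisp calls, 3x3 when missing IHC and
undecidable GE are kept as their own middle category.  The headline
statistic is the diagnostic odds ratio on the natural-log scale with a
Woolf-type 95% confidence interval; Cohen's kappa, Goodman-Kruskal
gamma and the discordant/conclusive rates complete the picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import IHCStatus
from .decision import GeneCall, GeneState
from .errors import EmptyInputError, InvalidInputError, LengthMismatchError

#: Row/column order of every table: negative, undecided/missing, positive.
STATE_ORDER_2 = ("neg", "pos")
STATE_ORDER_3 = ("neg", "zero", "pos")


@dataclass(frozen=True)
class CrossTable:
    """IHC x GE contingency table, 2x2 or 3x3.

    Rows index IHC states, columns GE states, both ordered
    (negative, [undecided,] positive).
    """

    counts: np.ndarray

    def __init__(self, counts):
        counts = np.asarray(counts)
        if counts.shape not in ((2, 2), (3, 3)):
            raise InvalidInputError(f"table must be 2x2 or 3x3, got shape {counts.shape}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)) or np.any(counts < 0):
                raise InvalidInputError("counts must be non-negative integers")
            counts = counts.astype(np.int64)
        if counts.sum() == 0:
            raise EmptyInputError("contingency table is empty")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ContingencySummary:
    """Agreement statistics of one IHC x GE table.

    ``log_dor`` is the natural log of the diagnostic odds ratio and
    ``log_dor_ci95`` its Woolf half-width; ``dor_finite`` is False when
    an off-diagonal zero makes the odds ratio infinite (no continuity
    correction is applied).  Rates are fractions of the table total.
    """

    log_dor: float
    log_dor_ci95: float
    kappa: float
    gamma: float
    discordant_rate: float
    conclusive_rate: float
    dor_finite: bool = True


def _kappa(t: np.ndarray) -> float:
    """Cohen's kappa from the table's marginals."""
    n = t.sum()
    p_obs = np.trace(t) / n
    p_chance = float((t.sum(axis=0) * t.sum(axis=1)).sum()) / n**2
    if p_chance == 1.0:
        return 1.0
    return float((p_obs - p_chance) / (1.0 - p_chance))


def _gamma(t: np.ndarray) -> float:
    """Goodman-Kruskal gamma via concordant/discordant pair counts.

    Works for any square ordinal table; on a 2x2 it reduces to Yule's Q.
    """
    r, c = t.shape
    con = dis = 0.0
    for i in range(r):
        for j in range(c):
            con += t[i, j] * t[i + 1 :, j + 1 :].sum()
            dis += t[i, j] * t[i + 1 :, :j].sum()
    if con + dis == 0:
        return 0.0
    return float((con - dis) / (con + dis))


def summarize_2x2(table: CrossTable) -> ContingencySummary:
    """Agreement statistics of a crisp 2x2 IHC x GE table.

    log DOR = ln[(n(-,-) n(+,+)) / (n(-,+) n(+,-))], Woolf half-width
    1.96 sqrt(sum of reciprocal cells).  A zero off-diagonal cell makes
    the DOR infinite: the summary is flagged rather than corrected.
    """
    t = table.counts.astype(float)
    if t.shape != (2, 2):
        raise InvalidInputError("summarize_2x2 needs a 2x2 table")
    a, b = t[0, 0], t[0, 1]  # IHC- row: GE-, GE+
    c, d = t[1, 0], t[1, 1]  # IHC+ row
    dor_finite = bool(np.all(t > 0))
    if b == 0 or c == 0:
        log_dor = math.inf
        hw = math.inf
    elif a == 0 or d == 0:
        log_dor = -math.inf
        hw = math.inf
    else:
        log_dor = math.log(a * d / (b * c))
        hw = 1.96 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    discordant = (b + c) / table.total
    return ContingencySummary(
        log_dor=log_dor,
        log_dor_ci95=hw,
        kappa=_kappa(t),
        gamma=_gamma(t),
        discordant_rate=float(discordant),
        conclusive_rate=float(1.0 - discordant),
        dor_finite=dor_finite,
    )


def summarize_3x3(table: CrossTable) -> ContingencySummary:
    """Agreement statistics of a 3x3 table with undecided middle states.

    Only hard contradictions (IHC- with GE+, IHC+ with GE-) count as
    discordant.  A sample is inconclusive when it is discordant or
    undecided by both assays, so
    conclusive = 1 - (discordant + n(IHC0, GE0)) / N.
    The odds-ratio-type statistics are computed on the embedded 2x2 of
    the crisply decided corner cells.
    """
    t = table.counts
    if t.shape != (3, 3):
        raise InvalidInputError("summarize_3x3 needs a 3x3 table")
    corners = CrossTable(t[np.ix_([0, 2], [0, 2])])
    crisp = summarize_2x2(corners)
    n = table.total
    discordant = (t[0, 2] + t[2, 0]) / n
    conclusive = 1.0 - (t[0, 2] + t[2, 0] + t[1, 1]) / n
    return ContingencySummary(
        log_dor=crisp.log_dor,
        log_dor_ci95=crisp.log_dor_ci95,
        kappa=crisp.kappa,
        gamma=crisp.gamma,
        discordant_rate=float(discordant),
        conclusive_rate=float(conclusive),
        dor_finite=crisp.dor_finite,
    )


_IHC_ROW = {IHCStatus.NEGATIVE: 0, IHCStatus.MISSING: 1, IHCStatus.POSITIVE: 2}
_GE_COL = {GeneState.GE_NEG: 0, GeneState.GE_ZERO: 1, GeneState.GE_POS: 2}


def cross_tabulate(ihc: Sequence[IHCStatus], calls: Sequence[GeneCall]) -> CrossTable:
    """Count samples into the 3x3 IHC x GE table.

    Rows: IHC-, IHC missing, IHC+.  Columns: GE-, GE0, GE+.  Cell sums
    conserve the number of samples.
    """
    if len(ihc) != len(calls):
        raise LengthMismatchError(f"{len(ihc)} IHC labels vs {len(calls)} calls")
    if len(ihc) == 0:
        raise EmptyInputError("no samples to tabulate")
    t = np.zeros((3, 3), dtype=np.int64)
    for s, call in zip(ihc, calls):
        state = call.state if isinstance(call, GeneCall) else call
        t[_IHC_ROW[s], _GE_COL[state]] += 1
    return CrossTable(t)
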