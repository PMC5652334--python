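"""Therapy-allocation check over ER and PGR, with Kaplan-Meier curves.

Endocrine (anti-hormone) therapy is indicated when either hormone
receptor (ER or PGR) is positive.  Comparing the IHC-based decision with
the gene-expression call sorts patients into four groups: two where GE
confirms the IHC-based therapy choice and two where GE contradicts it.
Contradiction is deliberately weak — it requires a crisp opposite GE
call, not merely an undecidable one — so that borderline samples do not
trigger warnings, yet no crisp contradiction is suppressed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import IHCStatus
from .decision import GeneCall, GeneState
from .errors import EmptyInputError, InvalidInputError


class AllocationGroup(enum.Enum):
    """Concordance groups of the therapy-allocation check."""

    HORMONE_POSITIVE_CONFIRMED = 1  # IHC+ hormone status, GE compatible
    NEGATIVE_CONFIRMED = 2          # both receptors IHC-, GE compatible
    POSITIVE_CONTRADICTED = 3       # IHC says positive, GE crisply negative
    NEGATIVE_CONTRADICTED = 4       # IHC says negative, GE crisply positive


def _state(call) -> GeneState:
    return call.state if isinstance(call, GeneCall) else call


def assign_group(
    er_ihc: IHCStatus,
    pgr_ihc: IHCStatus,
    er_call,
    pgr_call,
) -> Optional[AllocationGroup]:
    """Assign one patient to an allocation group (or None if unassignable).

    With P = IHC positive, N = IHC negative, and GE states -/0/+:

    * group 3 (positive contradicted): (ER P or PGR P) and both GE calls
      crisply negative;
    * group 4 (negative contradicted): both IHC negative and at least
      one GE call crisply positive;
    * group 1 (hormone-positive confirmed): (ER P and ER GE in {+,0}) or
      (PGR P and PGR GE in {+,0});
    * group 2 (negative confirmed): both IHC negative and both GE calls
      in {0,-}.

    The clauses overlap (one receptor may confirm while the other
    contradicts); contradiction groups are tested first so that a
    possibly decisive warning is never suppressed by a confirmation.
    Patients with both IHC statuses missing are unassigned.
    """
    er_ge, pgr_ge = _state(er_call), _state(pgr_call)
    er_p = er_ihc is IHCStatus.POSITIVE
    pgr_p = pgr_ihc is IHCStatus.POSITIVE
    er_n = er_ihc is IHCStatus.NEGATIVE
    pgr_n = pgr_ihc is IHCStatus.NEGATIVE
    if er_ihc is IHCStatus.MISSING and pgr_ihc is IHCStatus.MISSING:
        return None

    both_ge_neg = er_ge is GeneState.GE_NEG and pgr_ge is GeneState.GE_NEG
    any_ge_pos = er_ge is GeneState.GE_POS or pgr_ge is GeneState.GE_POS
    if (er_p or pgr_p) and both_ge_neg:
        return AllocationGroup.POSITIVE_CONTRADICTED
    if (er_n and pgr_n) and any_ge_pos:
        return AllocationGroup.NEGATIVE_CONTRADICTED
    if (er_p and er_ge in (GeneState.GE_POS, GeneState.GE_ZERO)) or (
        pgr_p and pgr_ge in (GeneState.GE_POS, GeneState.GE_ZERO)
    ):
        return AllocationGroup.HORMONE_POSITIVE_CONFIRMED
    if (
        er_n
        and pgr_n
        and er_ge in (GeneState.GE_ZERO, GeneState.GE_NEG)
        and pgr_ge in (GeneState.GE_ZERO, GeneState.GE_NEG)
    ):
        return AllocationGroup.NEGATIVE_CONFIRMED
    return None


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time on study and whether relapse occurred."""

    time: float
    event: bool

    def __post_init__(self):
        if not (self.time >= 0 and np.isfinite(self.time)):
            raise InvalidInputError(f"survival time must be finite and >= 0, got {self.time}")


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier step function with plain-Greenwood 95% bands.

    ``times`` starts at 0 where ``survival`` is 1; the curve is
    right-continuous and non-increasing.  Bands are
    S(t) +/- 1.96 sqrt(Var[S(t)]) with Greenwood's variance, clipped to
    [0, 1].
    """

    times: np.ndarray
    survival: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def kaplan_meier(records: Sequence[SurvivalRecord]) -> SurvivalCurve:
    """Product-limit survival estimate with Greenwood confidence bands.

    The step estimate and risk sets come from the standard product-limit
    construction (cross-checked in the tests against lifelines); the
    variance is Greenwood's
    Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i)).
    """
    if len(records) == 0:
        raise EmptyInputError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([bool(r.event) for r in records])
    if np.all(times == 0) and not events.any():
        import warnings

        warnings.warn("all follow-up times are zero with no events; degenerate curve",
                      stacklevel=2)

    event_times = np.unique(times[events])
    out_t = [0.0]
    out_s = [1.0]
    out_var_term = [0.0]
    s = 1.0
    cum = 0.0
    for t in event_times:
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        if n_at_risk == 0:
            continue
        s *= 1.0 - d / n_at_risk
        if n_at_risk > d:
            cum += d / (n_at_risk * (n_at_risk - d))
        else:
            cum = np.inf  # S hits 0; variance term degenerates
        out_t.append(float(t))
        out_s.append(s)
        out_var_term.append(cum)
    surv = np.array(out_s)
    with np.errstate(invalid="ignore"):
        var = surv**2 * np.array(out_var_term)
    var = np.where(np.isfinite(var), var, 0.0)  # S=0 has zero-width band
    half = 1.96 * np.sqrt(var)
    return SurvivalCurve(
        times=np.array(out_t),
        survival=surv,
        lower=np.clip(surv - half, 0.0, 1.0),
        upper=np.clip(surv + half, 0.0, 1.0),
    )


def group_survival(groups: Sequence[Optional[AllocationGroup]],
                   records: Sequence[SurvivalRecord]) -> dict:
    """Kaplan-Meier curve per allocation group (unassigned patients skipped)."""
    if len(groups) != len(records):
        from .errors import LengthMismatchError

        raise LengthMismatchError(f"{len(groups)} groups vs {len(records)} records")
    curves = {}
    for g in AllocationGroup:
        recs = [r for gg, r in zip(groups, records) if gg is g]
        if recs:
            curves[g] = kaplan_meier(recs)
    return curves
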