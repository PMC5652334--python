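"""Expression look-up table: projecting a new sample onto a reference cohort.

RMA-normalized cohorts share, to a good approximation, a common
distribution of per-sample expression values.  That makes rank a
portable currency: a newly diagnosed sample, measured in whatever raw
units its lab produces, can be placed on the reference cohort's
normalized scale by (a) ranking the receptor probe among the sample's
own probes and (b) reading the reference expression at that rank off a
monotone rank -> expression curve.  The projected value is directly
comparable with the critical-domain limits — no re-normalization of the
new sample is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InvalidMatrixError, MissingProbeError


@dataclass(frozen=True)
class LookupTable:
    """Monotone rank -> reference-expression curve for one receptor probe.

    ``curve[r-1]`` is the reference expression at rank r (1-based,
    ascending).  Built as the mean across reference samples of each
    sample's r-th smallest value — the quantile-reference construction —
    so it is non-decreasing by construction.
    """

    probe_id: str
    curve: np.ndarray
    n_reference_samples: int
    probe_ids: Optional[tuple] = None

    @property
    def n_probes(self) -> int:
        return int(self.curve.shape[0])

    def at_rank(self, rank: int) -> float:
        if not 1 <= rank <= self.n_probes:
            raise InvalidMatrixError(f"rank {rank} outside 1..{self.n_probes}")
        return float(self.curve[rank - 1])


def build_lookup(reference, probe_id: str) -> LookupTable:
    """Build the rank -> expression curve from a reference cohort.

    ``reference`` is an RMA-normalized probes x samples matrix (a
    DataFrame indexed by probe id, or any 2-D array-like).  Each
    sample's values are sorted ascending; the curve value at rank r is
    the mean over samples of the r-th order statistic.
    """
    probe_index = None
    if isinstance(reference, pd.DataFrame):
        probe_index = tuple(reference.index.astype(str))
        mat = reference.to_numpy(dtype=float)
    else:
        try:
            mat = np.asarray(reference, dtype=float)
        except (ValueError, TypeError) as exc:
            raise InvalidMatrixError(f"reference matrix is ragged or non-numeric: {exc}")
        if mat.ndim != 2:
            raise InvalidMatrixError(f"reference must be 2-D, got ndim={mat.ndim}")
    n_probes, n_samples = mat.shape
    if n_samples < 1 or n_probes < 10:
        raise InvalidMatrixError(
            f"reference needs >=1 sample and >=10 probes, got {n_samples} x {n_probes}"
        )
    if not np.all(np.isfinite(mat)):
        raise InvalidMatrixError("reference matrix contains non-finite values")
    if probe_index is not None and probe_id not in probe_index:
        raise MissingProbeError(f"probe {probe_id!r} not in the reference matrix")
    curve = np.sort(mat, axis=0).mean(axis=1)
    return LookupTable(
        probe_id=probe_id,
        curve=curve,
        n_reference_samples=n_samples,
        probe_ids=probe_index,
    )


def rank_in_sample(new_sample: pd.Series, probe_id: str) -> int:
    """Ascending ordinal rank of ``probe_id`` within one sample's values.

    Ties are broken by the stable order of the probes in the series, so
    the rank (and hence every projection) is reproducible bit for bit.
    """
    if probe_id not in new_sample.index:
        raise MissingProbeError(f"probe {probe_id!r} absent from the new sample")
    ranks = rankdata(new_sample.to_numpy(dtype=float), method="ordinal")
    pos = new_sample.index.get_loc(probe_id)
    return int(ranks[pos])


def project_sample(table: LookupTable, new_sample, probe_id: Optional[str] = None) -> float:
    """Project a new sample's receptor rank onto the reference curve.

    ``new_sample`` holds the sample's raw expression of *all* probes in
    the table's universe (a Series indexed by probe id, or a plain
    vector of length ``n_probes``).  The receptor probe's rank r within
    the sample maps to the r/n_probes quantile of the reference, i.e.
    ``curve[r-1]``, which is already on the reference's normalized scale.
    """
    probe_id = probe_id or table.probe_id
    if not isinstance(new_sample, pd.Series):
        if table.probe_ids is None:
            raise MissingProbeError(
                "plain vectors need a table built from a DataFrame (known probe order)"
            )
        new_sample = pd.Series(np.asarray(new_sample, dtype=float), index=table.probe_ids)
    if len(new_sample) != table.n_probes:
        raise InvalidMatrixError(
            f"sample covers {len(new_sample)} probes, table expects {table.n_probes}"
        )
    r = rank_in_sample(new_sample, probe_id)
    return table.at_rank(r)


# -- serialization -----------------------------------------------------------

def write_lookup_tsv(table: LookupTable, path, header_path=None) -> None:
    """Write the curve as a two-column TSV (rank, expression) plus a JSON
    sidecar with probe id and reference size."""
    import json

    df = pd.DataFrame(
        {"rank": np.arange(1, table.n_probes + 1), "expression": table.curve}
    )
    df.to_csv(path, sep="\t", index=False)
    if header_path is not None:
        with open(header_path, "w") as fh:
            json.dump(
                {
                    "probe_id": table.probe_id,
                    "n_probes": table.n_probes,
                    "n_reference_samples": table.n_reference_samples,
                },
                fh,
                indent=1,
            )


def read_lookup_tsv(path, header_path) -> LookupTable:
    import json

    df = pd.read_csv(path, sep="\t")
    with open(header_path) as fh:
        meta = json.load(fh)
    curve = df.sort_values("rank")["expression"].to_numpy(dtype=float)
    if len(curve) != meta["n_probes"]:
        raise InvalidMatrixError("lookup TSV length disagrees with its header")
    return LookupTable(
        probe_id=meta["probe_id"],
        curve=curve,
        n_reference_samples=meta["n_reference_samples"],
    )
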