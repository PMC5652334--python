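"""Reading and writing the package's file formats.

Everything tabular is TSV (expression ids never contain tabs, decimal
point always '.'); models travel as JSON.  Validation is strict: unknown
IHC tokens, duplicate identifiers and non-numeric expression cells each
raise their own named error rather than being coerced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionVector, IHCStatus, TwoComponentModel, parse_ihc
from .decision import GeneCall
from .errors import DuplicateSampleError, SchemaError

IHC_COLUMNS = {"ER": "er_ihc", "PGR": "pgr_ihc", "HER2": "her2_ihc"}
SURVIVAL_COLUMNS = ("rfs_months", "rfs_event")


@dataclass(frozen=True)
class CohortBundle:
    """Expression matrix plus matching annotations for one cohort."""

    expression: pd.DataFrame  # probes x samples
    annotations: pd.DataFrame  # indexed by sample_id
    source: str = ""
    normalization: str = "RMA-log2"

    def __post_init__(self):
        missing = set(self.annotations.index) - set(self.expression.columns)
        if missing:
            raise SchemaError(f"annotation rows without matrix columns: {sorted(missing)[:5]}")

    def probe_vector(self, probe_id: str) -> ExpressionVector:
        from .errors import MissingProbeError

        if probe_id not in self.expression.index:
            raise MissingProbeError(f"probe {probe_id!r} not in the expression matrix")
        row = self.expression.loc[probe_id]
        return ExpressionVector(
            sample_ids=list(row.index), values=row.to_numpy(dtype=float), probe_id=probe_id
        )

    def ihc_labels(self, receptor: str) -> list:
        col = IHC_COLUMNS.get(receptor, receptor)
        if col not in self.annotations.columns:
            raise SchemaError(f"annotation table lacks column {col!r}")
        ordered = self.annotations.reindex(self.expression.columns)
        return [parse_ihc(v) for v in ordered[col]]


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a probes x samples expression matrix.

    First column holds probe ids; remaining columns are samples.  Both
    probe and sample identifiers must be unique; every cell numeric.
    """
    header = pd.read_csv(path, sep="\t", header=None, nrows=1).iloc[0].astype(str)
    sample_ids = header.iloc[1:]
    if sample_ids.duplicated().any():
        dupes = sample_ids[sample_ids.duplicated()].tolist()
        raise DuplicateSampleError(f"duplicate sample ids: {dupes}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise DuplicateSampleError(f"duplicate probe ids: {dupes}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric expression cell: {exc}")
    if not np.all(np.isfinite(values.to_numpy())):
        raise SchemaError("expression matrix contains non-finite values")
    return values


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def read_annotations_tsv(path) -> pd.DataFrame:
    """Read the sample annotation table, validating IHC columns.

    Must contain a ``sample_id`` column; any of the known IHC columns
    are parsed (and re-stored as canonical '+'/'-'/'' tokens handled by
    :func:`receptorcall.core.parse_ihc` at use time).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if "sample_id" not in df.columns:
        raise SchemaError("annotation table needs a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise DuplicateSampleError(f"duplicate sample ids: {dupes}")
    df = df.set_index("sample_id")
    for col in IHC_COLUMNS.values():
        if col in df.columns:
            df[col].map(parse_ihc)  # validate every token now, fail early
    return df


def write_annotations_tsv(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="sample_id")


def write_calls_tsv(sample_ids: Sequence, calls: Sequence[GeneCall], path,
                    probe_id: str = "") -> None:
    """Per-sample calls TSV: sample_id, probe_id, expression, r_neg, state."""
    rows = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "probe_id": probe_id,
            "expression": [c.expression for c in calls],
            "r_neg": [c.responsibility_neg for c in calls],
            "state": [c.state.value for c in calls],
        }
    )
    rows.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_calls_tsv(path) -> pd.DataFrame:
    from .decision import GeneState

    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "expression", "state"}
    if not required <= set(df.columns):
        raise SchemaError(f"calls table needs columns {sorted(required)}")
    valid = {s.value for s in GeneState}
    bad = set(df["state"]) - valid
    if bad:
        raise SchemaError(f"unknown call states: {sorted(bad)}")
    return df


def write_model_json(model: TwoComponentModel, path, ci=None) -> None:
    doc = model.to_dict()
    if ci is not None:
        doc["ci"] = ci.to_dict()
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_model_json(path):
    """Read a model JSON; returns (model, ci_dict_or_None)."""
    with open(path) as fh:
        doc = json.load(fh)
    ci = doc.pop("ci", None)
    return TwoComponentModel.from_dict(doc), ci
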