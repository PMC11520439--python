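"""Readers and writers for every on-disk artifact of the pipeline.

All formats are plain UTF-8 text: tab-separated tables for expression,
labels and survival data, the standard GMT dialect for gene sets, and a
documented key-value text format for fitted models.  Expression matrices
are expected gene-level and log2-scale (genes on rows, samples on
columns); values are never reordered on read, and missing values are a
hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_labels",
    "write_labels",
    "read_survival",
    "write_survival",
    "read_model",
    "write_model",
]


@dataclass
class ExpressionMatrix:
    """A genes-by-samples matrix of log2 expression values for one cohort."""

    values: pd.DataFrame
    cohort_id: str = ""

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in expression matrix")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in expression matrix")
        arr = self.values.to_numpy()
        if arr.size == 0:
            raise ValueError("expression matrix is empty")
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {idx[g]!r}, sample {cols[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


class GeneSet(NamedTuple):
    description: str
    members: tuple[str, ...]


def read_expression(path: str | Path, cohort_id: str = "") -> ExpressionMatrix:
    """Read a genes-by-samples TSV (first column gene ids, header sample ids)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty expression file")
    sample_ids = header.rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample id {sid!r} in header")
        seen.add(sid)

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: expression file has no data rows or columns")
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    check = raw.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(check.isna().to_numpy())
    if bad.size:
        g, s = bad[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[g, s]!r} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}"
        )
    numeric = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    numeric.columns = sample_ids  # preserve exact header order/names
    numeric.index.name = raw.index.name
    return ExpressionMatrix(numeric.astype(float), cohort_id=cohort_id or path.stem)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    if df.index.name is None:
        df.index.name = "gene_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT gene-set file: ``name<TAB>description<TAB>member...`` per line."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    members.append(g)
                    seen.add(g)
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = GeneSet(desc, tuple(members))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: Mapping[str, GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, gs in sets.items():
            fh.write("\t".join([name, gs.description, *gs.members]) + "\n")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV ``sample_id<TAB>label`` with binary labels."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: labels file must have exactly 2 columns")
    sids, labs = df.iloc[:, 0], df.iloc[:, 1]
    if sids.duplicated().any():
        raise ValueError(f"{path}: duplicate sample id {sids[sids.duplicated()].iloc[0]!r}")
    if not labs.isin(["0", "1"]).all():
        bad = labs[~labs.isin(["0", "1"])].iloc[0]
        raise ValueError(f"{path}: label value {bad!r} is not 0 or 1")
    return pd.Series(labs.astype(np.int8).to_numpy(), index=list(sids), name="label")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, val in labels.items():
            fh.write(f"{sid}\t{int(val)}\n")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a three-column TSV ``sample_id<TAB>time<TAB>event``.

    Times must be strictly positive; events are 1 (death/event observed)
    or 0 (censored).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] != 3:
        raise ValueError(f"{path}: survival file must have exactly 3 columns")
    sids = df.iloc[:, 0]
    if sids.duplicated().any():
        raise ValueError(f"{path}: duplicate sample id {sids[sids.duplicated()].iloc[0]!r}")
    time = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    event = df.iloc[:, 2]
    if time.isna().any():
        raise ValueError(f"{path}: non-numeric survival time {df.iloc[:, 1][time.isna()].iloc[0]!r}")
    if (time <= 0).any():
        sid = sids[time <= 0].iloc[0]
        raise ValueError(f"{path}: non-positive survival time for sample {sid!r}")
    if not event.isin(["0", "1"]).all():
        raise ValueError(f"{path}: event value {event[~event.isin(['0', '1'])].iloc[0]!r} is not 0 or 1")
    out = pd.DataFrame(
        {"time": [float(x) for x in df.iloc[:, 1]],  # exact round-trip parse
         "event": event.astype(np.int8).to_numpy()},
        index=list(sids),
    )
    out.index.name = "sample_id"
    return out


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\ttime\tevent\n")
        for sid, row in surv.iterrows():
            fh.write(f"{sid}\t{float(row['time'])!r}\t{int(row['event'])}\n")


def write_model(model, path: str | Path) -> None:
    """Serialize a diagnostic or prognostic model to key-value text.

    Floats are written with ``repr`` so read(write(m)) reproduces every
    coefficient exactly and a write/read/write cycle is byte-identical.
    """
    from .models import DiagnosticModel, PrognosticModel  # local: avoid import cycle

    lines: list[str] = []
    if isinstance(model, DiagnosticModel):
        lines.append("pairdx-model\tdiagnostic\tv1")
    elif isinstance(model, PrognosticModel):
        lines.append("pairdx-model\tprognostic\tv1")
    else:
        raise TypeError(f"cannot serialize object of type {type(model).__name__}")
    for key in sorted(model.meta):
        lines.append(f"meta\t{key}\t{model.meta[key]!r}")
    if isinstance(model, DiagnosticModel):
        lines.append(f"intercept\t{model.intercept!r}")
    for pair, coef in zip(model.pairs, model.coefficients):
        lines.append(f"pair\t{pair.gene_a}\t{pair.gene_b}\t{coef!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_model(path: str | Path):
    """Read a model written by :func:`write_model`."""
    from .models import DiagnosticModel, PrognosticModel
    from .pairs import GenePair

    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("pairdx-model\t"):
        raise ValueError(f"{path}: not a pairdx model file")
    header = lines[0].split("\t")
    if len(header) != 3 or header[2] != "v1" or header[1] not in ("diagnostic", "prognostic"):
        raise ValueError(f"{path}: malformed model header {lines[0]!r}")
    kind = header[1]
    meta: dict[str, object] = {}
    intercept: float | None = None
    pairs: list[GenePair] = []
    coefs: list[float] = []
    import ast

    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        tag = fields[0]
        try:
            if tag == "meta" and len(fields) == 3:
                meta[fields[1]] = ast.literal_eval(fields[2])
            elif tag == "intercept" and len(fields) == 2 and kind == "diagnostic":
                intercept = float(fields[1])
            elif tag == "pair" and len(fields) == 4:
                pairs.append(GenePair(fields[1], fields[2]))
                coefs.append(float(fields[3]))
            else:
                raise ValueError
        except (ValueError, SyntaxError):
            raise ValueError(f"{path}:{lineno}: malformed model line {line!r}") from None
    if kind == "diagnostic":
        if intercept is None:
            raise ValueError(f"{path}: diagnostic model file lacks an intercept line")
        return DiagnosticModel(tuple(pairs), tuple(coefs), intercept, meta)
    return PrognosticModel(tuple(pairs), tuple(coefs), meta)
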