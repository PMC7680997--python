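"""Reading and writing pipeline artifacts.

Expression matrices (genes x samples, TSV/CSV), clinical/survival tables,
immune-gene lists and fitted gene-pair signatures all enter and leave the
pipeline through this module.  The published 14-pair prognostic signature
for papillary renal cell carcinoma ships as packaged data and is exposed
through :func:`load_published_signature`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "FittedSignature",
    "read_expression",
    "read_clinical",
    "read_gene_set",
    "load_published_signature",
    "write_model",
    "read_model",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative gene-by-sample abundance matrix (FPKM or intensity).

    ``data`` is indexed by gene symbol with one column per sample.  Values
    are unit-free: every downstream statistic in this package depends only
    on within-sample ranks, so FPKM and microarray intensities are handled
    identically.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample follow-up: time to event/censoring, event indicator, covariates.

    ``data`` is indexed by sample id with mandatory columns ``time`` (> 0,
    in ``time_unit``) and ``event`` (1 = death, 0 = censored); any further
    columns are clinical covariates (age, gender, stage, subtype, ...).
    """

    data: pd.DataFrame
    time_unit: str = "days"

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in clinical table")
        if self.time_unit not in ("days", "months", "years"):
            raise ValueError(f"unsupported time unit {self.time_unit!r}")
        time = self.data["time"].to_numpy(dtype=float)
        event = self.data["event"].to_numpy()
        if not np.all(np.isfinite(time)) or (time <= 0).any():
            raise ValueError("follow-up times must be finite and positive")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicator must be 0 (censored) or 1 (death)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.data["event"].astype(int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from clinical table: {missing[:5]}")
        return ClinicalTable(self.data.loc[list(sample_ids)], self.time_unit)


@dataclass(frozen=True)
class FittedSignature:
    """An ordered list of gene pairs with lasso-Cox coefficients.

    Scoring a sample sums ``coefficients[k]`` over the pairs whose first
    gene out-expresses the second in that sample.  ``cutoff`` is the risk
    threshold separating high from low risk, if one was chosen.
    """

    pairs: tuple[tuple[str, str], ...]
    coefficients: tuple[float, ...]
    cutoff: float | None = None
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple((str(a), str(b)) for a, b in self.pairs))
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        if len(self.pairs) != len(self.coefficients):
            raise ValueError("pairs and coefficients differ in length")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate gene pairs in signature")
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"pair ({a!r}, {b!r}) compares a gene with itself")
        for c in self.coefficients:
            if not np.isfinite(c) or c == 0.0:
                raise ValueError("coefficients must be finite and non-zero")
        if self.cutoff is not None and not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}

    def __len__(self) -> int:
        return len(self.pairs)


def _read_table(path: str | Path, fmt: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unsupported format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(header) != len(set(header)):
        raise ValueError(f"duplicate sample identifiers in header of {path}")
    return pd.read_csv(path, sep=sep)


def read_expression(
    path: str | Path,
    fmt: str | None = None,
    *,
    drop_zero_genes: bool = True,
) -> ExpressionMatrix:
    """Read a gene-by-sample expression matrix from TSV/CSV.

    The first column holds gene symbols, the header row sample ids.
    Duplicate gene rows are collapsed by per-sample maximum.  When
    ``drop_zero_genes`` is true (appropriate for FPKM-type RNA-seq input),
    genes with zero abundance in more than half of the samples are removed;
    disable it for microarray intensities, where zeros are not sparsity.
    """
    raw = _read_table(path, fmt)
    if raw.shape[1] < 2:
        raise ValueError("expression file needs a gene column plus at least one sample")
    gene_col = raw.columns[0]
    sample_ids = list(raw.columns[1:])
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample identifiers in expression header")
    values = raw[sample_ids].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(f"non-numeric expression values in columns {bad[:5]}")
    values.index = raw[gene_col].astype(str).str.strip()
    # collapse duplicate symbols by per-sample maximum
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by per-sample maximum", n_dup)
        values = values.groupby(level=0, sort=False).max()
    if drop_zero_genes:
        n_samples = values.shape[1]
        zero_frac = (values == 0).sum(axis=1)
        keep = zero_frac <= n_samples / 2
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("removing %d genes with zeros in more than half of samples", n_drop)
        values = values.loc[keep]
    if values.empty:
        raise ValueError("no genes left after filtering")
    return ExpressionMatrix(values)


def read_clinical(
    path: str | Path,
    fmt: str | None = None,
    *,
    time_unit: str = "days",
) -> ClinicalTable:
    """Read a clinical table with columns sample_id, time, event.

    Rows with missing time or event are dropped (incomplete follow-up);
    rows with non-positive time or an event flag outside {0, 1} are
    rejected with a warning.  Extra columns become covariates.
    """
    raw = _read_table(path, fmt)
    required = {"sample_id", "time", "event"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"clinical table lacks required columns {sorted(missing)}")
    n_in = len(raw)
    raw = raw.dropna(subset=["time", "event"])
    n_incomplete = n_in - len(raw)
    if n_incomplete:
        logger.warning("excluded %d samples without complete follow-up", n_incomplete)
    time = pd.to_numeric(raw["time"], errors="coerce")
    event = pd.to_numeric(raw["event"], errors="coerce")
    valid = time.notna() & (time > 0) & event.isin((0, 1))
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.warning("rejected %d rows with invalid time/event values", n_invalid)
    raw = raw.loc[valid]
    if raw.empty:
        raise ValueError("no usable clinical rows")
    table = raw.set_index(raw["sample_id"].astype(str)).drop(columns=["sample_id"])
    table.index.name = "sample_id"
    table["time"] = pd.to_numeric(table["time"])
    table["event"] = pd.to_numeric(table["event"]).astype(int)
    return ClinicalTable(table, time_unit=time_unit)


def read_gene_set(path: str | Path) -> set[str]:
    """Read a gene list, one symbol per line; trims whitespace, drops duplicates."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    symbols = {line.strip() for line in path.read_text().splitlines()}
    symbols.discard("")
    if not symbols:
        raise ValueError(f"gene set file {path} is empty")
    return symbols


def load_published_signature() -> FittedSignature:
    """The published 14-pair / 22-gene prognostic signature with its 0.184 cutoff."""
    payload = json.loads(
        resources.files("irgp.data").joinpath("published_signature.json").read_text()
    )
    return FittedSignature(
        pairs=tuple((p[0], p[1]) for p in payload["pairs"]),
        coefficients=tuple(payload["coefficients"]),
        cutoff=payload["cutoff"],
        meta=payload["meta"],
    )


def write_model(sig: FittedSignature, path: str | Path) -> None:
    """Serialize a signature to JSON (full coefficient precision)."""
    payload = {
        "pairs": [list(p) for p in sig.pairs],
        "coefficients": list(sig.coefficients),
        "cutoff": sig.cutoff,
        "meta": dict(sig.meta),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_model(path: str | Path) -> FittedSignature:
    """Read a signature written by :func:`write_model`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model file {path}: {exc}") from exc
    for key in ("pairs", "coefficients"):
        if key not in payload:
            raise ValueError(f"model file {path} lacks field {key!r}")
    return FittedSignature(
        pairs=tuple((p[0], p[1]) for p in payload["pairs"]),
        coefficients=tuple(payload["coefficients"]),
        cutoff=payload.get("cutoff"),
        meta=payload.get("meta", {}),
    )
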