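"""Readers, writers and validation for the tabular formats used throughout.

Four on-disk formats are supported:

* **Beta matrix** — delimited text, probes as rows, samples as columns,
  header ``probe_id,<sample>...``.  Values are methylation fractions in
  ``[0, 1]``; blank cells or ``NA`` denote missing.
* **Weight model** — CSV with header ``probe,weight`` and one reserved
  ``(Intercept)`` row.  Optional ``#calibration:`` header lines carry
  clock calibration metadata (see :mod:`pacemeter.scores`).
* **Probe list** — plain text, one probe id per line, ``#`` comments.
* **Phenotype table** — CSV keyed by a ``sample_id`` column.

All identifiers are case-sensitive and matched exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTERCEPT_ID = "(Intercept)"
MISSING_TOKENS = ("", "NA")


class PacemeterError(Exception):
    """Base class for all package errors."""


class ParseError(PacemeterError):
    """A file could not be parsed (non-numeric cell, missing header...)."""


class ValidationError(PacemeterError):
    """Parsed data violate a structural invariant (range, uniqueness...)."""


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    ``values`` is a DataFrame indexed by probe id with one column per
    sample.  Non-missing entries must lie in [0, 1]; NaN marks missing.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis(index="probe_id", columns=None)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0.0) | (arr > 1.0)
        if np.any(bad & ~np.isnan(arr)):
            r, c = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValidationError(
                f"beta value {arr[r, c]} outside [0, 1] at probe "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class WeightModel:
    """Linear scoring model: ``score = intercept + sum_c weight_c * beta_c``."""

    intercept: float
    weights: pd.Series  # indexed by probe id
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = pd.Series(self.weights, dtype=float)
        if self.weights.index.has_duplicates:
            raise ValidationError("duplicate probe ids in weight model")
        if not np.isfinite(self.intercept):
            raise ValidationError("non-finite intercept")
        if not np.all(np.isfinite(self.weights.to_numpy())):
            raise ValidationError("non-finite weights")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def n_probes(self) -> int:
        return len(self.weights)


@dataclass
class ProbeList:
    probe_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.probe_ids) == 0:
            raise ValidationError("probe list is empty")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate ids in probe list")

    def __len__(self) -> int:
        return len(self.probe_ids)

    def __iter__(self):
        return iter(self.probe_ids)


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_beta_matrix(
    path: str | Path, delimiter: str | None = None, transpose: bool = False
) -> BetaMatrix:
    """Read a delimited beta matrix (probes as rows unless ``transpose``).

    Blank cells and ``NA`` are read as missing.  Raises :class:`ParseError`
    for non-numeric cells (naming the offending row and column) and
    :class:`ValidationError` for out-of-range values or duplicate ids.
    """
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        dtype=str,
        keep_default_na=False,
        comment=None,
    )
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col].str.strip()
        missing = raw.isin(MISSING_TOKENS)
        parsed = pd.to_numeric(raw.where(~missing), errors="coerce")
        bad = parsed.isna() & ~missing
        if bad.any():
            probe = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric value {raw[bad].iloc[0]!r} at probe {probe!r}, "
                f"sample {col!r} in {path}"
            )
        # exact (correctly rounded) conversion, so write/read is bit-stable
        out[col] = [np.nan if m else float(v) for v, m in zip(raw, missing)]
    if transpose:
        out = out.T
    return BetaMatrix(out)


def write_beta_matrix(beta: BetaMatrix, path: str | Path, delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    # %.17g guarantees bit-exact float64 read-back
    beta.values.to_csv(path, sep=sep, na_rep="NA", float_format="%.17g")


def read_weight_model(path: str | Path) -> WeightModel:
    """Read a ``probe,weight`` CSV with one ``(Intercept)`` row.

    Lines starting with ``#`` are treated as comments; lines of the form
    ``#calibration: key=value ...`` are collected into ``meta['calibration']``.
    """
    calibration: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#calibration:"):
                for tok in line[len("#calibration:") :].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        calibration[k] = v
                continue
            if line.startswith("#") or not line.strip():
                continue
            rows.append(line)
    if not rows:
        raise ParseError(f"empty weight file: {path}")
    header = [h.strip() for h in rows[0].split(",")]
    if header[:2] != ["probe", "weight"]:
        raise ParseError(f"expected header 'probe,weight' in {path}, got {rows[0]!r}")
    probes: list[str] = []
    weights: list[float] = []
    intercept: float | None = None
    for line in rows[1:]:
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 2:
            raise ParseError(f"malformed row {line!r} in {path}")
        pid, w = parts[0], parts[1]
        try:
            val = float(w)
        except ValueError as exc:
            raise ParseError(f"non-numeric weight {w!r} for probe {pid!r} in {path}") from exc
        if pid == INTERCEPT_ID:
            if intercept is not None:
                raise ValidationError(f"duplicate intercept row in {path}")
            intercept = val
        else:
            probes.append(pid)
            weights.append(val)
    if intercept is None:
        raise ValidationError(f"weight file {path} has no '{INTERCEPT_ID}' row")
    if len(set(probes)) != len(probes):
        raise ValidationError(f"duplicate probe rows in {path}")
    meta: dict = {"source": str(path)}
    if calibration:
        meta["calibration"] = calibration
    return WeightModel(intercept, pd.Series(weights, index=probes), meta)


def write_weight_model(model: WeightModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        cal = model.meta.get("calibration")
        if cal:
            fh.write("#calibration: " + " ".join(f"{k}={v}" for k, v in cal.items()) + "\n")
        fh.write("probe,weight\n")
        fh.write(f"{INTERCEPT_ID},{model.intercept!r}\n")
        for pid, w in model.weights.items():
            fh.write(f"{pid},{w!r}\n")


def read_probe_list(path: str | Path) -> ProbeList:
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(line)
    return ProbeList(ids)


def write_probe_list(probes: ProbeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in probes:
            fh.write(pid + "\n")


def read_phenotypes(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a phenotype table keyed by ``sample_id``."""
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ParseError(f"phenotype table {path} lacks a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"duplicate sample_id in {path}")
    df = df.set_index("sample_id")
    if "age" in df.columns and (df["age"].dropna() < 0).any():
        raise ValidationError(f"negative ages in {path}")
    return df


def harmonize_probes(beta: BetaMatrix, keep: ProbeList) -> BetaMatrix:
    """Restrict ``beta`` to the probes in ``keep``, in ``keep``'s order.

    Probes of ``keep`` absent from ``beta`` are skipped (count logged).
    Raises :class:`ValidationError` on an empty intersection.
    """
    present = [p for p in keep if p in beta.values.index]
    if not present:
        raise ValidationError("no probes of the keep-list are present in the beta matrix")
    n_absent = len(keep) - len(present)
    n_dropped = beta.n_probes - len(present)
    if n_absent or n_dropped:
        logger.info(
            "harmonize_probes: kept %d probes, dropped %d from matrix, %d of keep-list absent",
            len(present), n_dropped, n_absent,
        )
    return BetaMatrix(beta.values.loc[present])
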