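"""TSV readers/writers and run configuration.

All interchange is plain TSV: samples as rows, features as columns, first
column the sample ID.  Writers emit a canonical numeric format so that
write -> read -> write round-trips byte-identically.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GroundTruthLedger

log = logging.getLogger("gutlipid")

_FLOAT_FORMAT = "%.10g"

REQUIRED_METADATA_COLUMNS = ("subject", "timepoint", "group")


class TableFormatError(ValueError):
    """Raised for malformed input tables, with row/column context."""


def read_feature_table(path, transpose: bool = False) -> pd.DataFrame:
    """Read a samples x features TSV (first column sample ID, numeric body).

    Duplicated sample IDs, non-numeric cells and ragged rows raise
    :class:`TableFormatError` naming the offender.  ``transpose`` accepts
    files stored features-as-rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise TableFormatError(f"{path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise TableFormatError(f"{path}: duplicated sample IDs: {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TableFormatError(
            f"{path}: non-numeric cell {df.iat[i, j]!r} at row {df.index[i]!r} "
            f"(line {i + 2}), column {df.columns[j]!r}"
        )
    numeric.index.name = df.index.name or "sample_id"
    return numeric.T if transpose else numeric


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table in canonical TSV format."""
    out = table.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FORMAT)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample sheet (sample_id, subject, timepoint, group)."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise TableFormatError(f"{path}: missing metadata columns {missing}")
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()].unique().tolist()
        raise TableFormatError(f"{path}: duplicated sample IDs: {dup}")
    pairs = meta[["subject", "timepoint"]].apply(tuple, axis=1)
    if pairs.duplicated().any():
        raise TableFormatError(f"{path}: duplicated (subject, timepoint) pairs")
    meta["timepoint"] = meta["timepoint"].astype(int)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t")


def check_tables_match(table: pd.DataFrame, meta: pd.DataFrame, name: str = "table") -> None:
    """Every sample in the data table must have metadata."""
    missing = table.index.difference(meta.index)
    if len(missing):
        raise TableFormatError(
            f"{name}: {len(missing)} samples lack metadata, e.g. {list(missing[:3])}"
        )


def write_ledger(ledger: GroundTruthLedger, path) -> None:
    Path(path).write_text(ledger.to_json() + "\n")


def read_ledger(path) -> GroundTruthLedger:
    return GroundTruthLedger.from_json(Path(path).read_text())


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    abundance: str | None = None
    lipids: str | None = None
    metadata: str | None = None
    panel: str | None = None
    out_dir: str = "gutlipid_out"
    r_min: float = 0.5
    q_max: float = 0.05
    long_chain_threshold: int = 54
    power_fold_change: float = 2.0
    power_sample_sizes: tuple[int, ...] = (4, 6, 8)
    power_reps: int = 200
    plaid_max_layers: int = 5
    plaid_n_shuffles: int = 39
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [0, 1]")
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must lie in (0, 1]")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")


def read_config(path) -> RunConfig:
    """Read a flat ``key = value`` configuration file."""
    values = {}
    known = {f.name: f for f in dataclasses.fields(RunConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise TableFormatError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise TableFormatError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = _coerce(known[key].type, value)
    return RunConfig(**values)


def _coerce(annotation, value: str):
    ann = str(annotation)
    if "tuple" in ann:
        return tuple(int(v) for v in value.replace(",", " ").split())
    if "int" in ann:
        return int(value)
    if "float" in ann:
        return float(value)
    return value


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
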