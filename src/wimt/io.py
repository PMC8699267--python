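"""Tabular I/O for MS1 feature tables, peptide identifications and references.

All interchange is plain TSV with fixed headers:

``features.tsv``
    run_id, feature_id, mz, rt_min, charge, intensity, snr
``ids.tsv``
    run_id, psm_id, peptide, charge, mz, rt_min, proteins, qvalue
    (``proteins`` is a ``;``-separated accession list, order-preserving)
``reference.tsv``
    accession, intensity

Retention times are minutes, m/z in Thomson, intensities linear-scale;
log transforms happen only inside computations. Parsers validate every row
and fail as a whole file with the offending row numbers -- rows are never
silently dropped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

__all__ = [
    "DepletionLevel",
    "TransferConfig",
    "TableFormatError",
    "FEATURE_COLUMNS",
    "ID_COLUMNS",
    "read_feature_table",
    "write_feature_table",
    "read_id_table",
    "write_id_table",
    "load_reference_intensities",
    "ReferenceIntensities",
]

FEATURE_COLUMNS = ("run_id", "feature_id", "mz", "rt_min", "charge", "intensity", "snr")
ID_COLUMNS = ("run_id", "psm_id", "peptide", "charge", "mz", "rt_min", "proteins", "qvalue")

#: float format used when writing -- round-trips cleanly at >=10 significant digits
_FLOAT_FMT = "%.10g"


class TableFormatError(ValueError):
    """A table violated its schema; carries 1-based data-row numbers."""

    def __init__(self, path, problems: list[str]):
        self.path = path
        self.problems = list(problems)
        msg = f"{path}: {len(self.problems)} invalid row(s)/column(s):\n  " + "\n  ".join(
            self.problems[:50]
        )
        super().__init__(msg)


class DepletionLevel(enum.IntEnum):
    """Degree of immunodepletion of a plasma run.

    Undepleted plasma is level 1; top-7 and top-14 antibody depletion are
    levels 2 and 3; SuperMix (removing ~50-60 abundant species) is level 4.
    """

    UNDEPLETED = 1
    LOW_DEP = 2
    MID_DEP = 3
    DEEP_DEP = 4


_AUTO = "auto"


@dataclass
class TransferConfig:
    """Parameters of the MS1-transfer workflow.

    Alignment uses ``max_rt_shift`` (minutes) and ``align_ppm``; feature
    linking uses ``link_rt_tol``/``link_ppm`` where the string ``"auto"``
    means the 95th percentile of post-alignment anchor residuals (with a
    floor of 5 ppm / 0.2 min). ``min_snr`` gates which features may anchor
    an alignment or seed a consensus.
    """

    max_rt_shift: float = 3.0
    align_ppm: float = 10.0
    link_rt_tol: Union[float, str] = _AUTO
    link_ppm: Union[float, str] = _AUTO
    min_snr: float = 5.0
    fdr_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("max_rt_shift", "align_ppm", "min_snr"):
            if float(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("link_rt_tol", "link_ppm"):
            v = getattr(self, name)
            if v != _AUTO and float(v) <= 0:
                raise ValueError(f"{name} must be > 0 or 'auto'")
        if not 0.0 < float(self.fdr_threshold) < 1.0:
            raise ValueError("fdr_threshold must be in (0, 1)")

    @classmethod
    def from_file(cls, path) -> "TransferConfig":
        """Read a flat ``key = value`` config file; unknown keys are an error."""
        known = {f.name: f for f in fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            if key == "seed":
                kwargs[key] = int(value)
            elif key in ("link_rt_tol", "link_ppm") and value == _AUTO:
                kwargs[key] = _AUTO
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    def with_seed(self, seed: int) -> "TransferConfig":
        return replace(self, seed=int(seed))


def _read_tsv(path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    problems = []
    missing = [c for c in columns if c not in df.columns]
    extra = [c for c in df.columns if c not in columns]
    if missing:
        problems.append(f"missing column(s): {missing}")
    if extra:
        problems.append(f"unexpected column(s): {extra}")
    if problems:
        raise TableFormatError(path, problems)
    return df[list(columns)]


def _numeric(df, col, problems, kind=float):
    out = pd.to_numeric(df[col], errors="coerce")
    for row in df.index[out.isna()] + 1:
        problems.append(f"row {row}: non-numeric {col} {df[col].iloc[row - 1]!r}")
    if kind is int:
        bad = out.notna() & (out != out.round())
        for row in df.index[bad] + 1:
            problems.append(f"row {row}: {col} is not an integer")
    return out


def read_feature_table(path) -> pd.DataFrame:
    """Read and validate a per-run MS1 feature table.

    Returns a DataFrame with columns :data:`FEATURE_COLUMNS`. Any invariant
    violation (non-positive m/z or intensity, negative RT or S/N, charge < 1,
    duplicate ``(run_id, feature_id)``) rejects the whole file with row
    numbers, so bad rows are never silently dropped.
    """
    df = _read_tsv(path, FEATURE_COLUMNS)
    problems: list[str] = []
    mz = _numeric(df, "mz", problems)
    rt = _numeric(df, "rt_min", problems)
    charge = _numeric(df, "charge", problems, int)
    intensity = _numeric(df, "intensity", problems)
    snr = _numeric(df, "snr", problems)
    for row in df.index[mz <= 0] + 1:
        problems.append(f"row {row}: mz must be > 0")
    for row in df.index[rt < 0] + 1:
        problems.append(f"row {row}: rt_min must be >= 0")
    for row in df.index[charge < 1] + 1:
        problems.append(f"row {row}: charge must be >= 1")
    for row in df.index[intensity <= 0] + 1:
        problems.append(f"row {row}: intensity must be > 0")
    for row in df.index[snr < 0] + 1:
        problems.append(f"row {row}: snr must be >= 0")
    dup = df.duplicated(subset=["run_id", "feature_id"], keep=False)
    for row in df.index[dup] + 1:
        problems.append(f"row {row}: duplicate (run_id, feature_id)")
    if problems:
        raise TableFormatError(path, problems)
    out = df.copy()
    out["mz"], out["rt_min"] = mz.astype(float), rt.astype(float)
    out["charge"] = charge.astype(int)
    out["intensity"], out["snr"] = intensity.astype(float), snr.astype(float)
    return out


def write_feature_table(df: pd.DataFrame, path) -> None:
    df = df[list(FEATURE_COLUMNS)]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_id_table(path) -> pd.DataFrame:
    """Read a peptide-identification table.

    The ``proteins`` column is split on ``;`` into an order-preserving tuple
    of accessions; an empty accession list or a q-value outside [0, 1] is a
    whole-file error.
    """
    df = _read_tsv(path, ID_COLUMNS)
    problems: list[str] = []
    _numeric(df, "mz", problems)
    _numeric(df, "rt_min", problems)
    charge = _numeric(df, "charge", problems, int)
    qvalue = _numeric(df, "qvalue", problems)
    for row in df.index[(qvalue < 0) | (qvalue > 1)] + 1:
        problems.append(f"row {row}: qvalue {qvalue.iloc[row - 1]} outside [0, 1]")
    proteins = []
    for i, cell in enumerate(df["proteins"]):
        accs = tuple(a for a in str(cell).split(";") if a)
        if not accs:
            problems.append(f"row {i + 1}: empty proteins field")
        proteins.append(accs)
    dup = df.duplicated(subset=["run_id", "psm_id"], keep=False)
    for row in df.index[dup] + 1:
        problems.append(f"row {row}: duplicate (run_id, psm_id)")
    if problems:
        raise TableFormatError(path, problems)
    out = df.copy()
    out["mz"] = pd.to_numeric(out["mz"]).astype(float)
    out["rt_min"] = pd.to_numeric(out["rt_min"]).astype(float)
    out["charge"] = charge.astype(int)
    out["qvalue"] = qvalue.astype(float)
    out["proteins"] = proteins
    return out


def write_id_table(df: pd.DataFrame, path) -> None:
    out = df[list(ID_COLUMNS)].copy()
    out["proteins"] = [
        ";".join(p) if not isinstance(p, str) else p for p in out["proteins"]
    ]
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


@dataclass(frozen=True)
class ReferenceIntensities:
    """Known plasma proteins with sorted log2 reference intensities."""

    log2_intensities: np.ndarray
    accessions: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        arr = np.asarray(self.log2_intensities, dtype=float)
        object.__setattr__(self, "log2_intensities", np.sort(arr))


def load_reference_intensities(path) -> ReferenceIntensities:
    """Load ``accession<TAB>intensity`` reference of known plasma proteins.

    Duplicate accessions collapse to their maximum intensity; the result
    carries ascending log2 intensities plus the accession set.
    """
    df = _read_tsv(path, ("accession", "intensity"))
    if len(df) == 0:
        raise TableFormatError(path, ["empty reference file"])
    problems: list[str] = []
    intensity = _numeric(df, "intensity", problems)
    for row in df.index[intensity <= 0] + 1:
        problems.append(f"row {row}: intensity must be > 0")
    if problems:
        raise TableFormatError(path, problems)
    collapsed = intensity.groupby(df["accession"]).max()
    return ReferenceIntensities(
        log2_intensities=np.log2(collapsed.to_numpy()),
        accessions=frozenset(collapsed.index),
    )


def concat_tables(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    return pd.concat(list(tables), ignore_index=True)
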