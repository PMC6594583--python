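"""Reading and writing electrogram exports and per-signal feature tables.

Signal exports use an open, documented text dialect (EP recording systems
export proprietary layouts; each lab maps its export to this dialect once):

* tab-separated values, UTF-8;
* comment lines starting ``#`` hold ``key=value`` metadata, including
  ``sample_rate_hz``;
* one header row naming the channels: ``time_ms``, ``abl_distal_mv``
  (distal ablation bipole), ``lead_i_mv`` (surface ECG lead I).

Feature tables are one row per ablation signal (CSV/TSV/XLSX) with an
outcome label, optional covariates, and optional feature columns named after
the quantities in :class:`~egmscore.features.SignalFeatures`.
"""

from __future__ import annotations

import io as _stdio
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ChannelMissingError,
    FormatError,
    SamplingError,
    SchemaError,
    ValidationError,
)
from .features import SUCCESSFUL, UNSUCCESSFUL, SignalFeatures

FEATURE_COLUMNS: list[str] = SignalFeatures.field_names()
COVARIATE_COLUMNS: list[str] = [
    "gender",
    "ap_side",
    "ap_location",
    "chd",
    "catheter_type",
    "energy",
    "approach",
    "atrial_paced",
    "lesions_in_case",
]
ID_COLUMNS: list[str] = ["signal_id", "patient_id", "outcome"]
SCHEMA_COLUMNS: list[str] = ID_COLUMNS + COVARIATE_COLUMNS + FEATURE_COLUMNS

_OUTCOME_ALIASES = {
    "successful": SUCCESSFUL, "success": SUCCESSFUL, "1": SUCCESSFUL,
    "true": SUCCESSFUL, "yes": SUCCESSFUL,
    "unsuccessful": UNSUCCESSFUL, "failure": UNSUCCESSFUL, "failed": UNSUCCESSFUL,
    "0": UNSUCCESSFUL, "false": UNSUCCESSFUL, "no": UNSUCCESSFUL,
}


# ---------------------------------------------------------------------------
# electrogram recordings


@dataclass
class ElectrogramRecording:
    """One exported beat: distal ablation bipole + surface lead I.

    ``time`` is in ms since export start and must be uniformly spaced at
    ``1000 / sample_rate``; amplitudes are in mV.
    """

    sample_rate: float
    time: np.ndarray
    abl_distal: np.ndarray
    lead_i: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.abl_distal = np.asarray(self.abl_distal, dtype=float)
        self.lead_i = np.asarray(self.lead_i, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        n = len(self.time)
        if n < 2 or len(self.abl_distal) != n or len(self.lead_i) != n:
            raise ValidationError(
                "all channels must share the same length >= 2"
            )
        step = 1000.0 / self.sample_rate
        diffs = np.diff(self.time)
        if diffs.min() <= 0:
            raise SamplingError("time axis must be strictly increasing")
        if not np.allclose(diffs, step, rtol=1e-6, atol=1e-9):
            raise SamplingError(
                f"time axis is not uniform at {step} ms "
                f"(declared rate {self.sample_rate} Hz)"
            )

    @property
    def duration_ms(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class ExportDialect:
    """How to interpret a signal-export text file.

    ``columns`` maps the three channel roles (``time``, ``abl_distal``,
    ``lead_i``) to column names in the file; ``time_scale``/``amp_scale``
    convert the file's units to ms and mV; the sample rate is taken from the
    metadata key ``sample_rate_key`` unless a constant ``sample_rate_hz`` is
    given.
    """

    delimiter: str = "\t"
    comment: str = "#"
    columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "time": "time_ms",
            "abl_distal": "abl_distal_mv",
            "lead_i": "lead_i_mv",
        }
    )
    sample_rate_key: str = "sample_rate_hz"
    sample_rate_hz: float | None = None
    time_scale: float = 1.0
    amp_scale: float = 1.0


DEFAULT_DIALECT = ExportDialect()


def read_signal_export(
    path: str | Path, dialect: ExportDialect = DEFAULT_DIALECT
) -> ElectrogramRecording:
    """Read one electrogram export into a validated recording.

    Raises :class:`FormatError` for an empty or malformed file,
    :class:`ChannelMissingError` naming any absent channel, and
    :class:`SamplingError` if the time axis disagrees with the declared
    sample rate by more than 0.1%.
    """
    path = Path(path)
    text = path.read_text()
    meta: dict[str, Any] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith(dialect.comment):
            stripped = line.lstrip(dialect.comment).strip()
            if "=" in stripped:
                key, _, value = stripped.partition("=")
                meta[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no data rows")
    try:
        df = pd.read_csv(_stdio.StringIO("\n".join(body_lines)),
                         sep=dialect.delimiter)
    except Exception as exc:  # malformed table
        raise FormatError(f"{path}: cannot parse table: {exc}") from exc
    for role, col in dialect.columns.items():
        if col not in df.columns:
            raise ChannelMissingError(
                f"{path}: required channel column {col!r} ({role}) is missing"
            )
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 samples")

    if dialect.sample_rate_hz is not None:
        fs = float(dialect.sample_rate_hz)
    elif dialect.sample_rate_key in meta:
        fs = float(meta[dialect.sample_rate_key])
    else:
        raise FormatError(
            f"{path}: no sample rate (metadata key "
            f"{dialect.sample_rate_key!r} absent)"
        )

    time = df[dialect.columns["time"]].to_numpy(float) * dialect.time_scale
    diffs = np.diff(time)
    if diffs.min() <= 0:
        raise SamplingError(f"{path}: time axis not strictly increasing")
    fs_reconstructed = 1000.0 / float(np.median(diffs))
    if abs(fs_reconstructed - fs) > 1e-3 * fs:
        raise SamplingError(
            f"{path}: reconstructed sample rate {fs_reconstructed:.3f} Hz "
            f"differs from declared {fs} Hz by more than 0.1%"
        )
    return ElectrogramRecording(
        sample_rate=fs,
        time=time,
        abl_distal=df[dialect.columns["abl_distal"]].to_numpy(float)
        * dialect.amp_scale,
        lead_i=df[dialect.columns["lead_i"]].to_numpy(float) * dialect.amp_scale,
        meta=meta,
    )


def write_signal_export(
    recording: ElectrogramRecording,
    path: str | Path,
    dialect: ExportDialect = DEFAULT_DIALECT,
) -> None:
    """Write a recording in the open export dialect (round-trips exactly)."""
    if len(recording.time) == 0:
        raise ValidationError("cannot write a zero-length recording")
    path = Path(path)
    cols = dialect.columns
    lines = [f"{dialect.comment} {dialect.sample_rate_key}={recording.sample_rate:.12g}"]
    for key, value in recording.meta.items():
        if key != dialect.sample_rate_key:
            lines.append(f"{dialect.comment} {key}={value}")
    lines.append(dialect.delimiter.join(
        [cols["time"], cols["abl_distal"], cols["lead_i"]]
    ))
    for t, a, l in zip(recording.time, recording.abl_distal, recording.lead_i):
        lines.append(dialect.delimiter.join(
            f"{v:.12g}" for v in (t, a, l)
        ))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# per-signal records


@dataclass
class SignalRecord:
    """One ablation signal: outcome, covariates and (optionally) features."""

    signal_id: str
    patient_id: str
    outcome: str
    features: SignalFeatures | None = None
    gender: str | None = None
    ap_side: str | None = None
    ap_location: str | None = None
    chd: bool | None = None
    catheter_type: str | None = None
    energy: str | None = None
    approach: str | None = None
    atrial_paced: bool | None = None
    lesions_in_case: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome not in (SUCCESSFUL, UNSUCCESSFUL):
            raise ValidationError(
                f"outcome must be {SUCCESSFUL!r} or {UNSUCCESSFUL!r}, "
                f"got {self.outcome!r}"
            )
        if not str(self.patient_id):
            raise ValidationError("patient_id must be present")
        if self.lesions_in_case is not None and self.lesions_in_case < 1:
            raise ValidationError("lesions_in_case must be >= 1")

    @property
    def successful(self) -> bool:
        return self.outcome == SUCCESSFUL

    @property
    def composite_score(self) -> float | None:
        return None if self.features is None else self.features.composite_score


def _parse_outcome(value: Any) -> str:
    key = str(value).strip().lower()
    if key in _OUTCOME_ALIASES:
        return _OUTCOME_ALIASES[key]
    raise SchemaError(f"outcome value {value!r} is not binary")


def _parse_bool(value: Any) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    key = str(value).strip().lower()
    if key in ("true", "1", "yes"):
        return True
    if key in ("false", "0", "no"):
        return False
    raise SchemaError(f"cannot interpret {value!r} as a boolean flag")


def _load_alias_map(alias_map: Mapping[str, str] | str | Path | None) -> dict:
    if alias_map is None:
        return {}
    if isinstance(alias_map, (str, Path)):
        data = yaml.safe_load(Path(alias_map).read_text())
        if not isinstance(data, dict):
            raise SchemaError("alias map file must contain a mapping")
        return {str(k): str(v) for k, v in data.items()}
    return dict(alias_map)


def _read_table(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "\t" if suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_feature_table(
    path: str | Path,
    alias_map: Mapping[str, str] | str | Path | None = None,
) -> list[SignalRecord]:
    """Read a per-signal feature table into :class:`SignalRecord` objects.

    ``alias_map`` renames foreign column headers to the package schema
    (either a mapping or a YAML file of ``their_name: schema_name`` pairs).
    Unknown columns are preserved per-record in ``meta``; row order is
    preserved.  Raises :class:`SchemaError` when the outcome column is
    absent or non-binary and :class:`ValidationError` on duplicate signal
    ids.
    """
    path = Path(path)
    df = _read_table(path).rename(columns=_load_alias_map(alias_map))
    if "outcome" not in df.columns:
        raise SchemaError(f"{path}: outcome column is missing")
    if "patient_id" not in df.columns:
        raise SchemaError(f"{path}: patient_id column is missing")
    if len(df) == 0:
        return []
    distinct = df["outcome"].dropna().astype(str).str.strip().str.lower().unique()
    mapped = {_OUTCOME_ALIASES.get(v) for v in distinct}
    if None in mapped or len(distinct) > 2:
        raise SchemaError(
            f"{path}: outcome column is not binary (values {sorted(distinct)})"
        )

    if "signal_id" in df.columns:
        dup = df["signal_id"][df["signal_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"{path}: duplicate signal_id values: "
                f"{sorted(set(dup.astype(str)))[:5]}"
            )

    extra_cols = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    records = []
    for i, row in df.iterrows():
        def _get(col: str) -> Any:
            if col not in df.columns:
                return None
            value = row[col]
            if isinstance(value, float) and math.isnan(value):
                return None
            return value

        features = None
        if _get("composite_score") is not None:
            features = SignalFeatures(**{
                name: float(row[name]) if _get(name) is not None else math.nan
                for name in FEATURE_COLUMNS
            })
        lesions = _get("lesions_in_case")
        records.append(SignalRecord(
            signal_id=str(_get("signal_id") if _get("signal_id") is not None else i),
            patient_id=str(_get("patient_id")),
            outcome=_parse_outcome(row["outcome"]),
            features=features,
            gender=_get("gender"),
            ap_side=_get("ap_side"),
            ap_location=_get("ap_location"),
            chd=_parse_bool(_get("chd")),
            catheter_type=_get("catheter_type"),
            energy=_get("energy"),
            approach=_get("approach"),
            atrial_paced=_parse_bool(_get("atrial_paced")),
            lesions_in_case=int(lesions) if lesions is not None else None,
            meta={c: row[c] for c in extra_cols if _get(c) is not None},
        ))
    return records


def records_to_frame(records: list[SignalRecord]) -> pd.DataFrame:
    """Tabular view of records (one row per signal, schema column order)."""
    rows = []
    meta_keys: list[str] = []
    for rec in records:
        row: dict[str, Any] = {
            "signal_id": rec.signal_id,
            "patient_id": rec.patient_id,
            "outcome": rec.outcome,
        }
        for col in COVARIATE_COLUMNS:
            row[col] = getattr(rec, col)
        if rec.features is not None:
            row.update(rec.features.to_dict())
        for key, value in rec.meta.items():
            row[key] = value
            if key not in meta_keys:
                meta_keys.append(key)
        rows.append(row)
    return pd.DataFrame(rows, columns=SCHEMA_COLUMNS + meta_keys)


def write_feature_table(
    records: list[SignalRecord], path: str | Path
) -> None:
    """Write records as a delimited table re-readable by
    :func:`read_feature_table` (lossless for all typed fields)."""
    path = Path(path)
    df = records_to_frame(records)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False)
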