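"""Reading, validating and writing long-call event annotation tables.

The canonical on-disk format is a plain CSV with columns
``file_id, call_id, section_id, kind, onset_s, duration_s`` where ``kind``
is ``pulse`` (voiced exhale) or ``pant`` (voiced inhale) and onsets are
absolute seconds within a recording.  Raven Pro selection tables
(tab-separated, ``Begin Time (s)`` / ``End Time (s)`` columns) are supported
read-only.  Archive dialects that ship pre-computed interval (t_k) or ratio
(r_k) tables rather than raw events are mapped through a small YAML column
mapping and returned as derived tables so downstream stages can start
mid-pipeline.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

KINDS = ("pulse", "pant")

CANONICAL_COLUMNS = ["file_id", "call_id", "section_id", "kind", "onset_s", "duration_s"]
_REQUIRED = ["file_id", "call_id", "kind", "onset_s", "duration_s"]

#: built-in column mappings for the archived derived-table dialects; the
#: deposit's headers are not standardized, so users may override these with
#: their own mapping file (``mapping_path=``).
DEFAULT_DIALECT_MAPPING: dict[str, dict[str, str]] = {
    "zenodo_tempo": {"file_id": "file", "section_id": "id", "tk_s": "tk", "tk_type": "type"},
    "zenodo_granger": {"file_id": "file", "section_id": "id", "kind": "type", "onset_s": "onset"},
    "zenodo_tk_rk": {"file_id": "file", "section_id": "id", "kind": "type", "tk_s": "tk", "rk": "rk"},
    "zenodo_rk_overall": {"file_id": "file", "call_id": "id", "tk_s": "tk", "rk": "rk"},
}

EVENT_DIALECTS = ("canonical_csv", "raven_selection")
DERIVED_DIALECTS = tuple(DEFAULT_DIALECT_MAPPING)


@dataclass
class EventTable:
    """Validated, sorted table of annotated vocal events.

    ``df`` columns: file_id, call_id, section_id, kind, onset_s, duration_s.
    ``flagged_calls`` lists (file_id, call_id) keys with fewer than two pulse
    events; such calls are kept, never silently dropped.
    """

    df: pd.DataFrame
    provenance: str = "memory"
    flagged_calls: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.df = _validate_events(self.df)
        self.flagged_calls = [
            key
            for key, grp in self.df.groupby(["file_id", "call_id"], sort=True)
            if (grp["kind"] == "pulse").sum() < 2
        ]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_exact=False)
        except AssertionError:
            return False
        return True

    @property
    def calls(self) -> list[tuple[str, str]]:
        return sorted(set(map(tuple, self.df[["file_id", "call_id"]].itertuples(index=False))))


@dataclass
class DerivedTable:
    """Pre-computed interval/ratio rows loaded from an archive dialect."""

    df: pd.DataFrame
    kind: str  # "intervals" or "ratios"
    provenance: str


def _validate_events(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    if "section_id" not in df.columns:
        df["section_id"] = ""
    df["section_id"] = df["section_id"].fillna("").astype(str)
    df["file_id"] = df["file_id"].astype(str)
    df["call_id"] = df["call_id"].astype(str)
    df["kind"] = df["kind"].astype(str).str.strip().str.lower()
    bad_kind = sorted(set(df["kind"]) - set(KINDS))
    if bad_kind:
        raise ValidationError(f"unknown kind label(s): {bad_kind}; expected one of {KINDS}")
    df["onset_s"] = pd.to_numeric(df["onset_s"])
    df["duration_s"] = pd.to_numeric(df["duration_s"])
    if (df["onset_s"] < 0).any():
        rows = df.index[df["onset_s"] < 0].tolist()
        raise ValidationError(f"negative onset_s at rows {rows}")
    if (df["duration_s"] <= 0).any():
        rows = df.index[df["duration_s"] <= 0].tolist()
        raise ValidationError(f"non-positive duration_s at rows {rows}")
    df = df.sort_values(["file_id", "call_id", "onset_s"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["file_id", "call_id", "onset_s"], keep=False)
    if dup.any():
        offending = df.loc[dup, ["file_id", "call_id", "onset_s"]].to_dict("records")
        raise ValidationError(f"tied onsets within a call are invalid: {offending}")
    return df[CANONICAL_COLUMNS]


def read_events(
    path: str | Path,
    dialect: str = "canonical_csv",
    *,
    mapping_path: str | Path | None = None,
    annotation_column: str | None = None,
) -> EventTable | DerivedTable:
    """Read an annotation file in the given dialect.

    Event-level dialects (``canonical_csv``, ``raven_selection``) return an
    :class:`EventTable`; archive dialects shipping pre-computed t_k/r_k rows
    return a :class:`DerivedTable` tagged with provenance.

    Parameters
    ----------
    annotation_column:
        For ``raven_selection``: name of the column holding the pulse/pant
        label.  Defaults to the first of ``Annotation``/``kind`` present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    provenance = f"{path}::{dialect}"

    if dialect == "canonical_csv":
        df = pd.read_csv(path, dtype={"file_id": str, "call_id": str, "section_id": str})
        return EventTable(df, provenance=provenance)

    if dialect == "raven_selection":
        df = pd.read_csv(path, sep="\t")
        for col in ("Begin Time (s)", "End Time (s)"):
            if col not in df.columns:
                raise SchemaError(f"missing required column(s): {col}")
        if annotation_column is None:
            candidates = [c for c in ("Annotation", "kind") if c in df.columns]
            if not candidates:
                raise SchemaError("missing required column(s): Annotation")
            annotation_column = candidates[0]
        elif annotation_column not in df.columns:
            raise SchemaError(f"missing required column(s): {annotation_column}")
        out = pd.DataFrame(
            {
                "file_id": df.get("Begin File", pd.Series([path.stem] * len(df))).astype(str),
                "call_id": df.get("call_id", pd.Series(["c1"] * len(df))).astype(str),
                "section_id": "",
                "kind": df[annotation_column],
                "onset_s": df["Begin Time (s)"],
                "duration_s": df["End Time (s)"] - df["Begin Time (s)"],
            }
        )
        return EventTable(out, provenance=provenance)

    if dialect in DERIVED_DIALECTS:
        mapping = dict(DEFAULT_DIALECT_MAPPING[dialect])
        if mapping_path is not None:
            user_map = yaml.safe_load(Path(mapping_path).read_text())
            mapping.update(user_map.get(dialect, user_map))
        raw = pd.read_csv(path)
        missing = [src for src in mapping.values() if src not in raw.columns]
        if missing:
            raise SchemaError(
                f"missing required column(s) for dialect {dialect}: {', '.join(missing)}"
            )
        df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
        if dialect == "zenodo_granger":
            # onsets of pulses/pants per section: event-level after all
            return EventTable(
                df.assign(call_id=df["section_id"], duration_s=0.1), provenance=provenance
            )
        kind = "ratios" if "rk" in df.columns else "intervals"
        return DerivedTable(df=df, kind=kind, provenance=provenance)

    raise ValueError(f"unknown dialect: {dialect!r}")


def write_events(table: EventTable, path: str | Path) -> Path:
    """Write an EventTable as canonical CSV; round-trips through read_events.

    Floats are written with repr-exact formatting so that writing the same
    table twice yields byte-identical files.
    """
    path = Path(path)
    buf = io.StringIO()
    table.df.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue())
    return path


def events_from_records(records: list[tuple], provenance: str = "memory") -> EventTable:
    """Build an EventTable from (file_id, call_id, kind, onset_s, duration_s) tuples."""
    df = pd.DataFrame(records, columns=_REQUIRED)
    return EventTable(df, provenance=provenance)


def warn_if_flagged(table: EventTable) -> None:
    if table.flagged_calls:
        warnings.warn(
            f"{len(table.flagged_calls)} call(s) have fewer than two pulses: "
            f"{table.flagged_calls[:5]}",
            stacklevel=2,
        )
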