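"""Interval (t_k) and ratio (r_k) computation, integer-ratio classification,
per-file bin tallies, and within-call positional densities.

The analysis runs at four levels of temporal organization:

``all_pulses``
    one onset sequence per call, pulses only (pants ignored);
``pulse_pant_series``
    one sequence per pulse/pant section — a maximal contiguous run of
    strictly alternating pulses and pants — using all onsets;
``pulses_within_series`` / ``pants_within_series``
    the pulse-only / pant-only onsets of each such section.

For an onset sequence o_1 < ... < o_n the inter-onset intervals are
t_k = o_{k+1} - o_k and the rhythm ratios r_k = t_k / (t_k + t_{k+1}).
r_k = 0.50 marks isochrony (1:1), 1/3 a 1:2 pattern and 2/3 a 2:1 pattern;
narrow "on-integer" windows around those values are contrasted with flanking
"off-integer" windows to test whether a rhythmic category is present.
Ratios are never chained across calls or sections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .events import EventTable


class AnalysisLevel(str, Enum):
    all_pulses = "all_pulses"
    pulse_pant_series = "pulse_pant_series"
    pulses_within_series = "pulses_within_series"
    pants_within_series = "pants_within_series"


LEVELS = tuple(AnalysisLevel)

#: default maximum silent gap (s) tolerated inside a pulse/pant section
DEFAULT_MAX_GAP_S = 5.0


@dataclass(frozen=True)
class RatioLabel:
    category: str  # iso_1_1 | half_1_2 | double_2_1 | none
    zone: str  # on | off | none

    def __post_init__(self):
        assert (self.category == "none") == (self.zone == "none")


_CATEGORY_OF_BIN = {
    "on1:1": ("iso_1_1", "on"),
    "off1:1": ("iso_1_1", "off"),
    "on1:2": ("half_1_2", "on"),
    "off1:2": ("half_1_2", "off"),
    "on2:1": ("double_2_1", "on"),
    "off2:1": ("double_2_1", "off"),
}

BIN_ORDER = ("off1:1", "on1:1", "off1:2", "on1:2", "off2:1", "on2:1")


@dataclass(frozen=True)
class BinScheme:
    """Half-open [lo, hi) on/off-integer windows around 1:2, 1:1 and 2:1.

    The on-window for 1:1 is [0.444, 0.555); its off-window is the union
    [0.400, 0.444) + [0.555, 0.600), and analogously for 1:2 (on
    [0.308, 0.364)) and 2:1 (on [0.636, 0.692)).  The six bins are pairwise
    disjoint and exactly cover [0.286, 0.714); ratios outside that range are
    left unbinned.
    """

    intervals: dict = field(
        default_factory=lambda: {
            "off1:2": ((0.286, 0.308), (0.364, 0.400)),
            "on1:2": ((0.308, 0.364),),
            "off1:1": ((0.400, 0.444), (0.555, 0.600)),
            "on1:1": ((0.444, 0.555),),
            "off2:1": ((0.600, 0.636), (0.692, 0.714)),
            "on2:1": ((0.636, 0.692),),
        }
    )

    def width_of(self, bin_name: str) -> float:
        return float(sum(hi - lo for lo, hi in self.intervals[bin_name]))

    def classify(self, r: float) -> RatioLabel:
        if not 0.0 < r < 1.0:
            raise ValidationError(f"ratio {r} outside the open interval (0, 1)")
        for name, spans in self.intervals.items():
            if any(lo <= r < hi for lo, hi in spans):
                cat, zone = _CATEGORY_OF_BIN[name]
                return RatioLabel(cat, zone)
        return RatioLabel("none", "none")

    def bin_of(self, r: float) -> str | None:
        """Bin name for a ratio, or None if unbinned."""
        if not 0.0 < r < 1.0:
            raise ValidationError(f"ratio {r} outside the open interval (0, 1)")
        for name, spans in self.intervals.items():
            if any(lo <= r < hi for lo, hi in spans):
                return name
        return None


def classify_ratio(r: float, scheme: BinScheme | None = None) -> RatioLabel:
    return (scheme or BinScheme()).classify(r)


@dataclass
class OnsetSeries:
    """One analysis-level onset sequence with its call context."""

    file_id: str
    call_id: str
    section_id: str
    level: AnalysisLevel
    onsets: np.ndarray
    call_start: float
    call_end: float


@dataclass
class IntervalSeries:
    file_id: str
    call_id: str
    section_id: str
    level: AnalysisLevel
    t_k: np.ndarray
    onsets: np.ndarray  # the n onsets generating the n-1 intervals
    call_start: float = 0.0
    call_end: float = 1.0
    flagged: bool = False  # fewer than 2 onsets -> empty series

    def __len__(self) -> int:
        return len(self.t_k)


@dataclass
class RatioSeries:
    file_id: str
    call_id: str
    section_id: str
    level: AnalysisLevel
    r_k: np.ndarray
    labels: list[RatioLabel]
    rel_pos: np.ndarray
    flagged: bool = False

    def __len__(self) -> int:
        return len(self.r_k)


def _sections(call_df: pd.DataFrame, max_gap_s: float) -> list[pd.DataFrame]:
    """Maximal runs of >=3 strictly alternating pulse/pant events with no
    inter-onset gap exceeding max_gap_s."""
    kinds = call_df["kind"].to_numpy()
    onsets = call_df["onset_s"].to_numpy()
    runs: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(call_df)):
        breaks = kinds[i] == kinds[i - 1] or (onsets[i] - onsets[i - 1]) > max_gap_s
        if breaks:
            runs.append((start, i))
            start = i
    runs.append((start, len(call_df)))
    return [call_df.iloc[a:b] for a, b in runs if b - a >= 3 and len(set(kinds[a:b])) == 2]


def build_series(
    events: EventTable,
    level: AnalysisLevel | str,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> list[OnsetSeries]:
    """Extract the onset sequences for one analysis level (one per call for
    ``all_pulses``, one per alternating pulse/pant section otherwise)."""
    level = AnalysisLevel(level)
    out: list[OnsetSeries] = []
    has_pants = (events.df["kind"] == "pant").any()
    if level is not AnalysisLevel.all_pulses and not has_pants:
        warnings.warn(f"no pant events: level {level.value} yields no series", stacklevel=2)
        return out
    for (file_id, call_id), call_df in events.df.groupby(["file_id", "call_id"], sort=True):
        call_start = float(call_df["onset_s"].iloc[0])
        call_end = float((call_df["onset_s"] + call_df["duration_s"]).iloc[-1])
        if level is AnalysisLevel.all_pulses:
            pulses = call_df.loc[call_df["kind"] == "pulse", "onset_s"].to_numpy(float)
            out.append(OnsetSeries(file_id, call_id, "", level, pulses, call_start, call_end))
            continue
        for idx, sec in enumerate(_sections(call_df, max_gap_s)):
            if level is AnalysisLevel.pulse_pant_series:
                sel = sec
            elif level is AnalysisLevel.pulses_within_series:
                sel = sec[sec["kind"] == "pulse"]
            else:
                sel = sec[sec["kind"] == "pant"]
            out.append(
                OnsetSeries(
                    file_id,
                    call_id,
                    f"{call_id}:s{idx}",
                    level,
                    sel["onset_s"].to_numpy(float),
                    call_start,
                    call_end,
                )
            )
    return out


def compute_tk(series: OnsetSeries | np.ndarray) -> IntervalSeries:
    """Inter-onset intervals t_k[i] = onsets[i+1] - onsets[i]."""
    if isinstance(series, OnsetSeries):
        onsets = np.asarray(series.onsets, float)
        meta = (series.file_id, series.call_id, series.section_id, series.level)
        span = (series.call_start, series.call_end)
    else:
        onsets = np.asarray(series, float)
        meta = ("", "", "", AnalysisLevel.all_pulses)
        span = (float(onsets[0]), float(onsets[-1])) if len(onsets) else (0.0, 1.0)
    if len(onsets) >= 2 and not np.all(np.diff(onsets) > 0):
        raise ValidationError("onsets must be strictly increasing")
    flagged = len(onsets) < 2
    t_k = np.diff(onsets) if not flagged else np.empty(0)
    return IntervalSeries(*meta, t_k=t_k, onsets=onsets, call_start=span[0], call_end=span[1], flagged=flagged)


def compute_rk(intervals: IntervalSeries, scheme: BinScheme | None = None) -> RatioSeries:
    """Rhythm ratios r_k[i] = t_k[i] / (t_k[i] + t_k[i+1]), classified.

    rel_pos[i] is the position of the ratio's first onset within its call,
    as a fraction of the call's duration.
    """
    scheme = scheme or BinScheme()
    t = np.asarray(intervals.t_k, float)
    if len(t) < 2:
        return RatioSeries(
            intervals.file_id,
            intervals.call_id,
            intervals.section_id,
            intervals.level,
            r_k=np.empty(0),
            labels=[],
            rel_pos=np.empty(0),
            flagged=True,
        )
    r = t[:-1] / (t[:-1] + t[1:])
    span = max(intervals.call_end - intervals.call_start, np.finfo(float).tiny)
    rel = (intervals.onsets[: len(r)] - intervals.call_start) / span
    labels = [scheme.classify(v) for v in r]
    return RatioSeries(
        intervals.file_id,
        intervals.call_id,
        intervals.section_id,
        intervals.level,
        r_k=r,
        labels=labels,
        rel_pos=np.clip(rel, 0.0, 1.0),
    )


def count_bins(
    ratios: list[RatioSeries],
    scheme: BinScheme | None = None,
    declared_files: list[str] | None = None,
) -> pd.DataFrame:
    """Per (file_id, level) tallies of ratios in each of the six bins.

    Returns exactly six rows per (file_id, level) with columns
    file_id, level, bin_name, count, bin_width, n_ratios_in_file; zero
    counts are retained (the count model is zero-inflated because zeros
    occur).  Ratios outside [0.286, 0.714) stay unbinned, so per file the
    counts sum to at most n_ratios_in_file.
    """
    scheme = scheme or BinScheme()
    tallies: dict[tuple[str, str], dict[str, int]] = {}
    totals: dict[tuple[str, str], int] = {}
    levels_seen: set[str] = set()
    for rs in ratios:
        key = (rs.file_id, AnalysisLevel(rs.level).value)
        levels_seen.add(key[1])
        cell = tallies.setdefault(key, {b: 0 for b in BIN_ORDER})
        totals[key] = totals.get(key, 0) + len(rs.r_k)
        for v in rs.r_k:
            b = scheme.bin_of(float(v))
            if b is not None:
                cell[b] += 1
    if declared_files:
        for f in declared_files:
            for lev in levels_seen or {AnalysisLevel.all_pulses.value}:
                tallies.setdefault((f, lev), {b: 0 for b in BIN_ORDER})
                totals.setdefault((f, lev), 0)
    rows = []
    for (file_id, lev), cell in sorted(tallies.items()):
        for b in BIN_ORDER:
            rows.append(
                {
                    "file_id": file_id,
                    "level": lev,
                    "bin_name": b,
                    "count": cell[b],
                    "bin_width": scheme.width_of(b),
                    "n_ratios_in_file": totals[(file_id, lev)],
                }
            )
    return pd.DataFrame(
        rows, columns=["file_id", "level", "bin_name", "count", "bin_width", "n_ratios_in_file"]
    )


def double_meter_share(bin_counts: pd.DataFrame, level: AnalysisLevel | str | None = None) -> dict:
    """Share of double meter (1:2 + 2:1) among on-integer ratios, pooled
    over files.

    Returns both denominator variants: ``share_on`` uses all on-integer
    counts (the primary statistic), ``share_classified`` uses all six bins.
    Undefined shares (zero denominator) are reported as NaN.
    """
    df = bin_counts
    if level is not None:
        df = df[df["level"] == AnalysisLevel(level).value]
    by_bin = df.groupby("bin_name")["count"].sum()
    on_total = sum(by_bin.get(b, 0) for b in ("on1:1", "on1:2", "on2:1"))
    all_total = int(by_bin.sum())
    double = by_bin.get("on1:2", 0) + by_bin.get("on2:1", 0)
    return {
        "share_on": float(double / on_total) if on_total else float("nan"),
        "share_classified": float(double / all_total) if all_total else float("nan"),
        "n_on": int(on_total),
        "n_classified": all_total,
    }


def category_position_density(
    ratios: list[RatioSeries],
    category: str,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of within-call positions of on-integer ratios
    of one rhythmic category, boundary-reflected so it integrates to 1 on
    [0, 1].

    bandwidth defaults to Silverman's rule; pass a float to override (same
    units as rel_pos).
    """
    pos = np.concatenate(
        [
            rs.rel_pos[[lab.category == category and lab.zone == "on" for lab in rs.labels]]
            for rs in ratios
        ]
        or [np.empty(0)]
    )
    if len(pos) < 2:
        raise ValidationError(
            f"need at least 2 on-integer ratios of category {category!r}, got {len(pos)}"
        )
    if grid is None:
        grid = np.linspace(0.0, 1.0, 201)
    if np.ptp(pos) == 0.0:
        # degenerate point mass: tiny fixed bandwidth around the atom
        bw = bandwidth or 1e-3
        kde = stats.norm(loc=pos[0], scale=bw)
        dens = kde.pdf(grid) + kde.pdf(-grid) + kde.pdf(2.0 - grid)
        return grid, dens
    kde = stats.gaussian_kde(pos, bw_method="silverman" if bandwidth is None else bandwidth / pos.std(ddof=1))
    dens = kde(grid) + kde(-grid) + kde(2.0 - grid)
    return grid, dens


def intervals_table(interval_series: list[IntervalSeries]) -> pd.DataFrame:
    """Tidy per-interval rows (intervals.csv layout)."""
    rows = []
    for s in interval_series:
        for k, t in enumerate(s.t_k):
            rows.append(
                {
                    "file_id": s.file_id,
                    "call_id": s.call_id,
                    "section_id": s.section_id,
                    "level": AnalysisLevel(s.level).value,
                    "k": k,
                    "t_k": float(t),
                }
            )
    return pd.DataFrame(rows, columns=["file_id", "call_id", "section_id", "level", "k", "t_k"])


def ratios_table(ratio_series: list[RatioSeries]) -> pd.DataFrame:
    """Tidy per-ratio rows (ratios.csv layout)."""
    rows = []
    for s in ratio_series:
        for k, (r, lab, pos) in enumerate(zip(s.r_k, s.labels, s.rel_pos)):
            rows.append(
                {
                    "file_id": s.file_id,
                    "call_id": s.call_id,
                    "section_id": s.section_id,
                    "level": AnalysisLevel(s.level).value,
                    "k": k,
                    "r_k": float(r),
                    "category": lab.category,
                    "zone": lab.zone,
                    "rel_pos": float(pos),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["file_id", "call_id", "section_id", "level", "k", "r_k", "category", "zone", "rel_pos"],
    )
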