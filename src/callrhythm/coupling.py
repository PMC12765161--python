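"""Pulse-pant synchrony and directionality.

For each pulse/pant section the pulse-derived and pant-derived series are
index-paired (truncated to the shorter one) and compared with

* a lagged sample cross-correlation (biased estimator, fixed full-series
  means and standard deviations, default max lag 20), and
* an order-1 Granger causality F-test in both directions, computed from
  nested OLS fits: restricted ``y_t ~ 1 + y_{t-1}`` versus unrestricted
  ``y_t ~ 1 + y_{t-1} + x_{t-1}``, F(1, n-4) for a paired length of n
  (the convention of R's ``grangertest`` with order 1).

Lag-sign convention: positive lag means x leads y, i.e. ``ccf[h]``
correlates x at index t with y at index t+h.  The default series mode is
``interval_durations`` (t_k sequences): raw onset times are monotone
trends whose cross-correlation is near 1 regardless of coupling, so
intervals are the scientifically meaningful default; an ``onset_times``
mode is provided for literal replication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import CouplingError

DEFAULT_MAX_LAG = 20
#: sections need at least this many paired points for the causality tally
MIN_GRANGER_OBS = 3


@dataclass
class CouplingSeriesPair:
    """Index-paired pulse-derived (x) and pant-derived (y) series."""

    section_id: str
    x: np.ndarray
    y: np.ndarray
    mode: str = "interval_durations"  # or "onset_times"

    def __post_init__(self):
        n = min(len(self.x), len(self.y))
        self.x = np.asarray(self.x, float)[:n]
        self.y = np.asarray(self.y, float)[:n]

    @property
    def n(self) -> int:
        return len(self.x)

    def swapped(self) -> "CouplingSeriesPair":
        return CouplingSeriesPair(self.section_id, self.y.copy(), self.x.copy(), self.mode)


@dataclass
class CouplingResult:
    section_id: str
    lags: np.ndarray
    ccf: np.ndarray
    best_lag: int
    best_ccf: float
    granger_xy_p: float  # does x (pulses) predict y (pants)?
    granger_yx_p: float
    n: int
    flags: list[str] = field(default_factory=list)


def cross_correlate(
    pair: CouplingSeriesPair, max_lag: int = DEFAULT_MAX_LAG
) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Sample cross-correlation r(h) for h in [-L, L], L = min(max_lag, n-1).

    r(h) = sum_t (x_t - xbar)(y_{t+h} - ybar) / (n * s_x * s_y) with the
    biased (divide-by-n) standard deviations; r(0) therefore equals the
    Pearson coefficient times (n-1)/n.  Returns (lags, ccf, best_lag,
    best_ccf) where best_lag maximizes r (ties broken toward lag 0).
    """
    x, y, n = pair.x, pair.y, pair.n
    if n < 2:
        raise CouplingError(f"section {pair.section_id}: need n >= 2, got {n}")
    L = min(max_lag, n - 1)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc**2))
    sy = np.sqrt(np.mean(yc**2))
    if sx == 0.0 or sy == 0.0:
        raise CouplingError(f"section {pair.section_id}: constant series, correlation undefined")
    lags = np.arange(-L, L + 1)
    ccf = np.empty(len(lags))
    for i, h in enumerate(lags):
        if h >= 0:
            s = np.dot(xc[: n - h], yc[h:])
        else:
            s = np.dot(xc[-h:], yc[: n + h])
        ccf[i] = s / (n * sx * sy)
    order = np.lexsort((np.abs(lags), -ccf))
    best = order[0]
    return lags, ccf, int(lags[best]), float(ccf[best])


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), int(rank)


def granger_order1(pair: CouplingSeriesPair) -> tuple[float, float]:
    """Order-1 Granger causality p-values (p_xy, p_yx).

    p_xy tests whether x at lag 1 improves prediction of y beyond y's own
    lag-1 history.  F(1, n-4); a paired length below 5 leaves no residual
    degrees of freedom and raises.  Collinear regressors yield NaN with a
    warning rather than a spurious p.
    """
    n = pair.n
    if n < 5:
        raise CouplingError(
            f"section {pair.section_id}: n = {n} leaves no residual df for the order-1 F test"
        )
    return _granger_one_direction(pair.x, pair.y), _granger_one_direction(pair.y, pair.x)


def _granger_one_direction(x: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    yt, ylag, xlag = y[1:], y[:-1], x[:-1]
    ones = np.ones(n - 1)
    rss_r, _ = _ols_rss(np.column_stack([ones, ylag]), yt)
    rss_u, rank = _ols_rss(np.column_stack([ones, ylag, xlag]), yt)
    df2 = n - 4
    if rank < 3:
        warnings.warn("collinear regressors in Granger test: p reported as NaN", stacklevel=3)
        return float("nan")
    if rss_u <= 0.0:
        return 0.0
    F = (rss_r - rss_u) / (rss_u / df2)
    return float(stats.f.sf(max(F, 0.0), 1, df2))


def analyze_pair(
    pair: CouplingSeriesPair, max_lag: int = DEFAULT_MAX_LAG
) -> CouplingResult:
    """Cross-correlation plus both Granger directions for one section."""
    flags: list[str] = []
    lags, ccf, best_lag, best_ccf = cross_correlate(pair, max_lag)
    try:
        p_xy, p_yx = granger_order1(pair)
    except CouplingError as exc:
        flags.append(str(exc))
        p_xy = p_yx = float("nan")
    return CouplingResult(
        section_id=pair.section_id,
        lags=lags,
        ccf=ccf,
        best_lag=best_lag,
        best_ccf=best_ccf,
        granger_xy_p=p_xy,
        granger_yx_p=p_yx,
        n=pair.n,
        flags=flags,
    )


def tally_causality(
    results: list[CouplingResult], alpha: float = 0.001
) -> tuple[int, int, int, int]:
    """(n_xy, n_yx, n_none, n_total) at significance alpha.

    A section counts in a direction when its p-value is below alpha;
    bi-directional sections count in both.  NaN p-values never count as
    significant.
    """
    n_xy = sum(1 for r in results if r.granger_xy_p < alpha)
    n_yx = sum(1 for r in results if r.granger_yx_p < alpha)
    n_none = sum(
        1
        for r in results
        if not (r.granger_xy_p < alpha) and not (r.granger_yx_p < alpha)
    )
    return n_xy, n_yx, n_none, len(results)


def pairs_from_sections(
    pulse_series: list, pant_series: list, mode: str = "interval_durations"
) -> list[CouplingSeriesPair]:
    """Build pulse/pant series pairs from the per-section onset sequences of
    the pulses-within-series and pants-within-series analysis levels."""
    if mode not in ("interval_durations", "onset_times"):
        raise ValueError(f"unknown mode {mode!r}")
    pants_by_key = {(s.file_id, s.section_id): s for s in pant_series}
    pairs = []
    for ps in pulse_series:
        key = (ps.file_id, ps.section_id)
        if key not in pants_by_key:
            continue
        qs = pants_by_key[key]
        if mode == "interval_durations":
            x, y = np.diff(ps.onsets), np.diff(qs.onsets)
        else:
            x, y = ps.onsets, qs.onsets
        pairs.append(CouplingSeriesPair(f"{ps.file_id}/{ps.section_id}", x, y, mode))
    return pairs
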