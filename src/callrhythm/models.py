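"""Count and tempo models for rhythmic-category testing.

Two model families are fitted:

* a zero-inflated Poisson mixed model for per-file bin counts: with
  probability pi an observation is a structural zero, otherwise it is
  Poisson with log-mean ``x'beta + log(bin width) + u_file`` where
  ``u_file ~ N(0, sigma_u^2)`` is a per-recording random intercept.  The
  marginal likelihood integrates the random intercept by adaptive
  Gauss-Hermite quadrature (Laplace approximation available as a fast
  path).  The six bin levels enter as cell means so that off-vs-on
  contrasts are plain coefficient differences.
* a Gaussian linear mixed model on log(t_k) with a three-level interval
  type factor (series / pants / pulses) and a per-section random
  intercept, fitted by maximum likelihood.

Both are tested full-versus-null with a likelihood-ratio chi-square, and
post-hoc pairwise contrasts are computed on the link scale from the
observed-information covariance.  No multiplicity adjustment is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import FitError

BIN_LEVELS = ("off1:1", "on1:1", "off1:2", "on1:2", "off2:1", "on2:1")
DEFAULT_COUNT_PAIRS = (("off1:1", "on1:1"), ("off1:2", "on1:2"), ("off2:1", "on2:1"))
TK_TYPES = ("series", "pants", "pulses")
DEFAULT_TEMPO_PAIRS = (("series", "pants"), ("series", "pulses"), ("pants", "pulses"))


@dataclass
class FitResult:
    """Maximum-likelihood fit summary shared by both model families."""

    model: str
    params: np.ndarray
    param_names: list[str]
    cov: np.ndarray  # observed-information covariance, full parameter vector
    loglik: float
    n_obs: int
    converged: bool
    message: str = ""
    df_resid: int | None = None  # tempo model only
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def coef(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def se(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(np.sqrt(self.cov[i, i]))

    @property
    def fixed_names(self) -> list[str]:
        return [n for n in self.param_names if not n.startswith(("zi_", "log_sigma", "re_", "log_resid"))]


@dataclass
class ContrastResult:
    pair: str
    estimate: float
    se: float
    statistic: float  # z (count model) or t (tempo model)
    p_value: float
    df: float | None = None  # residual df for t statistics

    @property
    def z_ratio(self) -> float:
        return self.statistic

    @property
    def t_ratio(self) -> float:
        return self.statistic


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return special.expit(x)


class ZipPoissonMixed:
    """Zero-inflated Poisson regression with a scalar per-group random
    intercept, fitted by direct marginal-likelihood maximization.

    Parameters
    ----------
    y, X, offset, groups:
        Response counts, design matrix (cell-means for the bin factor),
        log-width offset, and integer-coded group (file) labels.
    zero_inflation:
        Intercept-only structural-zero mixture on the logit scale
        (default on).
    method:
        ``"agh"`` — adaptive Gauss-Hermite quadrature (default, 21 nodes);
        ``"laplace"`` — Laplace approximation fast path.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        offset: np.ndarray,
        groups: np.ndarray,
        zero_inflation: bool = True,
        random_effect: bool = True,
        method: str = "agh",
        n_nodes: int = 21,
    ):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.offset = np.asarray(offset, float)
        codes, _ = pd.factorize(np.asarray(groups))
        self.g = codes
        self.m = int(codes.max()) + 1 if len(codes) else 0
        if random_effect and self.m < 2:
            warnings.warn(
                "fewer than 2 groups: random intercept unidentifiable, "
                "falling back to a fixed-intercept GLM",
                stacklevel=2,
            )
            random_effect = False
        self.zi = zero_inflation
        self.re = random_effect
        self.method = method
        nodes, wts = special.roots_hermite(n_nodes)
        self._nodes, self._logw = nodes, np.log(wts)
        self.p = self.X.shape[1]
        self._is_zero = self.y == 0
        self._gammaln_y = special.gammaln(self.y + 1.0)
        if self.re:
            # one-hot group indicator for vectorized per-group sums
            self._G = np.zeros((len(self.y), self.m))
            self._G[np.arange(len(self.y)), self.g] = 1.0

    # -- parameter packing: [beta..., zi_logit?, log_sigma?] -----------------
    @property
    def param_names(self) -> list[str]:
        names = [f"b{j}" for j in range(self.p)]
        if self.zi:
            names.append("zi_logit")
        if self.re:
            names.append("log_sigma")
        return names

    def _unpack(self, params: np.ndarray):
        beta = params[: self.p]
        k = self.p
        zi_logit = params[k] if self.zi else -np.inf
        k += self.zi
        log_sigma = params[k] if self.re else None
        return beta, zi_logit, log_sigma

    # -- per-observation ZIP pieces ------------------------------------------
    def _obs_ll_d1_d2(self, eta: np.ndarray, pi: float):
        """Per-observation loglik and first/second derivatives wrt eta."""
        mu = np.exp(eta)
        y, zero = self.y, self._is_zero
        ll = np.where(
            zero,
            np.logaddexp(np.log(pi) if pi > 0 else -np.inf, np.log1p(-pi) - mu),
            (np.log1p(-pi) if pi > 0 else 0.0) + y * eta - mu - self._gammaln_y,
        )
        # w = P(not structural | zero) for zero cells
        if pi > 0:
            w = np.where(zero, special.expit(-special.logit(pi) - mu), 1.0)
        else:
            w = np.ones_like(mu)
        d1 = np.where(zero, -w * mu, y - mu)
        d2 = np.where(zero, w * mu * (mu * (1.0 - w) - 1.0), -mu)
        return ll, d1, d2

    def _group_mode(self, eta0: np.ndarray, pi: float, sigma2: float):
        """Vectorized Newton search for the per-group posterior modes."""
        u = np.zeros(self.m)
        for _ in range(40):
            ll, d1, d2 = self._obs_ll_d1_d2(eta0 + u[self.g], pi)
            grad = np.bincount(self.g, weights=d1, minlength=self.m) - u / sigma2
            hess = np.bincount(self.g, weights=d2, minlength=self.m) - 1.0 / sigma2
            hess = np.minimum(hess, -1.0 / (2.0 * sigma2))
            step = np.clip(-grad / hess, -3.0 * np.sqrt(sigma2), 3.0 * np.sqrt(sigma2))
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        ll, d1, d2 = self._obs_ll_d1_d2(eta0 + u[self.g], pi)
        hess = np.bincount(self.g, weights=d2, minlength=self.m) - 1.0 / sigma2
        hess = np.minimum(hess, -1e-10)
        return u, hess

    def loglik(self, params: np.ndarray) -> float:
        beta, zi_logit, log_sigma = self._unpack(params)
        pi = float(_sigmoid(zi_logit)) if self.zi else 0.0
        eta0 = self.X @ beta + self.offset
        if not self.re:
            ll, _, _ = self._obs_ll_d1_d2(eta0, pi)
            return float(ll.sum())
        sigma2 = float(np.exp(2.0 * log_sigma))
        u_hat, hess = self._group_mode(eta0, pi, sigma2)
        s_hat = 1.0 / np.sqrt(-hess)

        def joint(U: np.ndarray) -> np.ndarray:
            # U: (k, m) random-intercept values -> (k, m) joint log-densities
            ll, _, _ = self._obs_ll_d1_d2(eta0[None, :] + U[:, self.g], pi)
            per_group = ll @ self._G
            prior = -0.5 * U**2 / sigma2 - 0.5 * np.log(2.0 * np.pi * sigma2)
            return per_group + prior

        if self.method == "laplace":
            return float(np.sum(joint(u_hat[None, :])[0] + 0.5 * np.log(2.0 * np.pi) + np.log(s_hat)))
        # adaptive Gauss-Hermite centred on the per-group modes
        U = u_hat[None, :] + np.sqrt(2.0) * s_hat[None, :] * self._nodes[:, None]
        terms = joint(U) + (self._nodes**2 + self._logw)[:, None]
        return float(np.sum(special.logsumexp(terms, axis=0) + 0.5 * np.log(2.0) + np.log(s_hat)))

    def _nll(self, params: np.ndarray) -> float:
        ll = self.loglik(params)
        return -ll if np.isfinite(ll) else 1e12

    def _start(self) -> np.ndarray:
        # crude Poisson rates per column of the cell-means design
        beta0 = np.zeros(self.p)
        for j in range(self.p):
            sel = self.X[:, j] != 0
            if sel.any():
                rate = (self.y[sel].sum() + 0.5) / np.exp(self.offset[sel]).sum()
                beta0[j] = np.log(rate)
        start = list(beta0)
        if self.zi:
            frac0 = max(self._is_zero.mean() / 2.0, 0.02)
            start.append(float(special.logit(frac0)))
        if self.re:
            start.append(np.log(0.5))
        return np.asarray(start)

    def fit(self, seed: int = 0, max_restarts: int = 3) -> FitResult:
        bounds = [(None, None)] * self.p
        if self.zi:
            bounds.append((-12.0, 8.0))
        if self.re:
            bounds.append((-7.0, 3.0))
        rng = np.random.default_rng(seed)
        start = self._start()
        best = None
        for attempt in range(max_restarts + 1):
            x0 = start if attempt == 0 else start + rng.normal(0, 0.3, size=len(start))
            res = optimize.minimize(
                self._nll, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if res.success:
                break
        res = best
        cov, cov_msg = self._covariance(res.x)
        diagnostics = {"optimizer": dict(niter=int(res.nit), message=str(res.message)), "cov": cov_msg}
        if self.zi:
            diagnostics["pi"] = float(_sigmoid(res.x[self.p]))
        if self.re:
            log_sigma = res.x[self.p + self.zi]
            diagnostics["sigma_u"] = float(np.exp(log_sigma))
            diagnostics["variance_pinned"] = bool(log_sigma <= -6.9)
        fit = FitResult(
            model="zip_poisson_mixed" if self.zi else "poisson_mixed",
            params=res.x,
            param_names=self.param_names,
            cov=cov,
            loglik=-float(res.fun),
            n_obs=len(self.y),
            converged=bool(res.success),
            message=str(res.message),
            diagnostics=diagnostics,
        )
        if not res.success:
            warnings.warn(f"count model did not converge: {res.message}", stacklevel=2)
        return fit

    def _covariance(self, params: np.ndarray):
        from statsmodels.tools.numdiff import approx_hess

        try:
            H = approx_hess(params, self._nll)
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError("non-PD information")
            return cov, "ok"
        except np.linalg.LinAlgError as exc:  # boundary / singular information
            H = approx_hess(params, self._nll)
            cov = np.linalg.pinv(H)
            d = np.diag(cov).copy()
            d[d <= 0] = np.nan
            cov[np.diag_indices_from(cov)] = d
            return cov, f"pinv fallback: {exc}"


def design_from_bin_counts(counts: pd.DataFrame, level: str | None = None):
    """Cell-means design (y, X, offset, groups, names) from a bin-count table."""
    df = counts if level is None else counts[counts["level"] == level]
    if df.empty:
        raise FitError(f"no bin counts for level {level!r}")
    # bins with zero total count carry no information about their rate
    # (the cell-mean MLE diverges to -inf); they are dropped from the
    # fixed-factor design and their contrasts are simply not estimable
    totals = df.groupby("bin_name")["count"].sum()
    levels = [b for b in BIN_LEVELS if totals.get(b, 0) > 0]
    if not levels:
        raise FitError("all bin counts are zero: nothing to fit")
    df = df[df["bin_name"].isin(levels)]
    X = np.column_stack([(df["bin_name"] == b).to_numpy(float) for b in levels])
    return (
        df["count"].to_numpy(float),
        X,
        np.log(df["bin_width"].to_numpy(float)),
        df["file_id"].to_numpy(),
        list(levels),
    )


def fit_zip_poisson_mixed(
    counts: pd.DataFrame,
    level: str | None = None,
    zero_inflation: bool = True,
    method: str = "agh",
    null: bool = False,
    seed: int = 0,
) -> FitResult:
    """Fit the zero-inflated Poisson mixed count model to a bin-count table.

    ``null=True`` keeps only the intercept in the conditional mean (random
    intercept and zero-inflation retained), the reference model for the
    full-versus-null likelihood-ratio test.
    """
    y, X, offset, groups, names = design_from_bin_counts(counts, level)
    if null:
        X = np.ones((len(y), 1))
        names = ["intercept"]
    model = ZipPoissonMixed(y, X, offset, groups, zero_inflation=zero_inflation, method=method)
    fit = model.fit(seed=seed)
    fit.param_names = names + fit.param_names[len(names):]
    fit.diagnostics["level"] = level
    return fit


def lrt_full_vs_null(full: FitResult, null: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio chi-square between nested fits on identical data."""
    if full.n_obs != null.n_obs:
        raise FitError("full and null fits must use identical data")
    chi2 = 2.0 * (full.loglik - null.loglik)
    df = full.n_params - null.n_params
    if chi2 < -1e-6:
        raise FitError(
            f"full log-likelihood below null ({full.loglik:.6f} < {null.loglik:.6f}): refit required"
        )
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def posthoc_contrasts(
    fit: FitResult,
    pairs: tuple | list = DEFAULT_COUNT_PAIRS,
) -> list[ContrastResult]:
    """Pairwise linear contrasts c'beta with SE = sqrt(c'Vc) on the link
    scale; z/normal p for count fits, t with residual df for tempo fits."""
    out = []
    for a, b in pairs:
        if a not in fit.param_names or b not in fit.param_names:
            continue
        c = np.zeros(fit.n_params)
        c[fit.param_names.index(a)] += 1.0
        c[fit.param_names.index(b)] -= 1.0
        est = float(c @ fit.params)
        var = float(c @ fit.cov @ c)
        if var < 0 or not np.isfinite(var):
            raise FitError(f"contrast {a} - {b}: invalid variance {var}")
        se = np.sqrt(var)
        if a == b or se == 0.0:
            stat, p = 0.0, 1.0
            se = max(se, 0.0)
        else:
            stat = est / se
            if fit.df_resid is not None:
                p = 2.0 * stats.t.sf(abs(stat), fit.df_resid)
            else:
                p = 2.0 * stats.norm.sf(abs(stat))
        out.append(
            ContrastResult(
                pair=f"{a} - {b}",
                estimate=est,
                se=se,
                statistic=stat,
                p_value=float(p),
                df=fit.df_resid,
            )
        )
    return out


def fit_tempo_model(
    tempo: pd.DataFrame,
    pairs: tuple | list = DEFAULT_TEMPO_PAIRS,
) -> tuple[FitResult, tuple[float, int, float], list[ContrastResult]]:
    """Gaussian LMM of log(t_k) on interval type with a per-section random
    intercept (maximum likelihood, not REML).

    ``tempo`` columns: section_id, tk_type in {series, pants, pulses}, t_k.
    Returns (full fit, full-vs-null LRT, pairwise contrasts with residual-df
    t tests).
    """
    import statsmodels.api as sm

    missing = set(TK_TYPES) - set(tempo["tk_type"])
    if missing:
        raise FitError(f"tk_type level(s) absent: {sorted(missing)}")
    if (tempo["t_k"] <= 0).any():
        raise FitError("non-positive t_k cannot be log-transformed")
    y = np.log(tempo["t_k"].to_numpy(float))
    levels = [t for t in TK_TYPES if t in set(tempo["tk_type"])]
    X = np.column_stack([(tempo["tk_type"] == t).to_numpy(float) for t in levels])
    groups = tempo["section_id"].to_numpy()

    def _ml_fit(exog):
        model = sm.MixedLM(y, exog, groups=groups)
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(res.llf):
                return res
        raise FitError("tempo mixed model failed to converge with any optimizer")

    full = _ml_fit(X)
    null = _ml_fit(np.ones((len(y), 1)))

    n, p = len(y), X.shape[1]
    cov = np.zeros((p + 1, p + 1))
    cov[:p, :p] = np.asarray(full.cov_params())[:p, :p]
    cov_re = float(np.asarray(full.cov_re)[0, 0])
    params = np.concatenate([full.fe_params, [cov_re]])
    fit = FitResult(
        model="tempo_lmm",
        params=params,
        param_names=levels + ["re_var"],
        cov=cov,
        loglik=float(full.llf),
        n_obs=n,
        converged=bool(full.converged),
        df_resid=n - p,
        diagnostics={
            "sigma_resid": float(np.sqrt(full.scale)),
            "sigma_section": float(np.sqrt(cov_re)),
        },
    )
    chi2 = max(2.0 * (full.llf - null.llf), 0.0)
    df = p - 1
    lrt = (float(chi2), df, float(stats.chi2.sf(chi2, df)))
    contrasts = posthoc_contrasts(fit, pairs)
    return fit, lrt, contrasts


def simulate_zip_counts(
    beta: np.ndarray,
    pi: float,
    sigma_u: float,
    n_files: int,
    widths: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a bin-count table from known ZIP mixed parameters (one row
    per file x bin), for calibration and recovery studies."""
    rng = rng or np.random.default_rng()
    if widths is None:
        from .rhythm import BinScheme

        scheme = BinScheme()
        widths = np.array([scheme.width_of(b) for b in BIN_LEVELS])
    beta = np.asarray(beta, float)
    rows = []
    for i in range(n_files):
        u = rng.normal(0.0, sigma_u)
        mu = np.exp(beta + np.log(widths) + u)
        y = rng.poisson(mu)
        y[rng.random(len(y)) < pi] = 0
        for b, w, c in zip(BIN_LEVELS, widths, y):
            rows.append(
                {
                    "file_id": f"f{i:03d}",
                    "level": "all_pulses",
                    "bin_name": b,
                    "count": int(c),
                    "bin_width": float(w),
                    "n_ratios_in_file": int(y.sum()),
                }
            )
    return pd.DataFrame(rows)
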