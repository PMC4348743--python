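"""Continuous-data benchmark-concentration (BMC / BMCL) engine.

The central mean model is the saturating exponential

    mu(X) = a * (c - (c - 1) * exp(-b * X)),   a > 0, b > 0, c > 1,

where ``a`` is the background response (per 1,000 cells for MN-RET rates),
``b`` the slope per ppm and ``c`` the asymptote ratio: mu(0) = a and
mu(inf) = a * c.  For log-normally distributed responses the model is fit on
natural-log scale with constant log-scale variance, and mu(X) is the median
response at concentration X.

Benchmark response (BMR) definitions:

* ``rel10`` — a 10% relative increase over background: target ratio r = 1.1;
* ``one_sd`` — one control-group SD (response scale) above background:
  r = 1 + SD_0 / a.

Inverting the mean model gives the closed-form benchmark concentration

    BMC = -(1/b) * ln((c - r) / (c - 1)),

defined only when the target is below the asymptote (r < c); otherwise the
estimate carries the status ``NA_target_exceeds_asymptote`` — the situation
in which a BMCL "could not be calculated" for shallow dose-response data.

The BMCL is the one-sided 95% lower profile-likelihood bound: the model is
reparameterized with BMC as a free parameter (b is recovered from (a, c,
BMC)), the likelihood is maximized over the nuisance parameters at fixed
BMC, and the bound is the smallest BMC whose constrained deviance
2 * (loglik_hat - loglik_profile) stays within the chi-square-1 0.90 quantile
(2.7055), the usual convention for a one-sided 95% limit.

A battery of standard continuous-data models (exponential, Hill, linear,
quadratic polynomial, power) is fit under the same distribution assumption
for model comparison by AIC and goodness of fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: chi-square(1) quantile at 0.90 — one-sided 95% profile bound
PROFILE_CHI2_CUTOFF = float(stats.chi2.ppf(0.90, 1))

STATUS_OK = "ok"
STATUS_NA_ASYMPTOTE = "NA_target_exceeds_asymptote"
STATUS_NA_NO_CONVERGENCE = "NA_no_convergence"


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseData:
    """Individual or group-summarized dose-response observations.

    ``individual`` holds columns (dose_ppm, response); ``summary`` holds
    (dose_ppm, n, mean, sd) with arithmetic group statistics.  ``distribution``
    selects the fit scale: log-normal data are fit on natural logs (summaries
    are converted by log-normal moment matching), normal data on the raw scale.
    """

    individual: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    distribution: str = "lognormal"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.individual is None) == (self.summary is None):
            raise ValueError("provide exactly one of individual or summary data")
        if self.distribution not in ("lognormal", "normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.individual is not None:
            if np.any(self.individual["dose_ppm"].to_numpy(float) < 0):
                raise ValueError("doses must be non-negative")
            if self.distribution == "lognormal" and np.any(
                self.individual["response"].to_numpy(float) <= 0
            ):
                raise ValueError("log-normal responses must be positive")
        else:
            if np.any(self.summary["dose_ppm"].to_numpy(float) < 0):
                raise ValueError("doses must be non-negative")

    @classmethod
    def from_individual(
        cls, dose_ppm, response, distribution: str = "lognormal"
    ) -> "DoseResponseData":
        frame = pd.DataFrame(
            {"dose_ppm": np.asarray(dose_ppm, float), "response": np.asarray(response, float)}
        )
        return cls(individual=frame, distribution=distribution)

    @classmethod
    def from_summary(
        cls, dose_ppm, n, mean, sd, distribution: str = "lognormal"
    ) -> "DoseResponseData":
        frame = pd.DataFrame(
            {
                "dose_ppm": np.asarray(dose_ppm, float),
                "n": np.asarray(n, int),
                "mean": np.asarray(mean, float),
                "sd": np.asarray(sd, float),
            }
        )
        return cls(summary=frame, distribution=distribution)

    @property
    def doses(self) -> np.ndarray:
        src = self.individual if self.individual is not None else self.summary
        return np.unique(src["dose_ppm"].to_numpy(float))

    @property
    def n_groups(self) -> int:
        return len(self.doses)

    @property
    def n_total(self) -> int:
        if self.individual is not None:
            return len(self.individual)
        return int(self.summary["n"].sum())

    def group_stats(self) -> pd.DataFrame:
        """Per-dose sufficient statistics on the fit scale.

        Columns: dose, n, mean (fit-scale group mean), ss (within-group sum
        of squares on fit scale).  For log-normal summaries the arithmetic
        (mean, sd) are converted by moment matching:
        sigma_log^2 = ln(1 + sd^2/mean^2), mu_log = ln(mean) - sigma_log^2/2.
        """
        rows = []
        if self.individual is not None:
            for d, sub in self.individual.groupby("dose_ppm"):
                y = sub["response"].to_numpy(float)
                v = np.log(y) if self.distribution == "lognormal" else y
                rows.append((d, len(v), v.mean(), ((v - v.mean()) ** 2).sum()))
        else:
            for _, row in self.summary.iterrows():
                n, m, s = int(row["n"]), float(row["mean"]), float(row["sd"])
                if self.distribution == "lognormal":
                    if m <= 0:
                        raise ValueError("log-normal summary means must be positive")
                    s2 = np.log1p((s / m) ** 2)
                    mu = np.log(m) - s2 / 2.0
                    rows.append((row["dose_ppm"], n, mu, (n - 1) * s2))
                else:
                    rows.append((row["dose_ppm"], n, m, (n - 1) * s**2))
        out = pd.DataFrame(rows, columns=["dose", "n", "mean", "ss"])
        return out.sort_values("dose").reset_index(drop=True)

    def control_sd(self) -> float:
        """Response-scale SD of the lowest-dose group (for the 1-SD BMR)."""
        if self.individual is not None:
            d0 = self.individual["dose_ppm"].min()
            y = self.individual.loc[
                self.individual["dose_ppm"] == d0, "response"
            ].to_numpy(float)
            return float(np.std(y, ddof=1))
        row = self.summary.loc[self.summary["dose_ppm"].idxmin()]
        return float(row["sd"])

    def control_mean_response(self) -> float:
        """Response-scale central value of the lowest-dose group (median for
        log-normal data)."""
        g = self.group_stats()
        m0 = float(g.loc[0, "mean"])
        return float(np.exp(m0)) if self.distribution == "lognormal" else m0


def drop_high_dose(data: DoseResponseData) -> DoseResponseData:
    """Remove the single highest dose group (the EPA-sanctioned remedy when a
    saturating model misfits the top of the exposure range)."""
    doses = data.doses
    if len(doses) <= 3:
        raise ValueError(
            f"refusing to drop a dose group: only {len(doses)} groups present "
            "(need > 3 so that >= 3 remain)"
        )
    top = doses.max()
    if data.individual is not None:
        kept = data.individual[data.individual["dose_ppm"] < top].reset_index(drop=True)
        out = DoseResponseData(individual=kept, distribution=data.distribution)
    else:
        kept = data.summary[data.summary["dose_ppm"] < top].reset_index(drop=True)
        out = DoseResponseData(summary=kept, distribution=data.distribution)
    out.provenance = list(data.provenance) + [f"dropped highest dose group ({top} ppm)"]
    return out


# ---------------------------------------------------------------------------
# mean models
# ---------------------------------------------------------------------------


def eval_exponential(a: float, b: float, c: float, X) -> np.ndarray:
    """mu(X) = a * (c - (c - 1) * exp(-b * X))."""
    if not (a > 0 and b > 0 and c > 1):
        raise ValueError("require a > 0, b > 0, c > 1")
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("doses must be non-negative")
    return a * (c - (c - 1.0) * np.exp(-b * X))


@dataclass
class ExpModelFit:
    """Fitted exponential model with the residual SD on the fit scale."""

    a: float
    b: float
    c: float
    sigma: float
    loglik: float
    aic: float
    converged: bool
    distribution: str = "lognormal"
    n: int = 0
    n_mean_params: int = 3
    n_params: int = 4

    def predict(self, X) -> np.ndarray:
        return eval_exponential(self.a, self.b, self.c, X)


@dataclass
class BmcEstimate:
    """BMC and its one-sided lower confidence bound with an explicit status."""

    bmr_type: str
    bmc: float | None
    bmcl: float | None
    status: str
    level: float = 0.95
    detail: str = ""


def _sse(mu_fit_scale: np.ndarray, g: pd.DataFrame) -> float:
    """Total sum of squares about the model on the fit scale from group
    sufficient statistics."""
    n = g["n"].to_numpy(float)
    m = g["mean"].to_numpy(float)
    ss = g["ss"].to_numpy(float)
    return float(np.sum(ss) + np.sum(n * (m - mu_fit_scale) ** 2))


def _loglik_from_sse(sse: float, N: int) -> float:
    sigma2 = max(sse / N, 1e-300)
    return -0.5 * N * (np.log(2 * np.pi * sigma2) + 1.0)


def _fit_scale_mu(mu_response: np.ndarray, distribution: str) -> np.ndarray:
    if distribution == "lognormal":
        with np.errstate(invalid="ignore"):
            return np.log(mu_response)
    return mu_response


def fit_exponential(data: DoseResponseData) -> ExpModelFit:
    """Maximum-likelihood exponential fit (sigma profiled out).

    Multi-start L-BFGS-B over (a, b, c) inside the constraint box
    a in (0, 10 * max group response], b in (1e-6, 10], c in (1 + 1e-6, 100],
    seeded from method-of-moments values.  Individual and summarized inputs
    share the same group-sufficient-statistic likelihood, so they agree
    exactly whenever the summaries are sufficient.
    """
    g = data.group_stats()
    if len(g) < 3:
        raise ValueError("need at least 3 distinct dose groups")
    N = int(g["n"].sum())
    doses = g["dose"].to_numpy(float)

    resp_mean = (
        np.exp(g["mean"].to_numpy(float))
        if data.distribution == "lognormal"
        else g["mean"].to_numpy(float)
    )
    a_hi = 10.0 * float(np.max(resp_mean))
    bounds = [(1e-9, a_hi), (1e-6, 10.0), (1.0 + 1e-6, 100.0)]

    a0 = max(float(resp_mean[0]), 1e-6)
    c0 = float(np.clip(np.max(resp_mean) / a0, 1.05, 50.0))
    pos = doses[doses > 0]
    b0 = 1.0 / float(np.median(pos)) if pos.size else 0.1
    starts = [
        (a0, b0, c0),
        (a0, b0 / 10.0, max(c0 * 2, 2.0)),
        (a0, min(b0 * 10.0, 5.0), c0),
        (a0, 0.1, 2.0),
    ]

    def objective(theta):
        a, b, c = theta
        mu = a * (c - (c - 1.0) * np.exp(-b * doses))
        if np.any(mu <= 0):
            return 1e12
        return _sse(_fit_scale_mu(mu, data.distribution), g)

    best = None
    for s in starts:
        res = optimize.minimize(
            objective, np.asarray(s, float), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b, c = best.x
    sse = float(best.fun)
    sigma = float(np.sqrt(max(sse / N, 0.0)))
    ll = _loglik_from_sse(sse, N)
    converged = bool(best.success) and sse < 1e11
    if not converged:
        logger.warning("exponential fit did not converge: %s", best.message)
    return ExpModelFit(
        a=float(a),
        b=float(b),
        c=float(c),
        sigma=sigma,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * 4,
        converged=converged,
        distribution=data.distribution,
        n=N,
    )


# ---------------------------------------------------------------------------
# BMC / BMCL
# ---------------------------------------------------------------------------


def _target_ratio(bmr_type: str, a: float, control_sd: float | None) -> float:
    if bmr_type == "rel10":
        return 1.1
    if bmr_type == "one_sd":
        if control_sd is None:
            raise ValueError("one_sd BMR requires the control-group SD")
        return 1.0 + control_sd / a
    raise ValueError(f"unknown BMR type {bmr_type!r}")


def bmc_closed_form(a: float, b: float, c: float, r: float) -> float:
    """BMC = -(1/b) * ln((c - r) / (c - 1)); requires 1 < r < c."""
    if not (1.0 < r < c):
        raise ValueError("target ratio must satisfy 1 < r < c")
    return float(-np.log((c - r) / (c - 1.0)) / b)


def bmc_from_fit(
    fit: ExpModelFit, bmr_type: str = "rel10", control_sd: float | None = None,
    level: float = 0.95,
) -> BmcEstimate:
    """Benchmark concentration from a converged exponential fit.

    When the target response exceeds the fitted asymptote (r >= c) the
    estimate is returned with status ``NA_target_exceeds_asymptote`` rather
    than raising — the model simply never reaches the benchmark response.
    """
    if not fit.converged:
        return BmcEstimate(
            bmr_type=bmr_type,
            bmc=None,
            bmcl=None,
            status=STATUS_NA_NO_CONVERGENCE,
            level=level,
            detail="model fit did not converge",
        )
    r = _target_ratio(bmr_type, fit.a, control_sd)
    if r >= fit.c:
        return BmcEstimate(
            bmr_type=bmr_type,
            bmc=None,
            bmcl=None,
            status=STATUS_NA_ASYMPTOTE,
            level=level,
            detail=(
                f"target ratio {r:.4g} >= asymptote ratio c = {fit.c:.4g}: "
                "benchmark response above the plateau"
            ),
        )
    return BmcEstimate(
        bmr_type=bmr_type,
        bmc=bmc_closed_form(fit.a, fit.b, fit.c, r),
        bmcl=None,
        status=STATUS_OK,
        level=level,
    )


def _profile_loglik(
    bmc: float,
    data_stats: pd.DataFrame,
    N: int,
    distribution: str,
    bmr_type: str,
    control_sd: float | None,
    start: np.ndarray,
    bounds,
) -> tuple[float, np.ndarray]:
    """Max log-likelihood over (a, c) at fixed BMC; b is recovered from
    (a, c, BMC) through the closed-form inversion."""
    doses = data_stats["dose"].to_numpy(float)

    def objective(theta):
        a, c = theta
        r = _target_ratio(bmr_type, a, control_sd)
        if r >= c:
            return 1e12
        b = -np.log((c - r) / (c - 1.0)) / bmc
        if not (1e-9 < b < 1e3):
            return 1e12
        mu = a * (c - (c - 1.0) * np.exp(-b * doses))
        if np.any(mu <= 0):
            return 1e12
        return _sse(_fit_scale_mu(mu, distribution), data_stats)

    best = None
    starts = [np.asarray(start, float)]
    if len(start) == 2 and not np.allclose(start, [start[0], 2.0]):
        starts.append(np.array([start[0], min(max(2.0, start[1] * 0.5), 99.0)]))
    for s in starts:
        res = optimize.minimize(
            objective, s, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        res2 = optimize.minimize(objective, s, method="L-BFGS-B", bounds=bounds)
        for cand in (res, res2):
            if best is None or cand.fun < best.fun:
                best = cand
    return _loglik_from_sse(float(best.fun), N), np.asarray(best.x, float)


def bmcl_profile(
    fit: ExpModelFit,
    data: DoseResponseData,
    bmr_type: str = "rel10",
    level: float = 0.95,
    control_sd: float | None = None,
) -> BmcEstimate:
    """One-sided lower profile-likelihood bound on the BMC.

    Steps the BMC down geometrically from the MLE until the profiled deviance
    crosses the chi-square cutoff, then refines the crossing by Brent root
    finding to relative tolerance 1e-4.
    """
    if bmr_type == "one_sd" and control_sd is None:
        control_sd = data.control_sd()
    point = bmc_from_fit(fit, bmr_type, control_sd, level=level)
    if point.status != STATUS_OK:
        return point
    bmc_hat = point.bmc
    cutoff = float(stats.chi2.ppf(2.0 * level - 1.0, 1))

    g = data.group_stats()
    N = int(g["n"].sum())
    resp_max = (
        float(np.exp(g["mean"].max()))
        if data.distribution == "lognormal"
        else float(g["mean"].max())
    )
    bounds = [(1e-9, 10.0 * resp_max), (1.0 + 1e-6, 100.0)]
    start = np.array([fit.a, fit.c])

    def deviance(bmc_value, warm):
        ll, theta = _profile_loglik(
            bmc_value, g, N, data.distribution, bmr_type, control_sd, warm, bounds
        )
        return 2.0 * (fit.loglik - ll), theta

    lo_dev, warm = deviance(bmc_hat, start)
    hi = bmc_hat
    hi_dev = lo_dev
    found = False
    for _ in range(200):
        lo = hi * 0.8
        dev, warm = deviance(lo, warm)
        if dev >= cutoff:
            found = True
            break
        hi, hi_dev = lo, dev
    if not found:
        return replace(
            point,
            status=STATUS_NA_NO_CONVERGENCE,
            detail="profile deviance never reached the cutoff while stepping down",
        )

    # bisection on the (noisy, warm-started) profile deviance; robust where a
    # root bracketer would lose its bracket to re-optimization jitter
    lo_b, hi_b = lo, hi  # deviance(lo_b) >= cutoff > deviance(hi_b)
    for _ in range(60):
        if (hi_b - lo_b) <= 1e-4 * hi_b:
            break
        mid = np.sqrt(lo_b * hi_b)
        dev, warm = deviance(mid, warm)
        if dev >= cutoff:
            lo_b = mid
        else:
            hi_b = mid
    bmcl = min(0.5 * (lo_b + hi_b), bmc_hat)
    return BmcEstimate(
        bmr_type=bmr_type, bmc=bmc_hat, bmcl=bmcl, status=STATUS_OK, level=level
    )


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def saturated_loglik(data: DoseResponseData) -> float:
    """Log-likelihood of the saturated model: free group means, common sigma."""
    g = data.group_stats()
    N = int(g["n"].sum())
    return _loglik_from_sse(float(g["ss"].sum()), N)


def lack_of_fit_test(fit, data: DoseResponseData) -> float:
    """LRT p-value of the fitted mean model against the saturated group-means
    model (same constant-variance assumption); chi-square with
    df = n_groups - n_mean_params."""
    df = data.n_groups - fit.n_mean_params
    if df <= 0:
        raise ValueError(
            f"lack-of-fit undefined: {data.n_groups} groups vs "
            f"{fit.n_mean_params} mean parameters"
        )
    ll_sat = saturated_loglik(data)
    stat = max(0.0, 2.0 * (ll_sat - fit.loglik))
    return float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# model battery
# ---------------------------------------------------------------------------


@dataclass
class GenericModelFit:
    """A battery member: named mean model with ML parameters."""

    model: str
    params: np.ndarray
    loglik: float
    aic: float
    converged: bool
    n_mean_params: int
    mu_fn: object = None  # params, X -> mu

    def predict(self, X) -> np.ndarray:
        return self.mu_fn(self.params, np.asarray(X, float))


def _battery_models(resp_mean: np.ndarray, doses: np.ndarray) -> dict:
    a0 = max(float(resp_mean[0]), 1e-6)
    top = float(resp_mean.max())
    dmax = float(doses.max()) if doses.max() > 0 else 1.0
    slope0 = (top - a0) / dmax if dmax > 0 else 0.1
    return {
        "exponential": dict(
            fn=lambda p, X: p[0] * (p[2] - (p[2] - 1) * np.exp(-p[1] * X)),
            bounds=[(1e-9, 10 * top), (1e-6, 10.0), (1 + 1e-6, 100.0)],
            starts=[(a0, 1 / max(np.median(doses[doses > 0]), 1e-3), max(top / a0, 1.05)),
                    (a0, 0.1, 2.0)],
            k_mean=3,
        ),
        "hill": dict(
            # a + v * X^h / (k^h + X^h), Hill coefficient restricted >= 1
            fn=lambda p, X: p[0] + p[1] * X ** p[3] / (p[2] ** p[3] + X ** p[3]),
            bounds=[(1e-9, 10 * top), (-10 * top, 10 * top), (1e-3, 10 * dmax), (1.0, 18.0)],
            starts=[(a0, top - a0, dmax / 2, 1.0), (a0, top - a0, dmax / 10, 2.0)],
            k_mean=4,
        ),
        "linear": dict(
            fn=lambda p, X: p[0] + p[1] * X,
            bounds=[(1e-9, 10 * top), (-1e3, 1e3)],
            starts=[(a0, slope0)],
            k_mean=2,
        ),
        "poly2": dict(
            fn=lambda p, X: p[0] + p[1] * X + p[2] * X**2,
            bounds=[(1e-9, 10 * top), (-1e3, 1e3), (-1e2, 1e2)],
            starts=[(a0, slope0, 0.0)],
            k_mean=3,
        ),
        "power": dict(
            # a + s * X^g with the EPA-restricted power g >= 1
            fn=lambda p, X: p[0] + p[1] * np.where(X > 0, X, 0.0) ** p[2],
            bounds=[(1e-9, 10 * top), (-1e3, 1e3), (1.0, 18.0)],
            starts=[(a0, slope0, 1.0), (a0, slope0 / 10, 2.0)],
            k_mean=3,
        ),
    }


def fit_model_battery(data: DoseResponseData) -> pd.DataFrame:
    """Fit the recommended continuous-model battery under one distribution.

    Returns one row per model with loglik, AIC (k = mean params + 1 for
    sigma), goodness-of-fit p (lack of fit vs the saturated model when df >
    0) and the numerically inverted rel10 BMC.  Non-convergence is recorded
    per row; the battery always returns.
    """
    g = data.group_stats()
    if len(g) < 3:
        raise ValueError("need at least 3 distinct dose groups")
    N = int(g["n"].sum())
    doses = g["dose"].to_numpy(float)
    resp_mean = (
        np.exp(g["mean"].to_numpy(float))
        if data.distribution == "lognormal"
        else g["mean"].to_numpy(float)
    )
    rows = []
    fits = {}
    for name, spec in _battery_models(resp_mean, doses).items():
        fn = spec["fn"]

        def objective(p, fn=fn):
            mu = fn(p, doses)
            if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
                return 1e12
            return _sse(_fit_scale_mu(mu, data.distribution), g)

        best = None
        for s in spec["starts"]:
            res = optimize.minimize(
                objective, np.asarray(s, float), method="L-BFGS-B",
                bounds=spec["bounds"],
            )
            if best is None or res.fun < best.fun:
                best = res
        ll = _loglik_from_sse(float(best.fun), N)
        k = spec["k_mean"] + 1
        fit = GenericModelFit(
            model=name,
            params=np.asarray(best.x, float),
            loglik=ll,
            aic=-2 * ll + 2 * k,
            converged=bool(best.success) and best.fun < 1e11,
            n_mean_params=spec["k_mean"],
            mu_fn=fn,
        )
        fits[name] = fit
        df = len(g) - spec["k_mean"]
        gof = lack_of_fit_test(fit, data) if df > 0 else np.nan
        rows.append(
            {
                "model": name,
                "loglik": ll,
                "aic": fit.aic,
                "gof_p": gof,
                "converged": fit.converged,
                "bmc_rel10": bmc_numeric(lambda X: fn(best.x, X), 1.1, doses.max()),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["fits"] = fits
    return table


def select_model(battery: pd.DataFrame, aic_tie_window: float = 2.0) -> str:
    """Selection rule: among converged models with goodness-of-fit p > 0.1,
    the lowest AIC; models within ``aic_tie_window`` of the best are treated
    as tied (the usual "delta-AIC < 2 is not meaningful" convention) and a
    tie is resolved in favour of the exponential model."""
    ok = battery[(battery["converged"]) & (battery["gof_p"].fillna(0) > 0.1)]
    if ok.empty:
        ok = battery[battery["converged"]]
    if ok.empty:
        raise ValueError("no model converged")
    best_aic = ok["aic"].min()
    tied = ok[ok["aic"] <= best_aic + aic_tie_window]
    if (tied["model"] == "exponential").any():
        return "exponential"
    return str(tied.sort_values("aic").iloc[0]["model"])


def bmc_numeric(mu_fn, r: float, dose_max: float) -> float | None:
    """Numerically invert an arbitrary mean model for the BMC: smallest X with
    mu(X) = r * mu(0), searched up to 100x the top dose.  None when the
    benchmark response is never reached."""
    mu0 = float(mu_fn(np.array([0.0]))[0])
    target = r * mu0

    def f(x):
        return float(mu_fn(np.array([x]))[0]) - target

    hi = max(dose_max, 1.0)
    for _ in range(12):
        if f(hi) > 0:
            break
        hi *= 2
    else:
        return None
    try:
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-12))
    except ValueError:
        return None
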