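"""Swimming-halo dose-response modelling.

Halo diameter on semi-solid agar shrinks as the carbon concentration rises
(starved rhizobia swim more).  Each strain x carbon-source series is modelled
either with a four-parameter log-logistic (4PL) curve

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

(b: slope, c/d: lower/upper asymptotes in mm, e: inflection concentration in
mM; b > 0 means the diameter decreases with concentration) or with an ordinary
straight line, whichever a small-sample-corrected information criterion
prefers.  A non-motile control strain defines the "maximum non-motile
diameter" baseline drawn on the dose-response plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FourPLFit",
    "LinearFit",
    "four_pl",
    "fit_four_pl",
    "fit_linear",
    "select_model",
    "non_motile_baseline",
    "predict_four_pl",
]


def four_pl(x, b, c, d, e):
    """Four-parameter log-logistic response at concentration(s) ``x`` (> 0)."""
    x = np.asarray(x, dtype=float)
    z = np.clip(b * (np.log(x) - np.log(e)), -500.0, 500.0)
    return c + (d - c) / (1.0 + np.exp(z))


@dataclass
class FourPLFit:
    b: float
    c: float
    d: float
    e: float
    rss: float
    n: int
    converged: bool
    degenerate: bool = False
    message: str = ""
    # approximate (curvature-based) standard errors for (b, c, d, e)
    se: dict = field(default_factory=dict)

    def predict(self, x):
        return four_pl(x, self.b, self.c, self.d, self.e)


@dataclass
class LinearFit:
    intercept: float
    slope: float
    rss: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _extract(measurements) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(measurements, pd.DataFrame):
        conc = measurements["conc_mM"].to_numpy(dtype=float)
        diam = measurements["diameter_mm"].to_numpy(dtype=float)
    else:
        conc, diam = measurements
        conc = np.asarray(conc, dtype=float)
        diam = np.asarray(diam, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0 (log-concentration model)")
    return conc, diam


def fit_four_pl(measurements, *, tol: float = 1e-12) -> FourPLFit:
    """Least-squares 4PL fit for one strain x carbon-source series.

    Requires >= 5 distinct concentrations.  Initialisation per the standard
    dose-response recipe (d = max mean diameter, c = min mean diameter,
    e = geometric mid-concentration) with a multi-start over slopes
    b in {+-0.5, +-1, +-2}; the lowest-RSS solution wins.  A series with all
    diameters identical is returned as a degenerate (flat) fit.
    """
    conc, diam = _extract(measurements)
    n = conc.size
    distinct = np.unique(conc)
    if distinct.size < 5:
        return FourPLFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, n, converged=False,
            message=f"need >= 5 distinct concentrations, got {distinct.size}",
        )
    if np.ptp(diam) == 0:
        v = float(diam[0])
        e0 = float(np.exp(0.5 * (np.log(distinct.min()) + np.log(distinct.max()))))
        return FourPLFit(1.0, v, v, e0, 0.0, n, converged=True, degenerate=True,
                         message="flat response: lower and upper asymptotes coincide")

    means = pd.Series(diam).groupby(pd.Series(conc)).mean()
    d0 = float(means.max())
    c0 = float(means.min())
    loge0 = 0.5 * (np.log(distinct.min()) + np.log(distinct.max()))
    logx = np.log(conc)

    def resid(p):
        b, c, d, loge = p
        z = np.clip(b * (logx - loge), -500.0, 500.0)
        return c + (d - c) / (1.0 + np.exp(z)) - diam

    def jac(p):
        b, c, d, loge = p
        z = np.exp(np.clip(b * (logx - loge), -500.0, 500.0))
        s = 1.0 / (1.0 + z)          # logistic factor
        ds_db = -(d - c) * s * s * z * (logx - loge)
        ds_dloge = (d - c) * s * s * z * b
        return np.column_stack([ds_db, 1.0 - s, s, ds_dloge])

    best = None
    for b0 in (0.5, -0.5, 1.0, -1.0, 2.0, -2.0):
        try:
            sol = least_squares(resid, x0=[b0, c0, d0, loge0], jac=jac,
                                method="lm", xtol=tol, ftol=tol, gtol=tol,
                                max_nfev=2000)
        except Exception:  # pragma: no cover - LM failures are silent restarts
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, np.nan, n,
                         converged=False, message="all optimiser starts failed")

    b, c, d, loge = best.x
    if c > d:
        # (b, c, d) and (-b, d, c) describe the same curve; report the
        # canonical orientation with d as the upper asymptote
        b, c, d = -b, d, c
        best.x[:] = (b, c, d, loge)
    rss = float(2.0 * best.cost)
    se = {}
    try:
        J = jac(best.x)
        cov = np.linalg.inv(J.T @ J) * max(rss, 1e-30) / max(n - 4, 1)
        sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        se = {"b": sd[0], "c": sd[1], "d": sd[2], "e": float(np.exp(loge)) * sd[3]}
    except np.linalg.LinAlgError:
        pass
    return FourPLFit(float(b), float(c), float(d), float(np.exp(loge)), rss, n,
                     converged=bool(best.success), se=se)


def fit_linear(measurements) -> LinearFit:
    """Ordinary least squares of diameter on concentration (>= 3 distinct)."""
    conc, diam = _extract(measurements)
    if np.unique(conc).size < 3:
        raise ValueError(
            f"linear fit needs >= 3 distinct concentrations, got {np.unique(conc).size}"
        )
    A = np.column_stack([np.ones_like(conc), conc])
    coef, *_ = np.linalg.lstsq(A, diam, rcond=None)
    resid = diam - A @ coef
    return LinearFit(float(coef[0]), float(coef[1]), float(resid @ resid), conc.size)


def _aicc(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood from RSS; k counts mean parameters + 1 variance.
    rss = max(rss, n * 1e-20)
    aic = n * np.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = np.inf
    return float(aic)


def select_model(fourpl: FourPLFit, linear: LinearFit) -> dict:
    """Pick 4PL vs linear by corrected information criterion (ties -> linear)."""
    crit_lin = _aicc(linear.rss, linear.n, k=3)
    if not fourpl.converged or fourpl.degenerate:
        return {"model": "linear", "criterion_4pl": np.inf,
                "criterion_linear": crit_lin,
                "reason": "4PL not converged or degenerate"}
    crit_4pl = _aicc(fourpl.rss, fourpl.n, k=5)
    model = "4PL" if crit_4pl < crit_lin else "linear"
    return {"model": model, "criterion_4pl": crit_4pl, "criterion_linear": crit_lin,
            "reason": "corrected information criterion"}


def non_motile_baseline(measurements: pd.DataFrame, control_strain: str) -> float:
    """Maximum non-motile diameter: mean + 2 SD of the control strain's halos."""
    rows = measurements[measurements["strain"] == control_strain]
    if rows.empty:
        raise ValueError(
            f"no measurements for non-motile control strain {control_strain!r}"
        )
    diam = rows["diameter_mm"].to_numpy(dtype=float)
    sd = diam.std(ddof=1) if diam.size > 1 else 0.0
    return float(diam.mean() + 2.0 * sd)


def predict_four_pl(fit: FourPLFit, grid) -> pd.DataFrame:
    """Fitted curve (and, where available, approximate 95% CI) on a grid."""
    grid = np.asarray(grid, dtype=float)
    pred = fit.predict(grid)
    out = pd.DataFrame({"conc_mM": grid, "fit_mm": pred})
    if fit.se:
        # delta-method CI using parameter SEs, ignoring covariances: labelled
        # approximate in output because the curvature approximation is rough.
        eps = 1e-6
        grads = []
        base = np.array([fit.b, fit.c, fit.d, fit.e])
        for i in range(4):
            p = base.copy()
            p[i] += eps * max(abs(p[i]), 1.0)
            grads.append((four_pl(grid, *p) - pred) / (p[i] - base[i]))
        sds = np.array([fit.se["b"], fit.se["c"], fit.se["d"], fit.se["e"]])
        var = sum(g * g * s * s for g, s in zip(grads, sds))
        half = 1.96 * np.sqrt(var)
        out["ci_lo_mm"] = pred - half
        out["ci_hi_mm"] = pred + half
    return out


def fit_halo_table(table: pd.DataFrame, control_strain: str | None = None) -> dict:
    """Fit every strain x carbon-source series in a long-form halo table.

    Returns {(strain, carbon): {"fourpl", "linear", "selection"}} plus the
    non-motile baseline when a control strain is named.  Series from the
    control strain itself are still fitted (they come out degenerate/flat).
    """
    results: dict = {}
    for (strain, carbon), grp in table.groupby(["strain", "carbon_source"], sort=True):
        fourpl = fit_four_pl(grp)
        try:
            linear = fit_linear(grp)
        except ValueError as err:
            warnings.warn(f"{strain}/{carbon}: {err}")
            continue
        results[(strain, carbon)] = {
            "fourpl": fourpl,
            "linear": linear,
            "selection": select_model(fourpl, linear),
        }
    if control_strain is not None:
        results["baseline_mm"] = non_motile_baseline(table, control_strain)
    return results
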