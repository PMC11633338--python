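"""Linear models of health outcomes on ilr time-use coordinates.

One ordinary-least-squares model is fitted per pivot rotation of the
24-h composition: the outcome (e.g. a PCS-12 or MCS-12 quality-of-life
score) is regressed on the three ilr coordinates plus optional
demographic covariates.  Because the four rotations span the same model
space, fitted values and R-squared are identical across rotations; only
the coefficient parameterisation changes, and each rotation's *leading*
coefficient is the interpretable one — the expected outcome change per
one-unit increase in the log-ratio of that behaviour against the
geometric mean of the remaining behaviours.

Isotemporal substitution ("one-for-remaining" reallocation) asks a more
concrete question: starting from a reference composition (typically the
compositional mean), what outcome difference does the model predict if
one behaviour gains delta minutes per day while the remaining behaviours
shrink proportionally to their share of the remainder?  The predicted
difference is a linear contrast of the fitted coefficients, so its 95%
confidence band follows from the coefficient covariance and a
t-quantile at the residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .coda import (DAY_MINUTES, N_ROTATIONS, PARTS, close_composition,
                   ilr_transform, rotation_label)

ILR_NAMES = ("ilr1", "ilr2", "ilr3")


@dataclass
class RegressionResult:
    """One fitted outcome ~ ilr (+ covariates) model."""

    rotation: int
    leading_domain: str
    outcome_name: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    resid_var: float
    r_squared: float
    n: int
    df_resid: float
    fittedvalues: np.ndarray
    covariate_names: tuple[str, ...]
    sm_result: object  # statsmodels RegressionResults, kept for diagnostics

    @property
    def leading_beta(self) -> float:
        return float(self.params["ilr1"])

    @property
    def leading_se(self) -> float:
        return float(self.bse["ilr1"])

    @property
    def leading_p(self) -> float:
        return float(self.pvalues["ilr1"])


@dataclass
class ReallocationCurve:
    """Predicted outcome differences along one-for-remaining reallocations."""

    domain: str
    outcome_name: str
    reference: np.ndarray           # the 4-part reference composition
    table: pd.DataFrame             # delta_min, estimate, lower, upper, feasible


def _design(compositions, covariates: pd.DataFrame | None,
            rotation: int) -> pd.DataFrame:
    z = ilr_transform(np.asarray(compositions, float), rotation=rotation)
    X = pd.DataFrame(z, columns=list(ILR_NAMES))
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        X = pd.concat([X, cov], axis=1)
    return sm.add_constant(X, has_constant="add")


def fit_ilr_model(compositions, outcome, covariates: pd.DataFrame | None = None,
                  rotation: int = 0,
                  outcome_name: str = "outcome") -> RegressionResult:
    """OLS of an outcome on the three ilr coordinates plus covariates.

    ``compositions`` is an (n, 4) array of strictly positive daily
    minutes (closed to 1440); ``covariates``, if given, must already be
    numeric (dummy-code categoricals upstream).  Raises on a
    rank-deficient design, naming the offending columns.
    """
    y = np.asarray(outcome, float)
    X = _design(compositions, covariates, rotation)
    if len(y) <= X.shape[1]:
        raise ValueError(f"n={len(y)} too small for {X.shape[1]} parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for col in X.columns:
            sub = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(col)
        raise ValueError(f"singular design matrix; offending columns: {bad}")
    fit = sm.OLS(y, X).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(fit.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0  # zero-variance outcome: the model explains nothing
    return RegressionResult(
        rotation=rotation,
        leading_domain=rotation_label(rotation),
        outcome_name=outcome_name,
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        cov_params=fit.cov_params(),
        resid_var=float(fit.mse_resid),
        r_squared=r2,
        n=int(fit.nobs),
        df_resid=float(fit.df_resid),
        fittedvalues=np.asarray(fit.fittedvalues, float),
        covariate_names=tuple(covariates.columns) if covariates is not None else (),
        sm_result=fit,
    )


def fit_all_rotations(compositions, outcome,
                      covariates: pd.DataFrame | None = None,
                      outcome_name: str = "outcome") -> list[RegressionResult]:
    """Fit the model under all four pivot rotations (same model space)."""
    return [fit_ilr_model(compositions, outcome, covariates, r, outcome_name)
            for r in range(N_ROTATIONS)]


def leading_effects_table(results: list[RegressionResult]) -> pd.DataFrame:
    """Leading-coordinate effects of each rotation, one row per domain.

    Each row gives the outcome change per one-unit increase in the ilr
    of the named domain versus the remaining domains.
    """
    rows = [{
        "outcome": r.outcome_name,
        "domain": r.leading_domain,
        "beta": r.leading_beta,
        "se": r.leading_se,
        "p_value": r.leading_p,
    } for r in results]
    return pd.DataFrame(rows)


def one_for_remaining(reference, domain: str | int, delta: float) -> np.ndarray:
    """Reallocate ``delta`` minutes into one domain from the remaining three.

    The focal domain gains ``delta``; each remaining domain loses in
    proportion to its share of the remainder, keeping the 1440-min total.
    Returns the new composition, or raises if any part would hit zero.
    """
    ref = close_composition(np.asarray(reference, float))
    j = PARTS.index(domain) if isinstance(domain, str) else int(domain)
    remainder = DAY_MINUTES - ref[j]
    if ref[j] + delta <= 0 or remainder - delta <= 0:
        raise ValueError(f"reallocation of {delta:+.0f} min into {PARTS[j]} "
                         "drives a part to zero")
    new = ref * (remainder - delta) / remainder
    new[j] = ref[j] + delta
    return new


def reallocation_curve(result: RegressionResult, reference, domain: str,
                       deltas=None, alpha: float = 0.05) -> ReallocationCurve:
    """Predicted outcome difference for one-for-remaining reallocations.

    For each delta on the grid the difference is the ilr-coordinate
    contrast ``(ilr(new) - ilr(ref)) . beta_ilr``; covariates cancel in
    the contrast (they are held fixed), so the variance is
    ``a' V a`` over the ilr block of the coefficient covariance.  Grid
    points that would drive a part non-positive are marked infeasible.
    """
    if deltas is None:
        deltas = np.arange(-60.0, 65.0, 5.0)
    ref = close_composition(np.asarray(reference, float))
    z_ref = ilr_transform(ref, rotation=result.rotation)
    beta = result.params[list(ILR_NAMES)].to_numpy(float)
    V = result.cov_params.loc[list(ILR_NAMES), list(ILR_NAMES)].to_numpy(float)
    tq = scipy.stats.t.ppf(1.0 - alpha / 2.0, result.df_resid)
    rows = []
    for d in np.asarray(deltas, float):
        try:
            new = one_for_remaining(ref, domain, d)
        except ValueError:
            rows.append({"delta_min": d, "estimate": np.nan,
                         "lower": np.nan, "upper": np.nan, "feasible": False})
            continue
        a = ilr_transform(new, rotation=result.rotation) - z_ref
        est = float(a @ beta)
        half = tq * float(np.sqrt(a @ V @ a))
        rows.append({"delta_min": d, "estimate": est,
                     "lower": est - half, "upper": est + half,
                     "feasible": True})
    return ReallocationCurve(domain=domain, outcome_name=result.outcome_name,
                             reference=ref, table=pd.DataFrame(rows))


def all_reallocation_curves(result: RegressionResult, reference,
                            deltas=None) -> dict[str, ReallocationCurve]:
    """One curve per behaviour domain from a single fitted model."""
    return {d: reallocation_curve(result, reference, d, deltas) for d in PARTS}


def model_diagnostics(result: RegressionResult, outdir=None,
                      prefix: str = "model") -> dict:
    """Residual diagnostics: plots plus numeric companions.

    Writes residual-vs-fitted, scale-location and normal-QQ plots (when
    ``outdir`` is given) and returns Breusch-Pagan (heteroscedasticity)
    and Shapiro-Wilk (normality) statistics.  The numbers are reported
    for inspection, not used as automatic gates.
    """
    import statsmodels.stats.api as sms

    fit = result.sm_result
    resid = np.asarray(fit.resid, float)
    fitted = np.asarray(fit.fittedvalues, float)
    bp_stat, bp_p, _, _ = sms.het_breuschpagan(resid, fit.model.exog)
    sw_stat, sw_p = scipy.stats.shapiro(resid)
    report = {"breusch_pagan_stat": float(bp_stat), "breusch_pagan_p": float(bp_p),
              "shapiro_stat": float(sw_stat), "shapiro_p": float(sw_p)}
    if outdir is not None:
        from pathlib import Path
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        std_resid = resid / np.sqrt(result.resid_var)
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
        axes[0].scatter(fitted, resid, s=12)
        axes[0].axhline(0.0, color="grey", lw=0.8)
        axes[0].set(xlabel="fitted", ylabel="residual",
                    title="Residuals vs fitted")
        axes[1].scatter(fitted, np.sqrt(np.abs(std_resid)), s=12)
        axes[1].set(xlabel="fitted", ylabel=r"$\sqrt{|std.\ resid|}$",
                    title="Scale-location")
        scipy.stats.probplot(resid, dist="norm", plot=axes[2])
        axes[2].set_title("Normal Q-Q")
        fig.suptitle(f"{result.outcome_name}, {result.leading_domain}-first "
                     f"rotation", fontsize=10)
        fig.tight_layout()
        path = outdir / f"{prefix}_diagnostics.png"
        fig.savefig(path, dpi=110)
        plt.close(fig)
        report["plot_path"] = str(path)
    return report


def plot_reallocation_curves(curves: dict[str, ReallocationCurve],
                             path, outcome_name: str) -> None:
    """Four-panel reallocation figure with shaded 95% confidence bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, (domain, curve) in zip(axes.ravel(), curves.items()):
        tab = curve.table[curve.table["feasible"]]
        ax.plot(tab["delta_min"], tab["estimate"], lw=1.6)
        ax.fill_between(tab["delta_min"], tab["lower"], tab["upper"], alpha=0.25)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_title(f"more {domain}, less remaining")
        ax.set_xlabel("reallocated minutes/day")
        ax.set_ylabel(f"estimated change in {outcome_name}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
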