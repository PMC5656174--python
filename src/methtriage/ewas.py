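"""Per-cohort epigenome-wide robust regression of methylation on maternal BMI.

Each probe's untransformed beta value is modelled as the outcome of an
M-type (Huber) robust linear regression on the exposure — continuous
maternal BMI in kg/m^2, a WHO category contrast, or maternal and paternal
BMI mutually adjusted — plus covariates (maternal age, smoking, parity,
social class, batch) and, optionally, estimated cell-type proportions.
Robust regression guards the per-CpG fits against heteroscedasticity and
gross methylation outliers.

Two-sided p-values come from z = beta/SE against the standard normal rather
than a t reference, consistent with downstream inverse-variance
meta-analysis of the summary statistics (METAL convention).  Offspring sex
is deliberately not a covariate: it cannot confound a pre-pregnancy
exposure, and conditioning on it risks collider bias through the
sex-dependent intrauterine environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simcohort import CohortDataset

__all__ = ["ModelSpec", "EwasError", "qc_exposure", "encode_exposure", "huber_fit", "run_ewas"]

EXPOSURE_MODES = (
    "continuous",
    "overweight_obese_vs_normal",
    "underweight_vs_normal",
    "mutual_parental",
)

DEFAULT_COVARIATES = ("maternal_age", "smoking", "parity", "social_class", "batch")


class EwasError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Specification of one EWAS model.

    ``huber_c`` defaults to 1.345, the conventional tuning constant giving
    95% efficiency under Gaussian errors.
    """

    exposure_mode: str = "continuous"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    adjust_cells: bool = True
    huber_c: float = 1.345
    max_iter: int = 50
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.exposure_mode not in EXPOSURE_MODES:
            raise EwasError(f"unknown exposure_mode {self.exposure_mode!r}")
        if self.huber_c <= 0:
            raise EwasError("huber_c must be > 0")
        if self.tol <= 0:
            raise EwasError("tol must be > 0")


# ---------------------------------------------------------------------------
# exposure handling
# ---------------------------------------------------------------------------


def qc_exposure(bmi: np.ndarray | pd.Series) -> np.ndarray:
    """Flag BMI entries at least 5 SD from the mean (flag-only; no removal).

    Mirrors the consortium instruction to double-check, not discard, extreme
    values.  A constant (zero-SD) vector is an error.
    """
    x = np.asarray(bmi, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise EwasError("qc_exposure needs at least two non-missing values")
    mu, sd = x[ok].mean(), x[ok].std(ddof=1)
    if sd == 0:
        raise EwasError("exposure has zero standard deviation; flagging is undefined")
    flags = np.zeros_like(x, dtype=bool)
    flags[ok] = np.abs(x[ok] - mu) >= 5 * sd
    return flags


def encode_exposure(bmi: np.ndarray | pd.Series, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Encode the exposure column and the sample inclusion mask.

    WHO cut-offs: overweight/obese is BMI >= 25.0, underweight is BMI < 18.5,
    and the normal-weight reference group is 18.5 <= BMI <= 24.9.  Samples in
    neither the index nor the reference group are excluded from the contrast.
    """
    x = np.asarray(bmi, dtype=float)
    present = ~np.isnan(x)
    if mode in ("continuous", "mutual_parental"):
        return x, present
    normal = present & (x >= 18.5) & (x <= 24.9)
    if mode == "overweight_obese_vs_normal":
        index = present & (x >= 25.0)
    elif mode == "underweight_vs_normal":
        index = present & (x < 18.5)
    else:
        raise EwasError(f"unknown exposure_mode {mode!r}")
    mask = normal | index
    codes = np.where(index, 1.0, 0.0)
    codes[~mask] = np.nan
    return codes, mask


# ---------------------------------------------------------------------------
# Huber IRLS
# ---------------------------------------------------------------------------

_MAD_CONST = 0.6745  # normal-consistency constant for the median absolute residual


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        from scipy.linalg import qr

        _, r, piv = qr(x, mode="economic", pivoting=True)
        d = np.abs(np.diag(r))
        bad = [names[piv[i]] for i in range(len(d)) if d[i] < d[0] * 1e-10] or [
            names[p] for p in piv[x.shape[1] :]
        ]
        raise EwasError(f"design matrix is rank deficient; collinear columns: {bad}")


def huber_fit(
    x: np.ndarray,
    y: np.ndarray,
    c: float = 1.345,
    tol: float = 1e-6,
    max_iter: int = 50,
    column_names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Huber M-estimation for a single outcome by IRLS.

    Weights are ``w(r) = min(1, c*s/|r|)`` with the residual scale
    ``s = median|r| / 0.6745`` re-estimated every iteration; convergence is
    declared when the largest coefficient change drops below ``tol``.
    Standard errors use the M-estimator asymptotic variance in Huber's
    correction-factor form,

        cov = K^2 * [sum psi(r/s)^2 s^2 / (n - p)] / mean(psi')^2 * (X'X)^-1,
        K   = 1 + (p/n) * var(psi') / mean(psi')^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    if n <= p:
        raise EwasError(f"need n > p (got n={n}, p={p})")
    names = column_names or [f"x{j}" for j in range(p)]
    _check_rank(x, names)
    coef, se, conv = _huber_fit_batch(x, y[:, None], c=c, tol=tol, max_iter=max_iter)
    return coef[0], se[0], bool(conv[0])


def _huber_fit_batch(
    x: np.ndarray,
    y: np.ndarray,
    c: float = 1.345,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Huber IRLS for many outcome vectors sharing one design.

    ``x`` is (n, p); ``y`` is (n, M).  Returns coefficients (M, p), standard
    errors (M, p) and a convergence flag per outcome.  Identical in model and
    tolerances to :func:`huber_fit` (which delegates here with M = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    m = y.shape[1]
    # precompute outer products so the weighted normal equations are BLAS calls
    z = (x[:, :, None] * x[:, None, :]).reshape(n, p * p)
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = np.linalg.lstsq(x, y, rcond=None)[0].T  # (M, p) OLS start
    converged = np.zeros(m, dtype=bool)
    active = np.arange(m)
    for _ in range(max_iter):
        resid = y[:, active] - x @ coef[active].T  # (n, a)
        s = np.median(np.abs(resid), axis=0) / _MAD_CONST
        s_safe = np.where(s > 0, s, 1.0)
        absr = np.abs(resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.minimum(1.0, c * s_safe / np.where(absr > 0, absr, np.inf))
        xtwx = (z.T @ w).T.reshape(-1, p, p)  # (a, p, p)
        xtwy = (x.T @ (w * resid)).T  # (a, p): solve on residuals, update coef
        delta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
        coef[active] += delta
        done = (np.max(np.abs(delta), axis=1) < tol) | (s <= 0)
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break

    # Huber correction-factor covariance, shared (X'X)^-1 across outcomes
    resid = y - x @ coef.T
    s = np.median(np.abs(resid), axis=0) / _MAD_CONST
    s_safe = np.where(s > 0, s, 1.0)
    u = resid / s_safe
    psi = np.clip(u, -c, c)
    dpsi = (np.abs(u) <= c).astype(float)
    m1 = dpsi.mean(axis=0)
    m1 = np.where(m1 > 0, m1, np.nan)
    kcorr = 1.0 + (p / n) * (m1 - m1**2) / m1**2
    v = kcorr**2 * (psi**2).sum(axis=0) * s_safe**2 / (n - p) / m1**2
    v = np.where(s > 0, v, 0.0)
    se = np.sqrt(np.outer(v, np.diag(xtx_inv)))
    return coef, se, converged


# ---------------------------------------------------------------------------
# EWAS driver
# ---------------------------------------------------------------------------


def _dummies(series: pd.Series, prefix: str) -> pd.DataFrame:
    d = pd.get_dummies(series, prefix=prefix, drop_first=True, dtype=float)
    return d


def build_design(
    phenotypes: pd.DataFrame,
    exposure_cols: list[str],
    covariates: tuple[str, ...],
    cell_props: pd.DataFrame | None,
) -> pd.DataFrame:
    """Assemble the design matrix: intercept, exposure(s), covariates, cells.

    Categorical covariates expand to treatment-coded dummies.  When cell
    proportions are supplied, the first cell column is dropped as the
    reference category (estimated proportions nearly sum to one, so the full
    set would be collinear with the intercept).
    """
    parts = [pd.DataFrame({"intercept": np.ones(len(phenotypes))}, index=phenotypes.index)]
    for col in exposure_cols:
        parts.append(phenotypes[[col]].astype(float))
    for cov in covariates:
        if cov not in phenotypes.columns:
            raise EwasError(f"covariate {cov!r} missing from phenotype table")
        s = phenotypes[cov]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            parts.append(_dummies(s, cov))
        else:
            parts.append(s.to_frame().astype(float))
    if cell_props is not None:
        cp = cell_props.loc[phenotypes.index]
        parts.append(cp.iloc[:, 1:].astype(float))
    design = pd.concat(parts, axis=1)
    # dummies for categories absent from this cohort are identically zero;
    # drop them (and any other degenerate constant column) before fitting
    protected = {"intercept", *exposure_cols}
    nunique = design.nunique(dropna=False)
    drop = [c for c in design.columns if c not in protected and nunique[c] <= 1]
    return design.drop(columns=drop)


def run_ewas(
    cohort: CohortDataset,
    spec: ModelSpec,
    cell_props: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the EWAS for one cohort and model; one row per probe per exposure.

    Returns the interchange table with columns ``probe_id, beta, se, pval, n``
    (plus ``exposure`` in the mutually adjusted parental model, where each
    probe yields a maternal-adjusted-for-paternal row and vice versa).
    Probes whose fit fails are recorded with missing statistics.
    """
    if spec.adjust_cells and cell_props is None:
        raise EwasError("adjust_cells=True but no cell proportions supplied")
    pheno = cohort.phenotypes

    if spec.exposure_mode == "mutual_parental":
        exposure_cols = ["maternal_bmi", "paternal_bmi"]
        mask = (~pheno["maternal_bmi"].isna()) & (~pheno["paternal_bmi"].isna())
        work = pheno.loc[mask].copy()
    else:
        codes, mask = encode_exposure(pheno["maternal_bmi"].to_numpy(), spec.exposure_mode)
        work = pheno.loc[mask].copy()
        work["exposure"] = codes[mask]
        exposure_cols = ["exposure"]

    x_df = build_design(work, exposure_cols, spec.covariates,
                        cell_props if spec.adjust_cells else None)
    # complete-case on the design
    keep = ~x_df.isna().any(axis=1)
    x_df = x_df.loc[keep]
    if len(x_df) == 0:
        raise EwasError("no usable samples after exposure encoding and covariate filtering")
    x = x_df.to_numpy(dtype=float)
    _check_rank(x, list(x_df.columns))
    y_all = cohort.beta.loc[x_df.index]
    n, p = x.shape
    if n <= p:
        raise EwasError(f"too few samples ({n}) for {p} model parameters")

    probe_ids = y_all.columns.to_numpy()
    y = y_all.to_numpy(dtype=float)
    good = ~np.isnan(y).any(axis=0)
    coef = np.full((len(probe_ids), p), np.nan)
    se = np.full((len(probe_ids), p), np.nan)
    if good.any():
        coef_g, se_g, _conv = _huber_fit_batch(
            x, y[:, good], c=spec.huber_c, tol=spec.tol, max_iter=spec.max_iter
        )
        coef[good] = coef_g
        se[good] = se_g
    # probes with partially missing betas: per-probe complete-case fit
    for j in np.flatnonzero(~good):
        okj = ~np.isnan(y[:, j])
        if okj.sum() > p:
            try:
                cj, sj, _ = huber_fit(x[okj], y[okj, j], c=spec.huber_c,
                                      tol=spec.tol, max_iter=spec.max_iter)
                coef[j], se[j] = cj, sj
            except EwasError:
                pass

    def table_for(col: str, label: str | None) -> pd.DataFrame:
        ci = x_df.columns.get_loc(col)
        b, s = coef[:, ci], se[:, ci]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = b / s
        pv = 2.0 * stats.norm.sf(np.abs(z))
        pv = np.where(np.isfinite(pv), np.maximum(pv, np.finfo(float).tiny), np.nan)
        n_used = np.where(good, n, (~np.isnan(y)).sum(axis=0))
        out = pd.DataFrame(
            {"probe_id": probe_ids, "beta": b, "se": s, "pval": pv, "n": n_used.astype(int)}
        )
        if label is not None:
            out.insert(1, "exposure", label)
        return out

    if spec.exposure_mode == "mutual_parental":
        return pd.concat(
            [table_for("maternal_bmi", "maternal"), table_for("paternal_bmi", "paternal")],
            ignore_index=True,
        )
    return table_for(exposure_cols[0], None)
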