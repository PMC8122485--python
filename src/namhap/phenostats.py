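"""Per-trial mixed-model analysis of plot-level phenotypes.

One trial at a time the model is

    y = mu + genotype + block (+ row + range) + residual

with every term after the intercept random and independent.  Variance
components are estimated by REML, profiling the residual variance out of
the likelihood and optimizing the remaining variance ratios by
coordinate-wise golden-section search.  Line BLUPs and their
prediction-error variances (PEV) come from the mixed-model equations at
the REML estimates, and heritability is the generalized form

    H^2 = 1 - mean PEV of line differences / (2 * sigma^2_g),

which handles unbalanced and partially replicated designs where the
classical ratio of variance components does not apply.

The field's 2-D spline spatial surface is intentionally not modelled;
row and range can instead enter as independent random factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "TrialFit",
    "fit_trial",
    "generalized_heritability",
    "selection_summary",
]


@dataclass
class TrialFit:
    """REML fit of one trial/trait: variance components, BLUPs, PEVs."""

    trial_id: str
    trait: str
    sigma2: dict[str, float]  # term -> variance (incl. "residual")
    blups: pd.Series  # line_id -> BLUP (deviation from mu)
    pev: pd.Series  # line_id -> prediction-error variance
    pev_matrix: np.ndarray  # (n_lines, n_lines) PEV of genotype effects
    mu: float
    loglik: float
    n_plots: int
    terms: tuple[str, ...] = field(default=("genotype", "block"))

    @property
    def sigma2_g(self) -> float:
        return self.sigma2["genotype"]

    @property
    def sigma2_e(self) -> float:
        return self.sigma2["residual"]


def _design(factor: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(factor))
    idx = {v: i for i, v in enumerate(levels)}
    z = np.zeros((len(factor), len(levels)))
    z[np.arange(len(factor)), [idx[v] for v in factor]] = 1.0
    return z, levels


def _reml_neg_loglik(
    log10_gammas: np.ndarray,
    y: np.ndarray,
    x: np.ndarray,
    zzts: list[np.ndarray],
) -> float:
    """-2 x restricted log-likelihood profiled over sigma^2_e."""
    n, p = x.shape
    v0 = np.eye(n)
    for g, zzt in zip(10.0 ** log10_gammas, zzts):
        v0 += g * zzt
    try:
        c = np.linalg.cholesky(v0)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    xi = np.linalg.solve(c, x)
    yi = np.linalg.solve(c, y)
    xtvx = xi.T @ xi
    sign, logdet_x = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, xi.T @ yi)
    resid = yi - xi @ beta
    ss = float(resid @ resid)
    if ss <= 0:
        ss = 1e-300
    sigma2e = ss / (n - p)
    return logdet_v + logdet_x + (n - p) * np.log(sigma2e)


def fit_trial(
    table: pd.DataFrame,
    trait: str,
    trial_id: str | None = None,
    spatial_factors: bool = False,
    ratio_tol: float = 1e-8,
    max_sweeps: int = 60,
) -> TrialFit:
    """REML fit of the random-genotype, random-block model for one trial.

    ``table`` uses the plot schema (line_id, trial, block, plot_row,
    plot_range, trait, value).  With ``spatial_factors=True`` plot row
    and range join the model as further independent random effects.
    Returns BLUPs/PEVs for every genotype level including checks.
    """
    df = table[table["trait"] == trait]
    if trial_id is not None:
        df = df[df["trial"] == trial_id]
    else:
        trials = df["trial"].unique()
        if len(trials) != 1:
            raise ValueError("table has several trials; pass trial_id")
        trial_id = trials[0]
    df = df.reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("degenerate design: need at least 2 plots")
    if df["line_id"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")

    y = df["value"].to_numpy(float)
    n = len(y)
    x = np.ones((n, 1))
    zg, geno_levels = _design(df["line_id"])
    zs = [zg]
    terms = ["genotype"]
    if df["block"].nunique() > 1:
        zb, _ = _design(df["block"])
        zs.append(zb)
        terms.append("block")
    if spatial_factors:
        for colname, term in (("plot_row", "row"), ("plot_range", "range")):
            if df[colname].nunique() > 1:
                zz, _ = _design(df[colname].astype(str))
                zs.append(zz)
                terms.append(term)

    # coordinate-wise golden-section search on log10 variance ratios
    zzts = [z @ z.T for z in zs]
    lo, hi = -8.0, 8.0
    gammas = np.zeros(len(zs))
    prev = np.inf
    for _ in range(max_sweeps):
        for j in range(len(zs)):

            def obj(g: float, j=j) -> float:
                gg = gammas.copy()
                gg[j] = g
                return _reml_neg_loglik(gg, y, x, zzts)

            res = minimize_scalar(
                obj, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10}
            )
            gammas[j] = res.x
        cur = _reml_neg_loglik(gammas, y, x, zzts)
        if abs(prev - cur) < ratio_tol:
            break
        prev = cur

    ratios = 10.0 ** gammas
    # residual variance at the optimum
    v0 = np.eye(n)
    for g, zzt in zip(ratios, zzts):
        v0 += g * zzt
    c = np.linalg.cholesky(v0)
    xi = np.linalg.solve(c, x)
    yi = np.linalg.solve(c, y)
    xtvx = xi.T @ xi
    beta = np.linalg.solve(xtvx, xi.T @ yi)
    resid = yi - xi @ beta
    sigma2e = float(resid @ resid) / (n - x.shape[1])
    sigma2e = max(sigma2e, 1e-12)
    sigma2 = {t: float(g * sigma2e) for t, g in zip(terms, ratios)}
    sigma2["residual"] = sigma2e
    # ratios at the search floor are numerically-zero components
    for t, g in zip(terms, ratios):
        if g <= 10.0 ** (lo + 0.5):
            sigma2[t] = 0.0

    # mixed-model equations for BLUPs and PEVs
    z = np.hstack(zs)
    qs = [zz.shape[1] for zz in zs]
    dinv = np.concatenate(
        [
            np.full(q, sigma2e / sigma2[t] if sigma2[t] > 0 else 1e12)
            for q, t in zip(qs, terms)
        ]
    )
    xtx = x.T @ x
    xtz = x.T @ z
    ztz = z.T @ z + np.diag(dinv)
    cmat = np.block([[xtx, xtz], [xtz.T, ztz]])
    rhs = np.concatenate([x.T @ y, z.T @ y])
    cinv = np.linalg.inv(cmat)
    sol = cinv @ rhs
    mu = float(sol[0])
    u = sol[1:]
    ng = qs[0]
    blup_g = u[:ng]
    pev_full = sigma2e * cinv[1 : 1 + ng, 1 : 1 + ng]
    blups = pd.Series(blup_g, index=geno_levels, name="blup")
    pev = pd.Series(np.diag(pev_full), index=geno_levels, name="pev")
    return TrialFit(
        trial_id=str(trial_id),
        trait=trait,
        sigma2=sigma2,
        blups=blups,
        pev=pev,
        pev_matrix=pev_full,
        mu=mu,
        loglik=-0.5 * _reml_neg_loglik(np.log10(np.maximum(ratios, 1e-300)), y, x, zzts),
        n_plots=n,
        terms=tuple(terms),
    )


def generalized_heritability(fit: TrialFit) -> float:
    """Generalized (Cullis) heritability of line means.

    H^2 = 1 - vBLUP/(2 sigma^2_g) with vBLUP the mean prediction-error
    variance of pairwise line-difference BLUPs; clamped to [0, 1].
    Returns 0 when the genetic variance is 0.
    """
    s2g = fit.sigma2_g
    if s2g <= 0:
        return 0.0
    p = fit.pev_matrix
    n = p.shape[0]
    if n < 2:
        return 0.0
    d = np.diag(p)
    # sum over ordered pairs i != j of (PEV_ii + PEV_jj - 2 PEV_ij)
    total = (n - 1) * d.sum() * 2.0 - 2.0 * (p.sum() - np.trace(p))
    npairs = n * (n - 1)
    vdiff = total / npairs
    h2 = 1.0 - vdiff / (2.0 * s2g)
    return float(min(max(h2, 0.0), 1.0))


def selection_summary(
    blups: pd.Series,
    maturity_checks: tuple[str, str] | None = None,
    height_max: float | None = None,
    height_blups: pd.Series | None = None,
) -> pd.DataFrame:
    """Fractions of lines inside the maturity window and below the height
    cap.

    ``maturity_checks`` names the early and late check varieties whose
    BLUPs bound the acceptance window (inclusive); ``height_max`` is a
    strict upper bound applied to ``height_blups`` (or ``blups`` when the
    height predictions live in the same series).  Check entries are not
    counted among the candidate lines.
    """
    rows = []
    if maturity_checks is not None:
        early, late = maturity_checks
        for chk in (early, late):
            if chk not in blups.index:
                raise KeyError(f"check {chk!r} absent from BLUPs")
        lo, hi = sorted((blups[early], blups[late]))
        lines = blups.drop(index=[early, late])
        frac = float(((lines >= lo) & (lines <= hi)).mean()) if len(lines) else np.nan
        rows.append(("maturity_window", lo, hi, len(lines), frac))
    if height_max is not None:
        hseries = height_blups if height_blups is not None else blups
        lines = hseries
        if maturity_checks is not None and height_blups is None:
            lines = hseries.drop(index=list(maturity_checks), errors="ignore")
        frac = float((lines < height_max).mean()) if len(lines) else np.nan
        rows.append(("height_below", -np.inf, height_max, len(lines), frac))
    return pd.DataFrame(
        rows, columns=["criterion", "low", "high", "n_lines", "fraction"]
    )
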