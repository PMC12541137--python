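"""Deer-density index construction and beta-regression overlap models.

The *cervid index* pools pellet-group counts of all four deer species on
a transect's fixed-area plots (100 m^2 for the large-bodied moose/red
deer class, 10 m^2 for the small roe/fallow class) and standardizes to
pellet groups per 100 m^2 of surveyed area.  Transects with fewer than
12 of the 16 plots surveyed are excluded, and transects with an index
above 25 pellet groups / 100 m^2 are removed as outliers.

Diet-overlap values (Pianka indices, bounded in [0, 1]) are modelled with
beta regression: y ~ Beta(mu * phi, (1 - mu) * phi), logit(mu) = X beta,
constant precision phi on the log scale, fitted by maximum likelihood.
Exact 0/1 responses are compressed with the standard adjustment
y' = (y (n - 1) + 0.5) / n before fitting (only when a stratum actually
contains boundary values).  The reported pseudo-R^2 is the squared
correlation between logit(y) and logit(fitted mu).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from statsmodels.othermod.betareg import BetaModel

from .io_model import CovariateTable, OverlapTable, PelletCountTable

MIN_PLOTS = 12           #: of the 16 per transect, required surveyed
OUTLIER_INDEX = 25.0     #: pellet groups / 100 m^2 above which removed
PREDICTORS = ("cervid_index", "habitat_shannon", "arable_prop")
COLLINEARITY_LIMIT = 0.3


def cervid_index(pellets: PelletCountTable,
                 min_plots: int = MIN_PLOTS,
                 outlier: float = OUTLIER_INDEX) -> pd.DataFrame:
    """Per-transect pooled pellet-group density (groups / 100 m^2).

    Surveyed area counts each distinct (plot, species class) once at its
    plot area, so the index is invariant to splitting one plot's count
    over several rows.  Returns columns transect_id, cervid_index,
    n_plots_surveyed, excluded, exclusion_reason.
    """
    frame = pellets.frame
    rows = []
    for tr, grp in frame.groupby("transect_id", sort=True):
        surveyed = grp[grp["surveyed"]]
        n_plots = surveyed["plot_id"].nunique()
        if n_plots < min_plots:
            rows.append({"transect_id": tr, "cervid_index": float("nan"),
                         "n_plots_surveyed": n_plots, "excluded": True,
                         "exclusion_reason": "too_few_plots"})
            continue
        area = surveyed.drop_duplicates(
            ["plot_id", "species_class"])["plot_area_m2"].sum()
        groups = surveyed["pellet_groups"].sum()
        idx = groups / area * 100.0
        if idx > outlier:
            rows.append({"transect_id": tr, "cervid_index": float(idx),
                         "n_plots_surveyed": n_plots, "excluded": True,
                         "exclusion_reason": "outlier"})
        else:
            rows.append({"transect_id": tr, "cervid_index": float(idx),
                         "n_plots_surveyed": n_plots, "excluded": False,
                         "exclusion_reason": ""})
    return pd.DataFrame(rows)


def boundary_adjust(y, n: int) -> np.ndarray:
    """Compress [0, 1] responses into (0, 1): y' = (y (n-1) + 0.5) / n."""
    y = np.asarray(y, dtype=float)
    return (y * (n - 1) + 0.5) / n


@dataclass
class BetaRegFit:
    """Maximum-likelihood beta-regression fit summary."""

    params: pd.Series          # intercept + slope per predictor
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    phi: float
    pseudo_r2: float
    loglik: float
    n: int
    converged: bool
    description: str = ""

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})


def betareg_fit(y, X: pd.DataFrame, description: str = "") -> BetaRegFit:
    """Fit logit-link beta regression of y on X (+ intercept) by ML.

    ``y`` must lie strictly inside (0, 1) (apply :func:`boundary_adjust`
    first if needed).  Raises on rank-deficient design or values outside
    the open interval.
    """
    y = np.asarray(y, dtype=float)
    if ((y <= 0) | (y >= 1)).any():
        raise ValueError("response values must be strictly inside (0, 1); "
                         "apply boundary_adjust first")
    X = pd.DataFrame(X).astype(float).reset_index(drop=True)
    design = X.copy()
    design.insert(0, "intercept", 1.0)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix "
                         "(duplicate or constant predictor?)")
    if len(y) < design.shape[1] + 2:
        raise ValueError("too few observations for the number of "
                         "predictors")
    # default links: logit for the mean, log for the precision
    model = BetaModel(y, design, exog_precision=np.ones((len(y), 1)))
    res = model.fit(disp=False)
    if not np.isfinite(res.llf):
        raise RuntimeError("beta regression failed to converge")
    k = design.shape[1]
    names = list(design.columns)
    params_all = np.asarray(res.params, dtype=float)
    bse_all = np.asarray(res.bse, dtype=float)
    params = pd.Series(params_all[:k], index=names)
    bse = pd.Series(bse_all[:k], index=names)
    zvals = params / bse
    from scipy.stats import norm
    pvals = 2 * norm.sf(np.abs(zvals))
    phi = float(np.exp(params_all[k]))
    mu_hat = expit(design.to_numpy() @ params.to_numpy())
    r = np.corrcoef(logit(mu_hat), logit(y))[0, 1] if len(y) > 2 else \
        float("nan")
    pseudo_r2 = float(r ** 2) if np.isfinite(r) else float("nan")
    converged = bool(getattr(res.mle_retvals, "get",
                             lambda *_: True)("converged", True))
    return BetaRegFit(params=params, bse=bse, zvalues=zvals,
                      pvalues=pd.Series(pvals, index=names), phi=phi,
                      pseudo_r2=pseudo_r2, loglik=float(res.llf), n=len(y),
                      converged=converged, description=description)


def beta_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Beta log-likelihood with mean/precision parameterization."""
    from scipy.special import gammaln
    a = mu * phi
    b = (1 - mu) * phi
    return float(np.sum(gammaln(phi) - gammaln(a) - gammaln(b)
                        + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y)))


def collinearity_flags(covariates: CovariateTable,
                       limit: float = COLLINEARITY_LIMIT) -> pd.DataFrame:
    """Pairwise predictor correlations, flagged above the screening limit."""
    frame = covariates.frame[list(PREDICTORS)]
    corr = frame.corr()
    rows = []
    for i, a in enumerate(PREDICTORS):
        for b in PREDICTORS[i + 1:]:
            r = float(corr.loc[a, b])
            rows.append({"predictor_a": a, "predictor_b": b,
                         "correlation": r, "flagged": abs(r) > limit})
    return pd.DataFrame(rows)


def drivers_analysis(overlaps: OverlapTable, covariates: CovariateTable,
                     min_n: int = 8, alpha: float = 0.05
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Beta-regression of overlap on density, habitat diversity and arable
    land, per landscape x season x species (intra) or pair (inter).

    Strata with fewer than ``min_n`` transect observations are skipped
    with a note.  Returns (coefficient table, skipped-strata table,
    collinearity flags); the coefficient table lists one row per
    coefficient with a ``significant`` column at ``alpha``.
    """
    cov = covariates.frame[covariates.frame["cervid_index"].notna()]
    merged = overlaps.frame.merge(cov, on="transect_id", how="inner")
    fits, skipped = [], []
    for key, grp in merged.groupby(
            ["landscape", "season", "kind", "species_a", "species_b"],
            sort=True):
        desc = "{}:{}:{}:{}-{}".format(*key)
        if len(grp) < min_n:
            skipped.append({"landscape": key[0], "season": key[1],
                            "kind": key[2], "species_a": key[3],
                            "species_b": key[4], "n": len(grp),
                            "note": f"fewer than {min_n} transects"})
            continue
        y = grp["pianka"].to_numpy()
        if ((y <= 0) | (y >= 1)).any():
            y = boundary_adjust(y, len(y))
        X = grp[list(PREDICTORS)]
        try:
            fit = betareg_fit(y, X, description=desc)
        except (ValueError, RuntimeError) as exc:
            skipped.append({"landscape": key[0], "season": key[1],
                            "kind": key[2], "species_a": key[3],
                            "species_b": key[4], "n": len(grp),
                            "note": f"fit failed: {exc}"})
            continue
        for name in fit.params.index:
            fits.append({
                "landscape": key[0], "season": key[1], "kind": key[2],
                "species_a": key[3], "species_b": key[4], "term": name,
                "beta": float(fit.params[name]),
                "se": float(fit.bse[name]),
                "z": float(fit.zvalues[name]),
                "p": float(fit.pvalues[name]),
                "phi": fit.phi, "pseudo_r2": fit.pseudo_r2, "n": fit.n,
                "converged": fit.converged,
                "significant": bool(fit.pvalues[name] < alpha
                                    and name != "intercept")})
    coef = pd.DataFrame(fits)
    skip = pd.DataFrame(skipped)
    flags = collinearity_flags(covariates)
    return coef, skip, flags
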