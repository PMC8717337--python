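"""Ordination and gradient regression.

PCoA follows the classical Gower construction: eigendecomposition of the
double-centered matrix -0.5 * D^2, scores scaled by the square roots of the
positive eigenvalues.  Negative eigenvalues (possible for non-Euclidean
dissimilarities such as Sorensen/PhyloSor) are reported, not corrected, so
users can judge the distortion.  Axis signs follow a fixed convention (the
largest-magnitude score on each axis is positive) for reproducible plots.

Regressions of community metrics on soil base-cation concentration use OLS
with a linear and a second-order polynomial model; the predictor is log10
cation concentration by default (raw scale available).  Both fits are always
reported with adjusted R^2 and the model F-test p-value; a display flag marks
p < .05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .beta import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = ["OrdinationResult", "pcoa", "envfit_axes", "fit_gradient_models"]


@dataclass
class OrdinationResult:
    sites: tuple[str, ...]
    scores: np.ndarray          # (n_sites, k), centered columns
    eigenvalues: np.ndarray     # all n eigenvalues, decreasing (may be negative)
    relative_eigenvalues: np.ndarray  # share of total positive eigenvalue mass

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=list(self.sites), columns=cols)


def pcoa(beta: BetaMatrix | np.ndarray, k: int = 2,
         sites: Sequence[str] | None = None) -> OrdinationResult:
    """Principal coordinates analysis of a dissimilarity matrix."""
    if isinstance(beta, BetaMatrix):
        D = beta.values
        sites = beta.sites
    else:
        D = np.asarray(beta, dtype=float)
        sites = tuple(sites) if sites is not None else tuple(
            f"site{i + 1}" for i in range(D.shape[0]))
    if np.isnan(D).any():
        raise ValueError("dissimilarity matrix contains missing values")
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    eigval, eigvec = scipy.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    pos = eigval > max(eigval.max(), 0) * 1e-12 if eigval.max() > 0 else np.zeros(n, bool)
    n_pos = int(pos.sum())
    if k > n_pos:
        logger.warning("requested %d axes but only %d positive eigenvalues; truncating",
                       k, n_pos)
        k = n_pos
    scores = eigvec[:, :k] * np.sqrt(eigval[:k])
    # deterministic orientation: largest-|score| entry positive on each axis
    for j in range(k):
        col = scores[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col
    total_pos = eigval[pos].sum() if n_pos else np.nan
    rel = eigval / total_pos if n_pos else np.full(n, np.nan)
    return OrdinationResult(sites=tuple(sites), scores=scores,
                            eigenvalues=eigval, relative_eigenvalues=rel)


_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "log10": np.log10,
    "log": np.log,
}


def envfit_axes(ordination: OrdinationResult, env: pd.DataFrame,
                variables: Mapping[str, str]) -> pd.DataFrame:
    """Correlation arrows of (transformed) environment variables with axes 1-2.

    ``variables`` maps column name -> transform ('identity', 'log10', 'log').
    Returns one row per variable with the Pearson correlations (r1, r2);
    zero-variance variables get a missing arrow with a log entry.
    """
    if ordination.scores.shape[1] < 2:
        raise ValueError("envfit_axes needs at least two ordination axes")
    env = env.set_index("site") if "site" in env.columns and env.index.name != "site" \
        else env
    env = env.loc[list(ordination.sites)]
    ax1, ax2 = ordination.scores[:, 0], ordination.scores[:, 1]
    rows = []
    for var, tf in variables.items():
        x = _TRANSFORMS[tf](env[var].to_numpy(dtype=float))
        if np.nanstd(x) == 0 or np.isnan(x).all():
            logger.warning("variable %s has zero variance; arrow omitted", var)
            rows.append((var, tf, np.nan, np.nan))
            continue
        r1 = np.corrcoef(x, ax1)[0, 1]
        r2 = np.corrcoef(x, ax2)[0, 1]
        rows.append((var, tf, r1, r2))
    return pd.DataFrame(rows, columns=["variable", "transform", "r_axis1", "r_axis2"])


def _fit_poly(x: np.ndarray, y: np.ndarray, degree: int) -> dict:
    """OLS polynomial fit on centered x; coefficients in the raw basis."""
    xc = x - x.mean()
    X = np.column_stack([xc**d for d in range(degree + 1)])
    model = sm.OLS(y, X).fit()
    # back-transform centered-basis coefficients to the raw polynomial basis
    raw = np.polynomial.polynomial.Polynomial(model.params)(
        np.polynomial.polynomial.Polynomial([-x.mean(), 1.0]))
    coef = np.zeros(degree + 1)
    coef[: len(raw.coef)] = raw.coef
    return {
        "coefficients": coef,  # [intercept, b1, (b2)]
        "r2": float(model.rsquared),
        "adj_r2": float(model.rsquared_adj),
        "p": float(model.f_pvalue) if model.df_model > 0 else np.nan,
        "p_highest_order": float(model.pvalues[-1]),
        "n": int(model.nobs),
    }


def fit_gradient_models(
    metrics_table: pd.DataFrame,
    env: pd.DataFrame,
    metrics: Sequence[str],
    predictor: str = "log10",
    p_from: str = "f",
) -> pd.DataFrame:
    """Linear and quadratic regressions of each metric on base-cation concentration.

    ``metrics_table`` must carry a ``site`` column plus one column per metric;
    sites with a missing metric value are dropped (logged).  ``predictor`` is
    'log10' (default) or 'raw'; ``p_from`` chooses the significance measure for
    the display flag: the model F-test ('f', default) or the highest-order
    coefficient's t-test ('t').  Metrics with fewer than 4 usable sites are
    skipped.
    """
    if predictor not in ("log10", "raw"):
        raise ValueError("predictor must be 'log10' or 'raw'")
    if p_from not in ("f", "t"):
        raise ValueError("p_from must be 'f' or 't'")
    env_idx = env.set_index("site") if env.index.name != "site" else env
    tbl = metrics_table.set_index("site") if "site" in metrics_table.columns \
        else metrics_table
    cation = env_idx.loc[tbl.index, "base_cation"].to_numpy(dtype=float)
    x_all = np.log10(cation) if predictor == "log10" else cation

    rows = []
    for metric in metrics:
        y_all = tbl[metric].to_numpy(dtype=float)
        ok = ~np.isnan(y_all) & ~np.isnan(x_all)
        if (~ok).any():
            logger.info("%s: dropping %d site(s) with missing values", metric,
                        int((~ok).sum()))
        if ok.sum() < 4:
            logger.warning("%s: only %d usable sites (<4); skipped", metric, int(ok.sum()))
            continue
        x, y = x_all[ok], y_all[ok]
        lin = _fit_poly(x, y, 1)
        quad = _fit_poly(x, y, 2)
        p_lin = lin["p"] if p_from == "f" else lin["p_highest_order"]
        p_quad = quad["p"] if p_from == "f" else quad["p_highest_order"]
        rows.append({
            "metric": metric,
            "predictor": f"{predictor}(base_cation)" if predictor == "log10"
                         else "base_cation",
            "n": lin["n"],
            "linear_intercept": lin["coefficients"][0],
            "linear_slope": lin["coefficients"][1],
            "linear_r2": lin["r2"],
            "linear_adj_r2": lin["adj_r2"],
            "linear_p": p_lin,
            "linear_significant": bool(p_lin < 0.05),
            "quad_b0": quad["coefficients"][0],
            "quad_b1": quad["coefficients"][1],
            "quad_b2": quad["coefficients"][2],
            "quad_r2": quad["r2"],
            "quad_adj_r2": quad["adj_r2"],
            "quad_p": p_quad,
            "quad_significant": bool(p_quad < 0.05),
        })
    return pd.DataFrame(rows)
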