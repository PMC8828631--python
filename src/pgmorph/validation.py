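"""Method validation regression and effect-size PCA.

Two checks establish that image-derived morphometry is trustworthy and
summarise how stress types differ:

* ``validation_regression`` — per parameter, ordinary least squares of
  image-measured values on the values the same articles report in tables,
  with a Kendall tau-b rank correlation and a test of the fitted slope
  against the ideal 1:1 relation.
* ``es_pca`` — principal component analysis of the stress-type × attribute
  mean effect-size matrix; effect sizes are commensurate log-ratios, so the
  PCA is centred but unscaled by default (unit-variance scaling available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA


# ---------------------------------------------------------------------------
# reported-vs-measured regression
# ---------------------------------------------------------------------------

def _regress_one(reported: np.ndarray, measured: np.ndarray) -> dict:
    if np.ptp(reported) == 0:
        raise ValueError("degenerate reported values (constant)")
    X = sm.add_constant(reported)
    fit = sm.OLS(measured, X).fit()
    intercept, slope = fit.params
    slope_se = fit.bse[1]
    # H0: slope = 1, via the slope's standard error; an exact fit has zero
    # residual, so the test degenerates to an equality check
    if slope_se > 0:
        t_stat = (slope - 1.0) / slope_se
        p_slope_one = 2.0 * stats.t.sf(abs(t_stat), df=fit.df_resid)
    else:
        t_stat = 0.0 if np.isclose(slope, 1.0) else np.inf
        p_slope_one = 1.0 if np.isclose(slope, 1.0) else 0.0
    # companion least-squares comparison: residual sums of the fitted line
    # versus the best line with slope fixed at 1
    rss_fit = float(fit.ssr)
    rss_slope1 = float(np.sum(
        (measured - reported - np.mean(measured - reported)) ** 2))
    tau, tau_p = stats.kendalltau(reported, measured)  # tau-b (tie-corrected)
    return {
        "slope": float(slope), "intercept": float(intercept),
        "slope_se": float(slope_se),
        "kendall_tau": float(tau), "kendall_p": float(tau_p),
        "slope_vs_one_t": float(t_stat),
        "slope_vs_one_p": float(p_slope_one),
        "rss_fit": rss_fit, "rss_slope_one": rss_slope1,
        "n": int(len(reported)),
    }


def validation_regression(pairs: pd.DataFrame) -> pd.DataFrame:
    """Reported-vs-measured regression, one row per parameter.

    ``pairs`` needs columns ``parameter, reported_value, measured_value``
    (an ``article_id`` column is carried along if present); each parameter
    needs at least three finite pairs.
    """
    required = {"parameter", "reported_value", "measured_value"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    rows = []
    for param, group in pairs.groupby("parameter", sort=True):
        reported = group["reported_value"].to_numpy(dtype=float)
        measured = group["measured_value"].to_numpy(dtype=float)
        ok = np.isfinite(reported) & np.isfinite(measured)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 finite pairs for {param!r}")
        rows.append({"parameter": param,
                     **_regress_one(reported[ok], measured[ok])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA of the stress × attribute effect-size matrix
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Explained variance (%), loadings (attribute × PC), scores (row × PC)."""

    explained_variance_pct: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    mean: pd.Series
    scale: pd.Series | None


def es_pca(matrix: pd.DataFrame, *,
           scale_to_unit_variance: bool = False,
           impute_missing: bool = False) -> PCAResult:
    """Centred PCA of a stress-type × attribute mean-ES matrix.

    Components are ordered by variance; for reproducibility each component's
    sign is fixed so its largest-magnitude loading is positive.  Missing
    cells are an error unless ``impute_missing`` replaces them with the
    column (attribute) mean.
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 rows (stress types)")
    X = matrix.astype(float).copy()
    if X.isna().any().any():
        if not impute_missing:
            raise ValueError("missing cells; pass impute_missing=True "
                             "to mean-impute")
        X = X.fillna(X.mean())
    scale = None
    values = X.to_numpy()
    if scale_to_unit_variance:
        scale = pd.Series(values.std(axis=0, ddof=1), index=X.columns)
        if (scale == 0).any():
            raise ValueError("zero-variance attribute cannot be scaled")
        values = values / scale.to_numpy()

    n_comp = min(values.shape[0] - 1, values.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(values)
    loadings = pca.components_.T  # attribute × component

    # sign convention: largest-|loading| entry positive per component
    for j in range(n_comp):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    return PCAResult(
        explained_variance_pct=100.0 * pca.explained_variance_ratio_,
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        mean=pd.Series(pca.mean_ * (scale.to_numpy() if scale is not None
                                    else 1.0), index=X.columns),
        scale=scale)


def es_matrix(summary: pd.DataFrame, *,
              exclude_pooled: bool = True) -> pd.DataFrame:
    """Pivot a stress summary table into the stress × attribute ES matrix."""
    table = summary
    if exclude_pooled:
        from .meta import POOLED_LABEL
        table = summary[summary["stress_type"] != POOLED_LABEL]
    return table.pivot(index="stress_type", columns="attribute",
                       values="mean_es")


def save_biplot(result: PCAResult, path, *, components=(1, 2)) -> None:
    """Write a simple PCA biplot (scores + loading arrows) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = components[0] - 1, components[1] - 1
    fig, ax = plt.subplots(figsize=(6, 6))
    sc = result.scores.to_numpy()
    ax.scatter(sc[:, i], sc[:, j], color="tab:grey")
    for name, (x, y) in zip(result.scores.index, sc[:, [i, j]]):
        ax.annotate(str(name), (x, y), fontsize=8)
    arrow_scale = 0.9 * np.abs(sc[:, [i, j]]).max() or 1.0
    for attr, row in result.loadings.iterrows():
        ax.annotate("", xy=(row.iloc[i] * arrow_scale,
                            row.iloc[j] * arrow_scale),
                    xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="tab:blue"))
        ax.annotate(str(attr), (row.iloc[i] * arrow_scale,
                                row.iloc[j] * arrow_scale),
                    color="tab:blue", fontsize=8)
    var = result.explained_variance_pct
    ax.set_xlabel(f"PC{components[0]} ({var[i]:.1f}%)")
    ax.set_ylabel(f"PC{components[1]} ({var[j]:.1f}%)")
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
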