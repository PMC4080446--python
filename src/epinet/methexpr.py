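"""Methylation-expression relationship: rank correlation, OLS line and a
95% prediction band.

Genes present in both matrices contribute one point (x = mean methylation
beta, y = mean expression over the chosen group's samples). The prediction
interval at x0 is ŷ(x0) ± t_{1−(1−level)/2, n−2} · s · sqrt(1 + 1/n +
(x0 − x̄)²/Sxx); a gene is flagged as methylation-coupled when its point
lies inside the band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import CASE, GeneProfileMatrix, RegressionFit


def gene_level_pairs(
    meth: GeneProfileMatrix, expr: GeneProfileMatrix, group: str = CASE
) -> pd.DataFrame:
    """Per-gene (mean methylation, mean expression) over the shared genes."""
    shared = meth.genes.intersection(expr.genes)
    x = meth.group_means(group).loc[shared]
    y = expr.group_means(group).loc[shared]
    return pd.DataFrame({"x": x, "y": y})


def spearman(pairs: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation with average ranks; p via t approximation."""
    x, y = pairs["x"].to_numpy(float), pairs["y"].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero rank variance: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def fit_line(pairs: pd.DataFrame, level: float = 0.95) -> RegressionFit:
    """OLS fit of y on x with prediction-interval geometry and Spearman rho."""
    x, y = pairs["x"].to_numpy(float), pairs["y"].to_numpy(float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs to fit")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    resid_sd = float(np.sqrt(model.scale))  # sqrt(SSR / (n - 2))
    x_mean = float(x.mean())
    sxx = float(((x - x_mean) ** 2).sum())
    if sxx == 0:
        raise ValueError("x has zero variance")
    t_crit = float(stats.t.ppf(1 - (1 - level) / 2, n - 2))
    rho, rho_p = spearman(pairs)
    return RegressionFit(
        slope=float(slope),
        intercept=float(intercept),
        resid_sd=resid_sd,
        n=n,
        level=level,
        x_mean=x_mean,
        sxx=sxx,
        t_crit=t_crit,
        spearman_rho=rho,
        spearman_p=rho_p,
    )


def flag_within_interval(
    fit: RegressionFit, pairs: pd.DataFrame
) -> tuple[pd.Series, int]:
    """Boolean flag per gene: expression inside the prediction band."""
    lower, upper = fit.interval(pairs["x"].to_numpy(float))
    y = pairs["y"].to_numpy(float)
    inside = pd.Series((y >= lower) & (y <= upper), index=pairs.index,
                       name="within_interval")
    return inside, int(inside.sum())


def plot_fit(fit: RegressionFit, pairs: pd.DataFrame, path) -> None:
    """Scatter of the gene-level points with the fitted line and band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = np.linspace(pairs["x"].min(), pairs["x"].max(), 200)
    lower, upper = fit.interval(xs)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(pairs["x"], pairs["y"], s=4, alpha=0.3, label="genes")
    ax.plot(xs, fit.predict(xs), "r-",
            label=f"y = {fit.slope:.3f}x + {fit.intercept:.3f}")
    ax.fill_between(xs, lower, upper, alpha=0.15, color="red",
                    label=f"{int(fit.level * 100)}% prediction interval")
    ax.set_xlabel("mean methylation (beta)")
    ax.set_ylabel("mean expression")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
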