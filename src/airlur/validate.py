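"""Model validation: leave-one-out, cross-campaign transfer, comparison.

R-squared throughout is the squared Pearson correlation between observed
and predicted values (the scatter-plot sense); the variance explained
against the 1:1 line, 1 - SSE/SST, is reported alongside as ``r2_identity``
because the two differ exactly when predictions are biased or mis-scaled.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .lur import LURModel, fit_coefficients, predict


@dataclass
class ValidationReport:
    r2: float  # squared Pearson correlation
    r2_identity: float  # 1 - SSE/SST against the 1:1 line
    slope: float  # observed ~ predicted OLS slope
    intercept: float
    mean_residual: float  # mean(observed - predicted)
    n: int
    mean_residual_by_type: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _report(observed, predicted, site_types=None) -> ValidationReport:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) < 3:
        raise ValueError("need at least 3 observed/predicted pairs")
    if np.std(pred) == 0 or np.std(obs) == 0:
        r2 = 0.0
        slope = 0.0
    else:
        r = np.corrcoef(obs, pred)[0, 1]
        r2 = float(r * r)
        slope = float(np.polyfit(pred, obs, 1)[0])
    sst = float(np.sum((obs - obs.mean()) ** 2))
    sse = float(np.sum((obs - pred) ** 2))
    r2_identity = 1.0 - sse / sst if sst > 0 else 0.0
    resid = obs - pred
    by_type = {}
    if site_types is not None:
        st = pd.Series(np.asarray(site_types), index=range(len(obs)))
        for t, idx in st.groupby(st).groups.items():
            by_type[str(t)] = float(resid[np.asarray(idx)].mean())
    return ValidationReport(
        r2=r2,
        r2_identity=r2_identity,
        slope=slope,
        intercept=float(obs.mean() - slope * pred.mean()),
        mean_residual=float(resid.mean()),
        n=len(obs),
        mean_residual_by_type=by_type,
    )


def loocv(y, table: pd.DataFrame, variables: list[str], site_types=None) -> ValidationReport:
    """Leave-one-out cross-validation of a fixed variable set.

    The selection path is not re-run per fold; only the coefficients are
    refit on the n-1 remaining sites, and the held-out site is predicted.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    preds = np.empty(n)
    idx = np.arange(n)
    X = table[list(variables)].to_numpy(float)
    for i in range(n):
        keep = idx != i
        res = fit_coefficients(y[keep], table.iloc[keep], list(variables))
        preds[i] = float(res.params[0] + X[i] @ res.params[1:])
    return _report(y, preds, site_types)


def external_validate(
    model: LURModel, y_other, table_other: pd.DataFrame, site_types=None
) -> ValidationReport:
    """Score a frozen model against another campaign; no refitting."""
    preds = predict(model, table_other)
    return _report(np.asarray(y_other, dtype=float), preds, site_types)


def in_sample(model: LURModel, y, table: pd.DataFrame, site_types=None) -> ValidationReport:
    return external_validate(model, y, table, site_types)


def compare_predictions(pred_a, pred_b) -> dict:
    """Agreement between two prediction vectors.

    Returns squared Pearson correlation (symmetric), the OLS slope of b on
    a, and the mean difference b - a.
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        r2, slope = 0.0, 0.0
    else:
        r = np.corrcoef(a, b)[0, 1]
        r2 = float(r * r)
        slope = float(np.polyfit(a, b, 1)[0])
    return {"r2": r2, "slope": slope, "mean_difference": float(np.mean(b - a))}


def scatter_plot(observed, predicted, path, title: str = "", site_types=None) -> None:
    """Observed-vs-predicted scatter with the 1:1 line (optional extra).

    Requires matplotlib; colours by site type when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    if site_types is not None:
        st = np.asarray(site_types)
        for t in np.unique(st):
            ax.scatter(pred[st == t], obs[st == t], s=18, label=str(t), alpha=0.8)
        ax.legend(fontsize=7)
    else:
        ax.scatter(pred, obs, s=18, alpha=0.8)
    lo = min(obs.min(), pred.min())
    hi = max(obs.max(), pred.max())
    ax.plot([lo, hi], [lo, hi], ls=":", c="k", lw=1)
    rep = _report(obs, pred)
    ax.set_xlabel("predicted NO2 (ug/m3)")
    ax.set_ylabel("observed NO2 (ug/m3)")
    ax.set_title(f"{title} R2={rep.r2:.2f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def residual_summary(observed, predicted, site_types) -> dict:
    """Mean residuals overall, per site type, and in the top quartile.

    The top-concentration-quartile residual is the hot-spot diagnostic: a
    positive value means the model underestimates the most polluted sites.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    resid = obs - pred
    st = np.asarray(site_types)
    q75 = np.percentile(obs, 75)
    top = obs >= q75
    return {
        "overall": float(resid.mean()),
        "by_type": {str(t): float(resid[st == t].mean()) for t in np.unique(st)},
        "top_quartile": float(resid[top].mean()),
        "top_quartile_threshold": float(q75),
    }
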