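"""Association of territory-averaged perfusion parameters with outcome.

Each angiography series contributes one row of eight features — the average
CBV, CBF, MTT and Tmax over the internal-carotid-artery (ICA) and
middle-cerebral-artery (MCA) territories — and a binary functional-outcome
label (favorable vs. unfavorable).  A maximum-likelihood logistic regression
on all eight features jointly yields per-feature odds ratios with Wald
p-values and an in-sample ROC AUC.

Features are z-scored before fitting, so the reported odds ratios are per
standard deviation of each feature; the perfusion parameters are in relative
units and their raw scale is not comparable across processing choices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconv import ParametricMaps
from .maps import territory_summary

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "ica_cbv", "ica_cbf", "ica_mtt", "ica_tmax",
    "mca_cbv", "mca_cbf", "mca_mtt", "mca_tmax",
]


def build_features(
    maps_list: list[ParametricMaps],
    ica_masks: list[np.ndarray],
    mca_masks: list[np.ndarray],
    labels: list[int],
    series_ids: list[str] | None = None,
) -> pd.DataFrame:
    """One feature row per series: territory means of the four parameters.

    Series whose ICA or MCA territory contains no valid perfusion pixel are
    dropped (with a logged count); the returned frame has the eight feature
    columns, the binary ``outcome`` and a ``series_id`` index.
    """
    n = len(maps_list)
    if not (len(ica_masks) == len(mca_masks) == len(labels) == n):
        raise ValueError("maps, masks and labels must have equal length")
    ids = series_ids if series_ids is not None else [f"series{i}" for i in range(n)]
    rows, dropped = [], 0
    for sid, maps, ica, mca, y in zip(ids, maps_list, ica_masks, mca_masks, labels):
        try:
            s_ica = territory_summary(maps, ica, "ica")
            s_mca = territory_summary(maps, mca, "mca")
        except ValueError:
            dropped += 1
            continue
        rows.append({
            "series_id": sid,
            "ica_cbv": s_ica.mean_cbv, "ica_cbf": s_ica.mean_cbf,
            "ica_mtt": s_ica.mean_mtt, "ica_tmax": s_ica.mean_tmax,
            "mca_cbv": s_mca.mean_cbv, "mca_cbf": s_mca.mean_cbf,
            "mca_mtt": s_mca.mean_mtt, "mca_tmax": s_mca.mean_tmax,
            "outcome": int(y),
        })
    if dropped:
        logger.warning("dropped %d series with an empty territory", dropped)
    df = pd.DataFrame(rows).set_index("series_id") if rows else pd.DataFrame(
        columns=FEATURE_COLUMNS + ["outcome"]
    )
    df.attrs["n_dropped"] = dropped
    return df


@dataclass
class LogisticReport:
    """Fit summary: per-feature effects, model AUC, overall LR test."""

    coefficients: dict[str, float]
    odds_ratios: dict[str, float]
    wald_z: dict[str, float]
    p_values: dict[str, float]
    auc: float
    lr_pvalue: float
    n: int
    separation_flag: bool = False
    feature_means: dict[str, float] = field(default_factory=dict)
    feature_stds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "auc": self.auc,
            "lr_pvalue": self.lr_pvalue,
            "separation_flag": self.separation_flag,
            "features": {
                name: {
                    "coefficient": self.coefficients[name],
                    "odds_ratio": self.odds_ratios[name],
                    "wald_z": self.wald_z[name],
                    "p_value": self.p_values[name],
                }
                for name in self.coefficients
            },
        }


def fit_outcome_model(
    table: pd.DataFrame, feature_columns: list[str] | None = None
) -> LogisticReport:
    """Logistic regression of the binary outcome on z-scored features.

    Requires at least two rows in each outcome class.  Perfect separation is
    reported through ``separation_flag`` rather than raised.
    """
    import statsmodels.api as sm
    from sklearn.metrics import roc_auc_score

    cols = feature_columns or FEATURE_COLUMNS
    y = table["outcome"].to_numpy(dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("single-class outcome: both labels must be present")
    if counts.min() < 2:
        raise ValueError("need at least 2 rows per outcome class")
    X = table[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant feature: leave centered at 0
    Z = (X - mu) / sd

    exog = sm.add_constant(Z, has_constant="add")
    separation = False
    model = sm.Logit(y, exog)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            separation = True
    except Exception:  # perfect separation or singular fit
        separation = True
        with np.errstate(all="ignore"):
            res = model.fit_regularized(alpha=1e-4, disp=0, maxiter=500)

    params = np.asarray(res.params)[1:]
    try:
        bse = np.asarray(res.bse)[1:]
        with np.errstate(all="ignore"):
            zstat = params / bse
        pvals = np.asarray(res.pvalues)[1:]
    except Exception:
        zstat = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
    try:
        lr_p = float(res.llr_pvalue)
    except Exception:
        lr_p = float("nan")

    scores = res.predict(exog)
    auc = float(roc_auc_score(y, scores))
    return LogisticReport(
        coefficients={c: float(b) for c, b in zip(cols, params)},
        odds_ratios={c: float(np.exp(b)) for c, b in zip(cols, params)},
        wald_z={c: float(v) for c, v in zip(cols, zstat)},
        p_values={c: float(v) for c, v in zip(cols, pvals)},
        auc=auc,
        lr_pvalue=lr_p,
        n=len(y),
        separation_flag=separation,
        feature_means={c: float(m) for c, m in zip(cols, mu)},
        feature_stds={c: float(s) for c, s in zip(cols, sd)},
    )


def simulate_cohort(
    n: int,
    coefficients: dict[str, float] | None = None,
    intercept: float = 0.0,
    seed: int = 0,
    feature_corr: float = 0.0,
) -> pd.DataFrame:
    """Synthetic cohort of standardized feature rows with logistic outcomes.

    Features are drawn standard normal (optionally equicorrelated) and the
    outcome from a Bernoulli with ``logit P = intercept + X beta``; a null
    cohort (no coefficients) has outcomes independent of the features.
    """
    rng = np.random.default_rng(seed)
    k = len(FEATURE_COLUMNS)
    if feature_corr:
        cov = np.full((k, k), feature_corr) + (1 - feature_corr) * np.eye(k)
        X = rng.multivariate_normal(np.zeros(k), cov, size=n)
    else:
        X = rng.standard_normal((n, k))
    beta = np.array([(coefficients or {}).get(c, 0.0) for c in FEATURE_COLUMNS])
    logits = intercept + X @ beta
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-logits))
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    df["outcome"] = y.astype(int)
    df.index = [f"series{i}" for i in range(n)]
    df.index.name = "series_id"
    return df
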