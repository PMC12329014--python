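"""Figures of merit and the condition-dependence statistics.

ROI statistics are taken over regions of constant ground-truth concentration
(each insert, split-insert half, vessel, collecting system or plaque carries
a distinct sampled value, so exact-value grouping recovers the ROI layout);
quantification is summarized by Pearson correlation, RMSE and MAPD (the
latter over nonzero-truth rows only), classification by voxel-wise one-vs-rest
sensitivity/specificity and overall accuracy, and condition dependence by
stratified mean absolute difference plus a linear mixed-effects model with
phantom size and tube current as fixed effects and a random intercept per
phantom, followed by an ANOVA of its residuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import ndimage, stats

from .phantoms import FeatureClass, MaterialVolume

__all__ = [
    "roi_statistics",
    "regression_metrics",
    "classification_metrics",
    "mad_by_condition",
    "fit_condition_model",
]

MATERIALS = ("iodine", "gadolinium", "calcium")


def roi_statistics(
    predicted: dict[str, np.ndarray],
    truth: MaterialVolume,
    condition: dict | None = None,
    erode_px: int = 1,
    min_voxels: int = 4,
) -> pd.DataFrame:
    """Per-ROI mean/sd of predicted concentration against the known truth.

    One row per (constant-truth region, material, acquisition); regions are
    eroded in-plane to suppress edge partial volume.  Empty regions are
    skipped with a warning.
    """
    condition = condition or {}
    rows = []
    for mat in MATERIALS:
        t = truth.concentrations[mat]
        for value in np.unique(t[t > 0]):
            mask = t == value
            er = np.stack(
                [ndimage.binary_erosion(mask[k], iterations=erode_px)
                 if mask[k].any() else mask[k]
                 for k in range(mask.shape[0])]
            )
            if er.sum() >= min_voxels:
                mask = er
            if mask.sum() < min_voxels:
                warnings.warn(
                    f"ROI for {mat}={value:.3g} mg/mL too small; skipped",
                    stacklevel=2,
                )
                continue
            vals = predicted[mat][mask]
            rows.append(
                {
                    "phantom_id": truth.meta.get("phantom_id"),
                    "material": mat,
                    "true": float(value),
                    "pred_mean": float(vals.mean()),
                    "pred_sd": float(vals.std()),
                    "n_voxels": int(mask.sum()),
                    "n_slices": int(mask.any(axis=(1, 2)).sum()),
                    "diameter_cm": truth.meta.get("diameter_cm"),
                    **condition,
                }
            )
    return pd.DataFrame(rows)


def regression_metrics(rows: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation, RMSE (mg/mL) and MAPD (%) per material.

    MAPD is averaged over rows with strictly positive truth only; RMSE uses
    all rows.
    """
    out = []
    for mat, sub in rows.groupby("material"):
        truth = sub["true"].to_numpy(float)
        pred = sub["pred_mean"].to_numpy(float)
        err = pred - truth
        pos = truth > 0
        if not pos.any():
            raise ValueError(f"MAPD undefined: no nonzero-truth rows for {mat}")
        corr = (
            float(np.corrcoef(truth, pred)[0, 1])
            if len(sub) >= 2 and truth.std() > 0
            else float("nan")
        )
        out.append(
            {
                "material": mat,
                "n_rois": len(sub),
                "correlation": corr,
                "rmse": float(np.sqrt(np.mean(err**2))),
                "mapd_pct": float(np.mean(np.abs(err[pos]) / truth[pos]) * 100.0),
            }
        )
    return pd.DataFrame(out)


def classification_metrics(
    true_classes: np.ndarray, predicted_classes: np.ndarray
) -> pd.DataFrame:
    """Voxel-wise multilabel metrics over the 4-class maps.

    Per class: one-vs-rest sensitivity and specificity.  Two accuracy rows:
    ``total`` (all voxels) and ``iodine_gadolinium`` (accuracy restricted to
    voxels whose ground truth is the contrast class).
    """
    t = np.asarray(true_classes).ravel()
    p = np.asarray(predicted_classes).ravel()
    if t.shape != p.shape:
        raise ValueError("class maps must share shape")
    rows = []
    for cls in FeatureClass:
        tp = np.sum((t == cls) & (p == cls))
        fn = np.sum((t == cls) & (p != cls))
        tn = np.sum((t != cls) & (p != cls))
        fp = np.sum((t != cls) & (p == cls))
        rows.append(
            {
                "class": cls.name.lower(),
                "sensitivity": float(tp / (tp + fn)) if tp + fn else float("nan"),
                "specificity": float(tn / (tn + fp)) if tn + fp else float("nan"),
                "accuracy": float((tp + tn) / t.size),
            }
        )
    rows.append(
        {
            "class": "total",
            "sensitivity": float("nan"),
            "specificity": float("nan"),
            "accuracy": float(np.mean(t == p)),
        }
    )
    contrast = t == FeatureClass.CONTRAST
    rows.append(
        {
            "class": "iodine_gadolinium",
            "sensitivity": float("nan"),
            "specificity": float("nan"),
            "accuracy": float(np.mean(p[contrast] == t[contrast]))
            if contrast.any()
            else float("nan"),
        }
    )
    return pd.DataFrame(rows)


def mad_by_condition(
    rows: pd.DataFrame,
    keys: tuple[str, ...] = ("diameter_cm", "isonoise_hu"),
) -> pd.DataFrame:
    """Mean absolute difference (mg/mL) stratified by acquisition condition."""
    df = rows.copy()
    df["abs_diff"] = (df["pred_mean"] - df["true"]).abs()
    out = (
        df.groupby(list(keys), dropna=False)["abs_diff"]
        .agg(mad="mean", n_rois="count")
        .reset_index()
    )
    return out


def fit_condition_model(
    rows: pd.DataFrame,
    size_col: str = "diameter_cm",
    dose_col: str = "mAs",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mixed-effects condition analysis per material.

    Fits ``pred_mean ~ size + mAs`` with a random intercept per phantom;
    reports estimate, SE, CI bounds, Wald F and p per fixed effect.  A
    singular mixed fit falls back to fixed-effects OLS (flagged).  The
    second table is an ANOVA of the model residuals by tube current and
    phantom size.
    """
    coef_rows, anova_rows = [], []
    for mat, sub in rows.groupby("material"):
        df = sub.rename(columns={size_col: "size", dose_col: "mas"}).copy()
        for col in ("size", "mas"):
            if df[col].nunique() < 2:
                raise ValueError(f"fixed effect {col!r} needs >= 2 levels")
        fallback = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = smf.mixedlm(
                    "pred_mean ~ size + mas", df, groups=df["phantom_id"]
                ).fit(reml=True, method="lbfgs")
                converged = bool(fit.converged)
            except Exception:
                converged = False
            if not converged:
                fallback = True
                fit = smf.ols("pred_mean ~ size + mas", df).fit()

        params = fit.params
        bse = fit.bse
        ci = fit.conf_int()
        for name, label in (
            ("Intercept", "intercept"),
            ("size", "size"),
            ("mas", "tube_current"),
        ):
            z = params[name] / bse[name]
            coef_rows.append(
                {
                    "material": mat,
                    "effect": label,
                    "estimate": float(params[name]),
                    "se": float(bse[name]),
                    "ci_lower": float(ci.loc[name, 0]),
                    "ci_upper": float(ci.loc[name, 1]),
                    "f_stat": float(z**2),
                    "p_value": float(2 * stats.norm.sf(abs(z))),
                    "model": "ols_fallback" if fallback else "mixedlm",
                }
            )

        resid = np.asarray(fit.resid)
        df = df.assign(resid=resid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols("resid ~ C(mas) + C(size)", df).fit()
            try:
                table = sm.stats.anova_lm(ols, typ=2)
            except Exception:
                table = sm.stats.anova_lm(ols, typ=1)
        for factor in table.index:
            if factor == "Residual":
                continue
            anova_rows.append(
                {
                    "material": mat,
                    "factor": "tube_current" if "mas" in factor else "size",
                    "f_stat": float(table.loc[factor, "F"]),
                    "p_value": float(table.loc[factor, "PR(>F)"]),
                }
            )
    return pd.DataFrame(coef_rows), pd.DataFrame(anova_rows)
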