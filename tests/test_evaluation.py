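"""Figures of merit against brute-force oracles, plus the mixed model."""

import numpy as np
import pandas as pd
import pytest

from specmat.evaluation import (
    classification_metrics,
    fit_condition_model,
    mad_by_condition,
    regression_metrics,
    roi_statistics,
)
from specmat.phantoms import generate_cylindrical_phantom


def _rows(true, pred, material="iodine", **extra):
    return pd.DataFrame(
        [
            {"material": material, "true": t, "pred_mean": p, **extra}
            for t, p in zip(true, pred)
        ]
    )


class TestRoiStatistics:
    def test_truth_against_itself_is_exact(self):
        vol = generate_cylindrical_phantom(20.0, seed=5, n=128, nz=1)
        vol.meta["phantom_id"] = "p"
        rows = roi_statistics(vol.concentrations, vol)
        assert len(rows) > 0
        assert rows["pred_mean"].to_numpy() == pytest.approx(
            rows["true"].to_numpy(), rel=1e-6
        )
        assert rows["pred_sd"].to_numpy() == pytest.approx(0.0, abs=1e-6)

    def test_one_row_per_constant_region(self):
        vol = generate_cylindrical_phantom(20.0, seed=6, n=128, nz=1)
        rows = roi_statistics(vol.concentrations, vol)
        # each sampled concentration value appears exactly once per material
        assert not rows.duplicated(subset=["material", "true"]).any()

    def test_constant_map_mean_and_sd(self):
        vol = generate_cylindrical_phantom(20.0, seed=7, n=128, nz=1)
        flat = {m: np.full(vol.shape, 2.0, dtype=np.float32)
                for m in vol.concentrations}
        rows = roi_statistics(flat, vol)
        assert (rows["pred_mean"] == 2.0).all()
        assert (rows["pred_sd"] == 0.0).all()

    def test_condition_columns_carried(self):
        vol = generate_cylindrical_phantom(20.0, seed=8, n=128, nz=1)
        rows = roi_statistics(
            vol.concentrations, vol, condition={"mAs": 110.0, "isonoise_hu": 5.0}
        )
        assert (rows["mAs"] == 110.0).all()
        assert (rows["isonoise_hu"] == 5.0).all()


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        m = regression_metrics(_rows([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        row = m.iloc[0]
        assert row["correlation"] == pytest.approx(1.0)
        assert row["rmse"] == 0.0
        assert row["mapd_pct"] == 0.0

    def test_hand_computed_mapd(self):
        # truth [2, 4], predictions [1, 5] -> (50% + 25%) / 2 = 37.5%
        m = regression_metrics(_rows([2.0, 4.0], [1.0, 5.0]))
        assert m.iloc[0]["mapd_pct"] == pytest.approx(37.5)

    def test_constant_bias_closed_form(self):
        true = np.array([2.0, 4.0, 5.0])
        m = regression_metrics(_rows(true, true + 0.5))
        assert m.iloc[0]["rmse"] == pytest.approx(0.5)
        assert m.iloc[0]["mapd_pct"] == pytest.approx(
            np.mean(0.5 / true) * 100.0
        )

    def test_zero_truth_rows_excluded_from_mapd_only(self):
        rows = _rows([0.0, 2.0], [0.4, 2.2])
        m = regression_metrics(rows)
        assert m.iloc[0]["mapd_pct"] == pytest.approx(10.0)  # only the 2.0 row
        assert m.iloc[0]["rmse"] == pytest.approx(
            np.sqrt((0.4**2 + 0.2**2) / 2), rel=1e-6
        )

    def test_all_zero_truth_is_an_error(self):
        with pytest.raises(ValueError):
            regression_metrics(_rows([0.0, 0.0], [0.1, 0.2]))

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        frames = []
        for mat in ("iodine", "gadolinium", "calcium"):
            true = rng.uniform(0.5, 7.5, size=30)
            pred = true + rng.normal(0, 0.5, size=30)
            frames.append(_rows(true, pred, material=mat))
        rows = pd.concat(frames, ignore_index=True)
        metrics = regression_metrics(rows).set_index("material")
        for mat, sub in rows.groupby("material"):
            t = sub["true"].to_numpy()
            p = sub["pred_mean"].to_numpy()
            # brute force with explicit loops
            rmse = np.sqrt(sum((a - b) ** 2 for a, b in zip(p, t)) / len(t))
            mapd = 100 * np.mean([abs(a - b) / b for a, b in zip(p, t) if b > 0])
            corr = np.corrcoef(t, p)[0, 1]
            assert metrics.loc[mat, "rmse"] == pytest.approx(rmse)
            assert metrics.loc[mat, "mapd_pct"] == pytest.approx(mapd)
            assert metrics.loc[mat, "correlation"] == pytest.approx(corr)


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        t = np.random.default_rng(1).integers(0, 4, size=1000)
        m = classification_metrics(t, t).set_index("class")
        assert m.loc["total", "accuracy"] == 1.0
        for cls in ("background", "calcium", "contrast", "tissue"):
            assert m.loc[cls, "sensitivity"] == 1.0
            assert m.loc[cls, "specificity"] == 1.0

    def test_constant_prediction(self):
        t = np.array([0, 1, 2, 3] * 10)
        p = np.ones_like(t)
        m = classification_metrics(t, p).set_index("class")
        assert m.loc["calcium", "sensitivity"] == 1.0
        assert m.loc["background", "sensitivity"] == 0.0
        assert m.loc["calcium", "specificity"] == 0.0

    def test_hand_confusion_counts(self):
        # TP=8, FN=2, TN=85, FP=5 for the calcium class
        t = np.array([1] * 10 + [0] * 90)
        p = np.array([1] * 8 + [0] * 2 + [1] * 5 + [0] * 85)
        m = classification_metrics(t, p).set_index("class")
        assert m.loc["calcium", "sensitivity"] == pytest.approx(0.8)
        assert m.loc["calcium", "specificity"] == pytest.approx(85 / 90)

    def test_contrast_restricted_accuracy(self):
        t = np.array([2, 2, 2, 2, 0, 0])
        p = np.array([2, 2, 0, 1, 0, 2])
        m = classification_metrics(t, p).set_index("class")
        assert m.loc["iodine_gadolinium", "accuracy"] == pytest.approx(0.5)

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(3)
        t = rng.integers(0, 4, size=500)
        p = rng.integers(0, 4, size=500)
        m = classification_metrics(t, p).set_index("class")
        names = ["background", "calcium", "contrast", "tissue"]
        for c, name in enumerate(names):
            tp = fn = tn = fp = 0
            for a, b in zip(t, p):
                if a == c and b == c:
                    tp += 1
                elif a == c:
                    fn += 1
                elif b == c:
                    fp += 1
                else:
                    tn += 1
            assert m.loc[name, "sensitivity"] == pytest.approx(tp / (tp + fn))
            assert m.loc[name, "specificity"] == pytest.approx(tn / (tn + fp))
        assert m.loc["total", "accuracy"] == pytest.approx(np.mean(t == p))


class TestMadByCondition:
    def test_single_row(self):
        df = _rows([3.0], [2.4], diameter_cm=20.0, isonoise_hu=5.0)
        out = mad_by_condition(df)
        assert len(out) == 1
        assert out.iloc[0]["mad"] == pytest.approx(0.6)

    def test_perfect_predictions_zero_everywhere(self):
        df = _rows([1.0, 2.0], [1.0, 2.0], diameter_cm=20.0, isonoise_hu=5.0)
        assert (mad_by_condition(df)["mad"] == 0).all()

    def test_pooled_mad_is_weighted_mean_of_strata(self):
        rng = np.random.default_rng(4)
        frames = []
        for d in (20.0, 28.0):
            for iso in (5.0, 8.5):
                n = int(rng.integers(3, 8))
                frames.append(
                    _rows(
                        rng.uniform(1, 5, n),
                        rng.uniform(1, 5, n),
                        diameter_cm=d,
                        isonoise_hu=iso,
                    )
                )
        df = pd.concat(frames, ignore_index=True)
        out = mad_by_condition(df)
        pooled = np.average(out["mad"], weights=out["n_rois"])
        direct = (df["pred_mean"] - df["true"]).abs().mean()
        assert pooled == pytest.approx(direct)


class TestConditionModel:
    @staticmethod
    def _simulate(seed, size_slope=0.0, mas_slope=0.0, n_phantoms=8):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_phantoms):
            size = rng.choice([20.0, 28.0, 36.0, 42.0])
            intercept = 3.0 + rng.normal(0, 0.2)  # random phantom effect
            for mas in (50.0, 110.0, 200.0):
                for _ in range(4):
                    pred = (
                        intercept
                        + size_slope * size
                        + mas_slope * mas
                        + rng.normal(0, 0.1)
                    )
                    rows.append(
                        {
                            "material": "iodine",
                            "phantom_id": f"p{p}",
                            "true": 3.0,
                            "pred_mean": pred,
                            "diameter_cm": size,
                            "mAs": mas,
                        }
                    )
        return pd.DataFrame(rows)

    def test_three_effect_rows_per_material(self):
        coefs, anova = fit_condition_model(self._simulate(0))
        assert list(coefs["effect"]) == ["intercept", "size", "tube_current"]
        assert set(anova["factor"]) == {"size", "tube_current"}

    def test_null_effects_covered_by_ci(self):
        coefs, _ = fit_condition_model(self._simulate(1))
        for effect in ("size", "tube_current"):
            row = coefs[coefs["effect"] == effect].iloc[0]
            assert row["ci_lower"] <= 0.0 <= row["ci_upper"]

    def test_planted_size_slope_recovered(self):
        coefs, _ = fit_condition_model(self._simulate(2, size_slope=0.05))
        row = coefs[coefs["effect"] == "size"].iloc[0]
        assert row["ci_lower"] <= 0.05 <= row["ci_upper"]
        assert row["estimate"] == pytest.approx(0.05, abs=0.02)
        assert row["p_value"] < 0.05

    def test_single_level_effect_rejected(self):
        df = self._simulate(3)
        df["mAs"] = 100.0
        with pytest.raises(ValueError):
            fit_condition_model(df)
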