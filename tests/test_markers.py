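"""Mid-parent predictors, TGW subgroups and VIP marker selection."""

import numpy as np
import pandas as pd
import pytest

from corehybrid import (FeatureTable, MarkerSet, assign_subgroups,
                        build_predictors, fit_pls, refilter_markers,
                        select_markers, threshold_sweep)


def _pedigree(rows):
    return pd.DataFrame(rows, columns=["hybrid_id", "female_id", "male_id",
                                       "population"])


class TestBuildPredictors:
    def test_mid_parent_is_arithmetic_mean(self):
        parents = FeatureTable(pd.DataFrame({"m": [2.0, 4.0]},
                                            index=["pa", "pb"]))
        ped = _pedigree([("h", "pa", "pb", "2012")])
        assert build_predictors(parents, ped).loc["h", "m"] == pytest.approx(3.0)

    def test_reciprocal_hybrids_identical_rows(self):
        parents = FeatureTable(pd.DataFrame({"m": [2.0, 4.0], "n": [1.0, 5.0]},
                                            index=["pa", "pb"]))
        ped = _pedigree([("h1", "pa", "pb", "2012"), ("h2", "pb", "pa", "2012")])
        table = build_predictors(parents, ped)
        assert table.loc["h1"].equals(table.loc["h2"])

    def test_three_parent_diallel_hand_enumeration(self):
        values = {"pa": [2.0, 0.0], "pb": [4.0, 2.0], "pc": [6.0, 10.0]}
        parents = FeatureTable(pd.DataFrame(values, index=["m1", "m2"]).T)
        rows = [(f"{f}x{m}", f, m, "2012")
                for f in values for m in values if f != m]
        table = build_predictors(parents, _pedigree(rows))
        for f in values:
            for m in values:
                if f == m:
                    continue
                expected = (np.array(values[f]) + np.array(values[m])) / 2
                assert np.allclose(table.loc[f"{f}x{m}"], expected)

    def test_replicates_averaged_before_midparent(self):
        data = pd.DataFrame({"m": [1.0, 3.0, 10.0]},
                            index=["pa_r1", "pa_r2", "pb_r1"])
        lines = pd.Series(["pa", "pa", "pb"], index=data.index)
        parents = FeatureTable(data, line_ids=lines)
        ped = _pedigree([("h", "pa", "pb", "2012")])
        # line pa averages to 2, mid-parent (2+10)/2 = 6
        assert build_predictors(parents, ped).loc["h", "m"] == pytest.approx(6.0)

    def test_missing_parent_reported(self):
        parents = FeatureTable(pd.DataFrame({"m": [1.0]}, index=["pa"]))
        with pytest.raises(KeyError, match="h.*pb"):
            build_predictors(parents, _pedigree([("h", "pa", "pb", "2012")]))


class TestAssignSubgroups:
    def test_boundaries_are_strict(self):
        phen = pd.Series({"a": 28.0, "b": 27.0, "c": 24.0, "d": 23.9, "e": 25.0})
        groups = assign_subgroups(phen)
        assert groups.to_dict() == {"a": "large", "b": "medium", "c": "medium",
                                    "d": "small", "e": "medium"}

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            assign_subgroups(pd.Series({"a": 25.0}), low=27, high=24)

    def test_missing_tgw_skipped_with_warning(self):
        phen = pd.Series({"a": 28.0, "b": np.nan})
        with pytest.warns(UserWarning, match="missing TGW"):
            groups = assign_subgroups(phen)
        assert list(groups.index) == ["a"]


@pytest.fixture(scope="module")
def screen(small_dataset):
    predictors = build_predictors(small_dataset["parents"],
                                  small_dataset["pedigree"])
    pop = small_dataset["pedigree"].set_index("hybrid_id")["population"]
    phen = small_dataset["phenotypes"][pop.index[pop == "2012"]]
    # tercile split of the small population guarantees populated extremes
    low, high = phen.quantile([0.33, 0.66])
    subgroups = assign_subgroups(phen, low=low, high=high)
    return predictors, subgroups


class TestSelectMarkers:
    def test_zero_threshold_returns_every_analyte(self, screen):
        predictors, subgroups = screen
        markers, _ = select_markers(predictors, subgroups, vip_threshold=0.0)
        assert markers.analyte_ids == list(predictors.columns)

    def test_increasing_threshold_never_grows_the_set(self, screen):
        predictors, subgroups = screen
        sizes = []
        previous = None
        for t in (0.0, 0.5, 1.0, 1.5, 2.0):
            markers, _ = select_markers(predictors, subgroups, vip_threshold=t)
            sizes.append(len(markers))
            if previous is not None:
                assert set(markers.analyte_ids) <= previous
            previous = set(markers.analyte_ids)
        assert sizes == sorted(sizes, reverse=True)

    def test_selection_is_deterministic(self, screen):
        predictors, subgroups = screen
        a, _ = select_markers(predictors, subgroups, vip_threshold=1.0, cv_seed=3)
        b, _ = select_markers(predictors, subgroups, vip_threshold=1.0, cv_seed=3)
        assert a.analyte_ids == b.analyte_ids
        assert a.vip_values.equals(b.vip_values)

    def test_empty_extreme_group_rejected(self, screen):
        predictors, _ = screen
        phen = pd.Series(25.0, index=predictors.index)   # all medium
        subgroups = assign_subgroups(phen)
        with pytest.raises(ValueError, match="extreme"):
            select_markers(predictors, subgroups)

    def test_causal_analytes_have_higher_mean_vip(self, default_result):
        """On the study-scale scenario the causal analytes out-rank the rest."""
        res = default_result
        vips = res.markers.vip_values
        causal = vips.index.isin(res.truth.causal_analyte_ids)
        assert vips[causal].mean() > 1.5 * vips[~causal].mean()


class TestRefilterMarkers:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(20)
        names = [f"m{i:02d}" for i in range(20)]
        X = rng.normal(size=(40, 20))
        y = X[:, :5] @ rng.normal(size=5) + 0.3 * rng.normal(size=40)
        model = fit_pls(X, y, 4, feature_names=names)
        current = MarkerSet(names, 0.0, pd.Series(1.0, index=names))
        return model, current

    def test_zero_threshold_is_identity(self, fitted):
        model, current = fitted
        assert refilter_markers(model, current, 0.0).analyte_ids == current.analyte_ids

    def test_increasing_thresholds_are_nested(self, fitted):
        model, current = fitted
        sets = [set(refilter_markers(model, current, t).analyte_ids)
                for t in (0.2, 0.6, 1.0, 1.4)]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger

    def test_survivors_match_independent_vip_computation(self, fitted):
        """Recompute Wold VIP from the stored factors and compare."""
        model, current = fitted
        W, T, q = model.x_weights, model.x_scores, model.y_loadings
        ssy = q ** 2 * np.einsum("ij,ij->j", T, T)
        oracle = np.sqrt(len(current.analyte_ids) * (W ** 2 @ ssy) / ssy.sum())
        threshold = 1.0
        expected = [a for a, v in zip(current.analyte_ids, oracle) if v > threshold]
        assert refilter_markers(model, current, threshold).analyte_ids == expected

    def test_analyte_mismatch_rejected(self, fitted):
        model, current = fitted
        wrong = MarkerSet(current.analyte_ids[:10], 0.0,
                          pd.Series(1.0, index=current.analyte_ids[:10]))
        with pytest.raises(ValueError, match="mismatch"):
            refilter_markers(model, wrong, 0.5)


class TestThresholdSweep:
    def test_extreme_thresholds(self):
        vips = pd.Series([0.5, 1.0, 2.0], index=["a", "b", "c"])
        table = threshold_sweep(vips, [0.0, 10.0])
        assert table["n_markers"].tolist() == [3, 0]

    def test_counts_non_increasing(self):
        rng = np.random.default_rng(21)
        vips = pd.Series(rng.uniform(0, 3, size=50))
        counts = threshold_sweep(vips, np.linspace(0, 3, 10))["n_markers"]
        assert (counts.diff().dropna() <= 0).all()
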