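"""End-to-end pipeline: training, prediction, bins, combinations, clustering."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import grapearoma as ga
from grapearoma.errors import ModelError, ValidationError


class TestQualityBins:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (4.7, "excellent"),
            (3.4, "poor"),
            (3.5, "average"),
            (4.0, "good"),
            (4.5, "good"),        # upper bound of "good" is inclusive
            (4.500001, "excellent"),
            (1.0, "poor"),
            (5.0, "excellent"),
        ],
    )
    def test_bin_assignment(self, score, expected):
        assert ga.quality_bin(score) == expected

    def test_bins_partition_the_line(self):
        for score in np.linspace(0.5, 5.5, 401):
            assert ga.quality_bin(float(score)) in {"poor", "average", "good", "excellent"}

    def test_non_finite_score_rejected(self):
        with pytest.raises(ValidationError):
            ga.quality_bin(float("nan"))


class TestTrain:
    def test_default_cohort_trains_adequately(self, fitted):
        assert fitted.q2y > 0.5
        assert fitted.effective
        assert fitted.model.stats["R2Y"] > fitted.q2y

    def test_too_few_cultivars_for_folds_rejected(self, cohort):
        sset, truth = cohort
        scores = truth.observed_scores.loc[truth.train_cultivars[:3]]
        with pytest.raises(ModelError, match="folds"):
            ga.train(sset, scores, ga.PipelineConfig(n_permutations=0))

    def test_random_response_flags_model_ineffective(self, cohort):
        sset, truth = cohort
        rng = np.random.default_rng(0)
        scores = pd.Series(
            rng.uniform(1, 5, size=len(truth.train_cultivars)), index=truth.train_cultivars
        )
        fitted = ga.train(sset, scores, ga.PipelineConfig(n_permutations=0, seed=0))
        assert not fitted.effective
        assert any("ineffective" in w for w in fitted.warnings)

    def test_series_feature_block_runs_with_same_diagnostics(self, cohort):
        sset, truth = cohort
        scores = truth.observed_scores.loc[truth.train_cultivars]
        fitted = ga.train(
            sset, scores,
            ga.PipelineConfig(n_permutations=0, seed=1, feature_block="series"),
        )
        assert "Q2Y" in fitted.model.stats and "RMSECV" in fitted.model.stats

    def test_screening_removes_injected_outlier_before_fitting(self, cohort):
        sset, truth = cohort
        out = sset
        for rep in (1, 2, 3):
            out = ga.inject_outlier(out, ga.SampleKey("P07", "pulp", rep), 50.0)
            out = ga.inject_outlier(out, ga.SampleKey("P07", "skin", rep), 50.0)
        scores = truth.observed_scores.loc[truth.train_cultivars]
        fitted = ga.train(out, scores, ga.PipelineConfig(n_permutations=0, seed=1))
        assert "P07" in fitted.removed_outliers
        assert "P07" not in fitted.training_cultivars

    def test_end_to_end_determinism(self, cohort):
        sset, truth = cohort
        scores = truth.observed_scores.loc[truth.train_cultivars]
        config = ga.PipelineConfig(n_permutations=0, seed=42)
        runs = []
        for _ in range(2):
            fitted = ga.train(sset, scores, config)
            reports = ga.predict_liking(fitted, sset)
            runs.append(json.dumps([r.to_dict() for r in reports], sort_keys=True))
        assert runs[0] == runs[1]


class TestPredictLiking:
    def test_reports_have_replicate_scores_and_bins(self, fitted, cohort):
        sset, truth = cohort
        reports = ga.predict_liking(fitted, sset)
        by_id = {r.cultivar_id: r for r in reports}
        assert set(by_id) == set(sset.cultivars)
        for r in reports:
            assert len(r.replicate_scores) == 3
            assert r.predicted_score == pytest.approx(np.mean(r.replicate_scores))
            assert r.quality_bin == ga.quality_bin(r.predicted_score)

    def test_noiseless_cohort_recovers_true_ranking_exactly(self):
        """With no liking noise and a well-posed panel the pipeline must
        reproduce the ground-truth preference order (Spearman rho = 1)."""
        config = ga.CohortConfig(
            n_train_cultivars=40, n_test_cultivars=15, n_compounds=12,
            n_key_positive=6, n_key_negative=3, noise_sd=0.0,
            n_orthogonal_factors=0, dropout_rate=0.0, seed=3,
        )
        sset, truth = ga.generate_cohort(config)
        fitted = ga.train(
            sset, truth.observed_scores.loc[truth.train_cultivars],
            ga.PipelineConfig(n_permutations=0, seed=3, min_improvement=1e-6, max_ortho=11),
        )
        reports = ga.predict_liking(fitted, sset)
        pred = pd.Series(
            {r.cultivar_id: r.predicted_score for r in reports}
        ).loc[truth.test_cultivars]
        rho = spearmanr(pred, truth.true_scores.loc[truth.test_cultivars]).statistic
        assert rho == pytest.approx(1.0)


class TestKeyCompounds:
    def test_selection_respects_cutoff(self, fitted, cohort):
        sset, _ = cohort
        table = ga.compute_oav(sset)
        selected = ga.select_key_compounds(fitted, table)
        assert all(k.vip > 1.0 for k in selected)
        vips = [k.vip for k in selected]
        assert vips == sorted(vips, reverse=True)

    def test_cutoff_above_maximum_gives_empty_list(self, fitted, cohort):
        sset, _ = cohort
        table = ga.compute_oav(sset)
        top = float(fitted.vip_scores.vip.max())
        assert ga.select_key_compounds(fitted, table, cutoff=top + 1) == []

    def test_recovers_injected_keys(self, fitted, cohort):
        sset, truth = cohort
        table = ga.compute_oav(sset)
        selected = {k.compound_id for k in ga.select_key_compounds(fitted, table)}
        truth_keys = set(truth.key_compounds)
        assert len(selected & truth_keys) / len(truth_keys) >= 0.8

    def test_directions_match_injected_signs(self, fitted, cohort):
        sset, truth = cohort
        table = ga.compute_oav(sset)
        for k in ga.select_key_compounds(fitted, table):
            if k.compound_id in truth.key_positive:
                assert k.direction == "positive"
            elif k.compound_id in truth.key_negative:
                assert k.direction == "negative"

    def test_ineffective_model_blocks_selection_unless_overridden(self, cohort):
        sset, truth = cohort
        rng = np.random.default_rng(1)
        scores = pd.Series(
            rng.uniform(1, 5, size=len(truth.train_cultivars)), index=truth.train_cultivars
        )
        weak = ga.train(sset, scores, ga.PipelineConfig(n_permutations=0, seed=1))
        table = ga.compute_oav(sset)
        with pytest.raises(ModelError, match="ineffective"):
            ga.select_key_compounds(weak, table)
        assert isinstance(
            ga.select_key_compounds(weak, table, allow_ineffective=True), list
        )


class TestAromaCombinations:
    def _reports(self, cultivars):
        return [
            ga.LikingReport(c, 4.0, [4.0], "good") for c in cultivars
        ]

    def test_single_cultivar_single_group(self, cohort, fitted):
        sset, _ = cohort
        table = ga.compute_oav(sset)
        keys = ga.select_key_compounds(fitted, table)
        reports = self._reports(["U01"])
        labels = ga.assign_aroma_combinations(reports, keys, sset, n_groups=1, seed=0)
        assert list(labels) == ["I"]
        assert reports[0].aroma_combination == "I"

    def test_two_separated_blobs_recovered(self, tiny_library):
        # c3 positive key, c2 negative key; two (P, N) blobs far apart
        rows, cultivars = [], []
        rng = np.random.default_rng(0)
        for i in range(6):
            lo = i < 3
            base = 10.0 if lo else 500.0
            cultivars.append(f"C{i}")
            for t in ("pulp", "skin"):
                rows.append(((f"C{i}", t, 1),
                             [1.0, base + rng.uniform(0, 2), base + rng.uniform(0, 2)]))
        index = pd.MultiIndex.from_tuples([r[0] for r in rows],
                                          names=["cultivar_id", "tissue", "replicate"])
        sset = ga.SampleSet(pd.DataFrame([r[1] for r in rows], index=index,
                                         columns=tiny_library.ids), tiny_library)
        keys = [
            ga.KeyCompound("c3", 1.5, "positive", True),
            ga.KeyCompound("c2", 1.2, "negative", True),
        ]
        labels = ga.assign_aroma_combinations(self._reports(cultivars), keys, sset,
                                              n_groups=2, seed=0)
        assert set(labels[cultivars[:3]]) == {"I"}      # low-content blob first
        assert set(labels[cultivars[3:]]) == {"II"}

    def test_labels_ordered_by_total_content(self, cohort, fitted):
        sset, truth = cohort
        table = ga.compute_oav(sset)
        keys = ga.select_key_compounds(fitted, table)
        reports = self._reports(truth.test_cultivars)
        labels = ga.assign_aroma_combinations(reports, keys, sset, n_groups=5, seed=0)
        whole = sset.combine_tissues(0.2).cultivar_means("whole")
        key_ids = [k.compound_id for k in keys]
        totals = whole.loc[labels.index, key_ids].sum(axis=1)
        group_means = totals.groupby(labels).mean()
        romans = ["I", "II", "III", "IV", "V"]
        ordered = [group_means[r] for r in romans if r in group_means]
        assert ordered == sorted(ordered)

    def test_more_groups_than_cultivars_rejected(self, cohort, fitted):
        sset, _ = cohort
        with pytest.raises(ValidationError):
            ga.assign_aroma_combinations(self._reports(["U01", "U02"]), [], sset, n_groups=3)


class TestHcaClusters:
    @pytest.fixture()
    def profile(self, cohort, taxonomy):
        sset, _ = cohort
        memberships = ga.resolve_memberships(sset.library, taxonomy)
        return ga.series_values(ga.compute_oav(sset), memberships, "secondary")

    def test_k_equal_to_samples_gives_singletons(self, profile):
        pulp = ga.SeriesProfile("secondary", profile.values.xs(
            "pulp", level="tissue", drop_level=False))
        k = len(pulp.values)
        result = ga.hca_clusters(pulp, k)
        assert result.labels.nunique() == k

    def test_requested_cluster_count_is_honoured(self, profile):
        for k, tissue in ((5, "pulp"), (6, "skin")):
            result = ga.hca_clusters(profile, k, tissue=tissue)
            assert result.labels.nunique() == k
            assert len(result.cluster_means) == k

    def test_two_separated_blobs_split_cleanly(self):
        rng = np.random.default_rng(2)
        low = rng.normal(0, 0.1, size=(8, 4))
        high = rng.normal(8, 0.1, size=(8, 4))
        index = pd.MultiIndex.from_tuples(
            [(f"C{i}", "pulp", 1) for i in range(16)],
            names=["cultivar_id", "tissue", "replicate"],
        )
        profile = ga.SeriesProfile(
            "primary", pd.DataFrame(np.vstack([low, high]), index=index,
                                    columns=["a", "b", "c", "d"])
        )
        result = ga.hca_clusters(profile, 2)
        labels = result.labels.to_numpy()
        assert len(set(labels[:8])) == 1
        assert len(set(labels[8:])) == 1
        assert labels[0] != labels[-1]

    def test_k_beyond_sample_count_rejected(self, profile):
        with pytest.raises(ValidationError):
            ga.hca_clusters(profile, len(profile.values) + 1)
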