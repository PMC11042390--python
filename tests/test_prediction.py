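"""Site scoring, outcome prediction, ROI benchmarking, specificity."""

import numpy as np
import pytest

import circuitmap as cm
from circuitmap.prediction import ScoreMethod
from circuitmap.volumes import VolumeError


def make_circuit_map(grid, data, mask=None, weight=10.0, name="c"):
    vol = cm.BrainVolume(grid=grid, data=np.clip(data, -1, 1), brain_mask=mask)
    return cm.CircuitMap(rmap=vol, weight=weight, provenance=[name])


class TestDbsOverlapScore:
    def _site(self, grid, left_voxels, right_voxels):
        left = np.zeros(grid.shape)
        right = np.zeros(grid.shape)
        for v in left_voxels:
            left[v] = 1.0
        for v in right_voxels:
            right[v] = 1.0
        return cm.dbs_pair_site(cm.BrainVolume(grid=grid, data=left),
                                cm.BrainVolume(grid=grid, data=right))

    def test_hand_computed_example(self, grid8):
        # left covers circuit values {0.2, 0.4}, right covers {0.1}:
        # mean(0.2, 0.4) + mean(0.1) = 0.3 + 0.1 = 0.4
        data = np.zeros(grid8.shape)
        data[0, 0, 0], data[0, 0, 1], data[7, 7, 7] = 0.2, 0.4, 0.1
        circuit = make_circuit_map(grid8, data)
        site = self._site(grid8, [(0, 0, 0), (0, 0, 1)], [(7, 7, 7)])
        score = cm.dbs_overlap_score(site, circuit)
        assert score.score == pytest.approx(0.4)
        assert score.method is ScoreMethod.OVERLAP

    def test_zero_circuit_under_fields(self, grid8):
        circuit = make_circuit_map(grid8, np.zeros(grid8.shape))
        site = self._site(grid8, [(1, 1, 1)], [(6, 6, 6)])
        assert cm.dbs_overlap_score(site, circuit).score == 0.0

    def test_hemifield_swap_symmetry(self, grid8, rng):
        circuit = make_circuit_map(grid8, rng.normal(size=grid8.shape) / 4)
        a = self._site(grid8, [(0, 0, 0), (1, 1, 1)], [(6, 6, 6)])
        b = self._site(grid8, [(6, 6, 6)], [(0, 0, 0), (1, 1, 1)])
        assert cm.dbs_overlap_score(a, circuit).score == pytest.approx(
            cm.dbs_overlap_score(b, circuit).score)

    def test_empty_hemifield_contributes_zero(self, grid8, rng):
        circuit = make_circuit_map(grid8, rng.normal(size=grid8.shape) / 4)
        empty = cm.BrainVolume(grid=grid8, data=np.zeros(grid8.shape))
        field = np.zeros(grid8.shape)
        field[3, 3, 3] = 1.0
        site = cm.dbs_pair_site(empty, cm.BrainVolume(grid=grid8, data=field))
        assert cm.dbs_overlap_score(site, circuit).score == pytest.approx(
            circuit.rmap.data[3, 3, 3])

    def test_fields_outside_mask_rejected(self, grid8):
        mask = np.zeros(grid8.shape, bool)
        mask[:2] = True
        circuit = make_circuit_map(grid8, np.where(mask, 0.5, 0.0), mask=mask)
        site = self._site(grid8, [(5, 5, 5)], [(6, 6, 6)])
        with pytest.raises(VolumeError, match="outside"):
            cm.dbs_overlap_score(site, circuit)

    def test_non_dbs_site_rejected(self, grid8, rng):
        circuit = make_circuit_map(grid8, rng.normal(size=grid8.shape) / 4)
        data = np.zeros(grid8.shape)
        data[0, 0, 0] = 1.0
        site = cm.lesion_site(cm.BrainVolume(grid=grid8, data=data))
        with pytest.raises(ValueError, match="dbs_pair"):
            cm.dbs_overlap_score(site, circuit)


class TestSiteConnectivityScore:
    def _conn_map(self, grid, data):
        site_data = np.zeros(grid.shape)
        site_data[0, 0, 0] = 1.0
        site = cm.StimulationSite(kind=cm.SiteKind.TMS,
                                  weights=cm.BrainVolume(grid=grid, data=site_data))
        return cm.ConnectivityMap(zmap=cm.BrainVolume(grid=grid, data=data),
                                  site=site, n_subjects_used=1)

    def test_proportional_map_scores_one(self, grid8, rng):
        data = rng.normal(size=grid8.shape)
        circuit = make_circuit_map(grid8, np.clip(data / np.abs(data).max(), -1, 1))
        conn = self._conn_map(grid8, 3.0 * circuit.rmap.data)
        assert cm.site_connectivity_score(conn, circuit).score == pytest.approx(1.0)

    def test_negated_map_scores_minus_one(self, grid8, rng):
        data = rng.normal(size=grid8.shape)
        circuit = make_circuit_map(grid8, np.clip(data / np.abs(data).max(), -1, 1))
        conn = self._conn_map(grid8, -circuit.rmap.data)
        assert cm.site_connectivity_score(conn, circuit).score == pytest.approx(-1.0)

    def test_matches_pearson_oracle(self, rng):
        grid = cm.make_grid((16, 16, 16), 2.0)
        z = rng.normal(size=grid.shape)
        c = np.clip(rng.normal(size=grid.shape) / 4, -1, 1)
        circuit = make_circuit_map(grid, c)
        score = cm.site_connectivity_score(self._conn_map(grid, z), circuit).score
        assert score == pytest.approx(np.corrcoef(z.ravel(), c.ravel())[0, 1],
                                      abs=1e-12)


class TestPredictOutcomeChange:
    def _score_list(self, values):
        return [cm.SiteScore(patient_id=f"p{i}", score=float(v),
                             method="overlap", circuit_provenance=["c"])
                for i, v in enumerate(values)]

    def _dataset(self, outcome, n):
        grid = cm.make_grid((4, 4, 4), 2.0)
        records = []
        for i in range(n):
            data = np.zeros(grid.shape)
            data[0, 0, 0] = 1.0
            site = cm.lesion_site(cm.BrainVolume(grid=grid, data=data))
            records.append(cm.PatientRecord(id=f"p{i}", site=site,
                                            anxiety=float(outcome[i]), depression=0.0))
        return cm.CohortDataset(name="pred", modality="lesion", records=records)

    def test_recovers_construction_correlation(self):
        rng = np.random.default_rng(10)
        n, b, sigma = 200, 1.0, 1.0
        s = rng.normal(size=n)
        y = b * s + rng.normal(scale=sigma, size=n)
        ds = self._dataset(y, n)
        r, p, _ = cm.predict_outcome_change(self._score_list(s), ds,
                                            covariate_fields=())
        theory = b / np.sqrt(b**2 + sigma**2)
        assert abs(r - theory) < 0.1
        assert p < 1e-6

    def test_null_calibration(self):
        rng = np.random.default_rng(20)
        n = 40
        from scipy import stats
        crit = stats.t.ppf(0.975, n - 2)
        r_crit = crit / np.sqrt(n - 2 + crit**2)
        rejections = 0
        reps = 200
        for _ in range(reps):
            s = rng.normal(size=n)
            y = rng.normal(size=n)
            ds = self._dataset(y, n)
            r, p, _ = cm.predict_outcome_change(self._score_list(s), ds,
                                                covariate_fields=())
            rejections += abs(r) > r_crit
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * se + 1e-9

    def test_constant_scores_rejected(self):
        ds = self._dataset(np.random.default_rng(0).normal(size=10), 10)
        with pytest.raises(ValueError, match="residual variance"):
            cm.predict_outcome_change(self._score_list(np.ones(10)), ds,
                                      covariate_fields=())

    def test_misaligned_scores_rejected(self):
        ds = self._dataset(np.random.default_rng(0).normal(size=10), 10)
        scores = self._score_list(np.arange(9))
        with pytest.raises(ValueError, match="missing"):
            cm.predict_outcome_change(scores, ds, covariate_fields=())


class TestRoiBenchmark:
    def test_circuit_as_roi_reproduces_prediction(self, spec, circuit, connectome,
                                                  lesion_cohort, tms_cohort):
        lodo = cm.leave_one_dataset_out([lesion_cohort, tms_cohort], "lesion-a")
        table = cm.roi_benchmark({"self": lodo.rmap}, [lesion_cohort],
                                 include_circuit=False)
        scores = cm.score_dataset(lesion_cohort, lodo)
        r, p, n = cm.predict_outcome_change(scores, lesion_cohort)
        row = table.iloc[0]
        assert row["r"] == pytest.approx(r, abs=1e-12)
        assert row["n"] == n

    def test_row_counting(self, lesion_cohort, tms_cohort, circuit, rng):
        grid = circuit.grid
        rois = {}
        for i in range(3):
            data = np.zeros(grid.shape)
            data[6 + i, 6:9, 6:9] = 1.0
            rois[f"roi{i}"] = cm.BrainVolume(grid=grid, data=data,
                                             brain_mask=circuit.brain_mask)
        table = cm.roi_benchmark(rois, [lesion_cohort, tms_cohort],
                                 include_circuit=True)
        # (3 ROIs + 1 circuit row) x 2 datasets
        assert len(table) == 8
        assert set(table["roi_name"]) == {"circuit", "roi0", "roi1", "roi2"}

    def test_empty_roi_rejected(self, lesion_cohort, circuit):
        empty = cm.BrainVolume(grid=circuit.grid,
                               data=np.zeros(circuit.grid.shape))
        with pytest.raises(VolumeError, match="empty"):
            cm.roi_benchmark({"empty": empty}, [lesion_cohort],
                             include_circuit=False)


class TestSpecificityProfile:
    def _dataset_with_measures(self, n=120, seed=4):
        rng = np.random.default_rng(seed)
        trait = rng.normal(size=n)
        state = 0.5 * trait + np.sqrt(1 - 0.25) * rng.normal(size=n)
        mdd = (rng.random(n) < 0.4).astype(float)
        site_measure = trait + 0.5 * rng.normal(size=n)
        grid = cm.make_grid((4, 4, 4), 2.0)
        records = []
        for i in range(n):
            data = np.zeros(grid.shape)
            data[0, 0, 0] = 1.0
            site = cm.lesion_site(cm.BrainVolume(grid=grid, data=data))
            records.append(cm.PatientRecord(
                id=f"p{i}", site=site, anxiety=0.0, depression=0.0,
                extra_covariates={"trait_anxiety": trait[i],
                                  "state_anxiety": state[i], "mdd": mdd[i]}))
        ds = cm.CohortDataset(name="spec", modality="lesion", records=records)
        return ds, site_measure

    def test_trait_construction_ranks_first(self):
        ds, site_measure = self._dataset_with_measures()
        profile = cm.specificity_profile(site_measure, ds, "trait_anxiety",
                                         ["state_anxiety", "mdd"])
        assert profile.rank_of_primary == 1
        r_trait = profile.measures["trait_anxiety"][0]
        r_state = profile.measures["state_anxiety"][0]
        assert r_trait > 2 * abs(r_state)

    def test_primary_absent_rejected(self):
        ds, site_measure = self._dataset_with_measures()
        with pytest.raises(KeyError, match="unknown field"):
            cm.specificity_profile(site_measure, ds, "nope", ["state_anxiety"])

    def test_collinear_predictors_rejected(self):
        ds, site_measure = self._dataset_with_measures()
        for rec in ds.records:
            rec.extra_covariates["trait_copy"] = rec.extra_covariates["trait_anxiety"]
        with pytest.raises(ValueError, match="collinear|condition"):
            cm.specificity_profile(site_measure, ds, "trait_anxiety",
                                   ["trait_copy", "state_anxiety"])


class TestSubgroupPrediction:
    def test_single_dataset_reduction_and_weights(self, spec, circuit, connectome,
                                                  lesion_cohort, tms_cohort,
                                                  dbs_cohort):
        pooled = cm.subgroup_prediction([lesion_cohort, tms_cohort, dbs_cohort],
                                        "anxiety_disorder")
        assert set(pooled) <= {0, 1}
        for level, res in pooled.items():
            ns = [row["n"] for row in res["per_dataset"]]
            rs = [row["r"] for row in res["per_dataset"]]
            assert res["n_total"] == sum(ns)
            expected = np.average(rs, weights=ns)
            assert res["pooled_r"] == pytest.approx(expected)

    def test_similar_effects_give_similar_pooled_r(self, spec, circuit, connectome,
                                                   lesion_cohort, tms_cohort,
                                                   dbs_cohort):
        pooled = cm.subgroup_prediction([lesion_cohort, tms_cohort, dbs_cohort],
                                        "anxiety_disorder")
        if len(pooled) == 2:
            # grouping label is independent of the causal effect: both
            # subgroups should show a comparably positive pooled r
            assert abs(pooled[0]["pooled_r"] - pooled[1]["pooled_r"]) < 0.5
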