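import math

import numpy as np
import pandas as pd
import pytest

from tamspatial import (
    AttractionKernel,
    CovariateEffect,
    PhenotypePlacement,
    SimConfig,
    SurvivalModelConfig,
    cohort_survival_records,
    simulate_cohort,
    simulate_expression,
    simulate_sample,
)
from tamspatial.synthetic_data import SimulationError, _pattern


class TestSimulateSample:
    def test_deterministic_given_seeds(self):
        cfg = SimConfig(seed=17)
        s1, t1 = simulate_sample(cfg, 3)
        s2, t2 = simulate_sample(cfg, 3)
        pd.testing.assert_frame_equal(s1.cells, s2.cells)
        assert t1["tumor_area_mm2"] == t2["tumor_area_mm2"]
        s3, _ = simulate_sample(cfg, 4)
        assert not s1.cells.equals(s3.cells)

    def test_zero_macrophage_intensities_gives_pure_tumor(self):
        cfg = SimConfig(seed=2, placements=(), marker_noise=0.0,
                        pdl1_rate=0.0)
        sample, truth = simulate_sample(cfg, 0)
        assert sample.n_cells > 0
        assert sample.cells["CK_pos"].all()
        assert not sample.cells[[f"{m}_pos" for m in sample.panel
                                 if m != "CK"]].any().any()

    def test_tumor_cells_lie_within_nest_radius(self):
        cfg = SimConfig(seed=8, marker_noise=0.0)
        sample, truth = simulate_sample(cfg, 1)
        from scipy.spatial import cKDTree
        tree = cKDTree(truth["parents"])
        xy = sample.cells[["x_um", "y_um"]].to_numpy()
        d, _ = tree.query(xy, k=1)
        in_tumor = sample.cells["compartment"].to_numpy() == "tumor"
        assert np.all(d[in_tumor] <= cfg.nest_radius_um + 1e-9)
        assert np.all(d[~in_tumor] > cfg.nest_radius_um)

    def test_poisson_count_calibration(self):
        """Observed stroma counts stay within 4 sqrt(lambda A) of lambda A
        in at least 95% of seeds."""
        lam = 40.0
        placement = PhenotypePlacement("P", _pattern(CD68=True), 0.0, lam)
        within = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed, placements=(placement,),
                            marker_noise=0.0, tumor_cells_per_nest=10.0)
            sample, truth = simulate_sample(cfg, 0)
            a = truth["stroma_area_mm2"]
            observed = truth["true_counts"]["P"]["stroma"] + \
                truth["true_counts"]["P"]["tumor"]
            # placement count is drawn before compartment re-labelling noise;
            # compare against the stroma expectation
            if abs(observed - lam * a) <= 4 * math.sqrt(lam * a):
                within += 1
        assert within >= 95

    def test_truth_counts_match_emitted_cells_without_noise(self):
        cfg = SimConfig(seed=14, marker_noise=0.0, pdl1_rate=0.0)
        sample, truth = simulate_sample(cfg, 2)
        n_truth = sum(c["tumor"] + c["stroma"]
                      for c in truth["true_counts"].values())
        assert n_truth == sample.n_cells
        n_ck = truth["true_counts"]["CK"]["tumor"] + \
            truth["true_counts"]["CK"]["stroma"]
        assert int(sample.cells["CK_pos"].sum()) == n_ck

    def test_mc_area_close_to_exact_for_central_nest(self):
        # a single nest fully inside the core has exact area pi r^2
        cfg = SimConfig(seed=3, nest_parent_intensity=1e-9,  # forces 1 parent
                        nest_radius_um=200.0, tumor_cells_per_nest=5.0,
                        placements=())
        areas = []
        for s in range(10):
            sample, truth = simulate_sample(cfg, s)
            r = math.hypot(*truth["parents"][0])
            if r < cfg.core_radius_um - cfg.nest_radius_um:
                areas.append(truth["tumor_area_mm2"])
        exact = math.pi * 0.2 ** 2
        for a in areas:
            assert a == pytest.approx(exact, rel=0.05)

    def test_oversized_config_refused(self):
        with pytest.raises(SimulationError):
            SimConfig(seed=0, tumor_cells_per_nest=1e7)


class TestSimulateCohort:
    def test_cohort_determinism_and_truth_consistency(self):
        cfg = SimConfig(seed=9)
        c1, t1 = simulate_cohort(cfg, n_samples=4)
        c2, t2 = simulate_cohort(cfg, n_samples=4)
        for sid in c1.samples:
            pd.testing.assert_frame_equal(c1[sid].cells, c2[sid].cells)
            assert c1[sid].clinical == c2[sid].clinical
        assert len(c1) == 4

    def test_null_model_survival_independent_of_features(self):
        cfg = SimConfig(seed=4, survival_model=SurvivalModelConfig(betas={}))
        cohort, truth = simulate_cohort(cfg, n_samples=6)
        recs = cohort_survival_records(cohort)
        assert len(recs) == 6
        assert truth.betas == {}

    def test_binary_density_beta_shifts_hazard(self):
        beta = math.log(3)
        name = "density:Total CD68+"
        cfg = SimConfig(
            seed=31,
            survival_model=SurvivalModelConfig(
                betas={name: CovariateEffect(beta=beta)}))
        cohort, truth = simulate_cohort(cfg, n_samples=60)
        cov = truth.covariates[name]
        assert set(cov.unique()) == {0.0, 1.0}
        recs = {r.sample_id: r for r in cohort_survival_records(cohort)}
        t_high = np.median([recs[s].time_months
                            for s in cov.index[cov == 1.0]])
        t_low = np.median([recs[s].time_months
                           for s in cov.index[cov == 0.0]])
        assert t_high < t_low  # higher hazard, shorter survival

    def test_unknown_covariate_rejected(self):
        cfg = SimConfig(seed=1, survival_model=SurvivalModelConfig(
            betas={"density:NotAPhenotype": CovariateEffect(beta=1.0)}))
        with pytest.raises(Exception):
            simulate_cohort(cfg, n_samples=2)

    def test_attraction_kernel_shrinks_nn_distance(self, catalogue):
        """A kernel-attracted phenotype sits closer to malignant cells than
        an intensity-matched free phenotype in the same cohorts."""
        from tamspatial import per_sample_distance_frame
        near = PhenotypePlacement(
            "near", _pattern(CD68=True, CD163=True), 15.0, 15.0,
            kernel=AttractionKernel(scale_um=100.0, strength=25.0))
        far = PhenotypePlacement("far", _pattern(CD68=True, CD206=True),
                                 15.0, 15.0)
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimConfig(seed=seed, placements=(near, far),
                            marker_noise=0.0, nest_parent_intensity=1.5,
                            tumor_cells_per_nest=60.0)
            cohort, _ = simulate_cohort(cfg, n_samples=8)
            frame = per_sample_distance_frame(
                cohort, catalogue,
                phenotypes=["(M2) CD68+CD163+MRP8-14negCD86neg",
                            "(M2) CD68+CD206+MRP8-14negCD86neg"])
            med = frame.median()
            if med.iloc[0] < med.iloc[1]:
                wins += 1
        assert wins >= 9


class TestSimulateExpression:
    def test_determinism(self):
        m1, _ = simulate_expression(20, 10, seed=6)
        m2, _ = simulate_expression(20, 10, seed=6)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    def test_null_copula_has_small_offdiagonal_correlation(self):
        matrix, _ = simulate_expression(10, 500, seed=13)
        corr = matrix.values.T.corr(method="spearman").to_numpy()
        off = corr[~np.eye(10, dtype=bool)]
        assert np.quantile(np.abs(off), 0.95) < 0.1

    def test_infeasible_targets_rejected_with_guidance(self):
        targets = [("G0000", "G0001", 0.9), ("G0001", "G0002", 0.9),
                   ("G0000", "G0002", -0.9)]
        with pytest.raises(SimulationError, match="shrink"):
            simulate_expression(3, 10, correlation_targets=targets, seed=0)
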