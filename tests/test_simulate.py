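"""Synthetic-data generators: determinism, Poisson counts, mixtures, regions."""

import numpy as np
import pandas as pd
import pytest

import marrowmap as mm
from marrowmap.simulate import SpacingError


class TestSimulateCellmap:
    def test_aggregate_only_exact_count(self):
        cfg = mm.CellMapSimConfig(
            background_intensity={},
            aggregates=[mm.AggregateSpec({"T": 1.0}, 100, 3.0)],
            min_cell_spacing_um=1.0, seed=1)
        m, truth = mm.simulate_cellmap(cfg)
        assert m.n_cells == 100
        assert (truth.aggregate_id == 1).all()

    def test_poisson_background_mean(self):
        # 200 replicate seeds at intensity 1000/mm^2 on 1 mm^2:
        # mean count within 3 standard errors of 1000
        counts = []
        for seed in range(200):
            cfg = mm.CellMapSimConfig(background_intensity={"T": 1000.0},
                                      seed=seed)
            m, _ = mm.simulate_cellmap(cfg)
            counts.append(m.n_cells)
        se = np.sqrt(1000.0 / 200)
        assert abs(np.mean(counts) - 1000.0) < 3 * se

    def test_determinism(self):
        cfg = mm.CellMapSimConfig(
            background_intensity={"T": 300.0, "B": 100.0},
            aggregates=[mm.AggregateSpec({"T": 0.7, "B": 0.3}, 60, 10.0)],
            marker_probs={"PD1": 0.2}, seed=42)
        m1, t1 = mm.simulate_cellmap(cfg)
        m2, t2 = mm.simulate_cellmap(cfg)
        pd.testing.assert_frame_equal(m1.cells, m2.cells)
        pd.testing.assert_series_equal(t1.aggregate_id, t2.aggregate_id)

    def test_min_spacing_respected(self):
        cfg = mm.CellMapSimConfig(background_intensity={"T": 800.0},
                                  min_cell_spacing_um=4.0, seed=5)
        m, _ = mm.simulate_cellmap(cfg)
        from scipy.spatial import cKDTree
        xy = m.cells[["x_um", "y_um"]].to_numpy()
        d, _ = cKDTree(xy).query(xy, k=2)
        assert d[:, 1].min() >= 4.0

    def test_unsatisfiable_spacing_fails(self):
        cfg = mm.CellMapSimConfig(
            field_width_um=20.0, field_height_um=20.0,
            background_intensity={},
            aggregates=[mm.AggregateSpec({"T": 1.0}, 500, 2.0,
                                         center=(10.0, 10.0))],
            min_cell_spacing_um=4.0, seed=0)
        with pytest.raises(SpacingError):
            mm.simulate_cellmap(cfg)

    def test_cells_inside_field(self):
        cfg = mm.CellMapSimConfig(
            field_width_um=200.0, field_height_um=200.0,
            background_intensity={"T": 500.0},
            aggregates=[mm.AggregateSpec({"T": 1.0}, 50, 30.0,
                                         center=(5.0, 5.0))],
            min_cell_spacing_um=1.0, seed=2)
        m, _ = mm.simulate_cellmap(cfg)
        xy = m.cells[["x_um", "y_um"]].to_numpy()
        assert (xy >= 0).all() and (xy <= 200.0).all()

    def test_true_density_matches_counts(self):
        cfg = mm.CellMapSimConfig(background_intensity={"T": 400.0, "B": 100.0},
                                  seed=9)
        m, truth = mm.simulate_cellmap(cfg)
        assert truth.true_density["B"] * m.tissue_area_mm2 == pytest.approx(
            (m.cells["phenotype"] == "B").sum())

    def test_intended_class_thresholds(self):
        cfg = mm.CellMapSimConfig(
            background_intensity={},
            aggregates=[
                mm.AggregateSpec({"T": 1.0}, 5, 5.0, center=(100.0, 100.0)),
                mm.AggregateSpec({"T": 1.0}, 50, 5.0, center=(400.0, 400.0)),
                mm.AggregateSpec({"T": 0.9, "B": 0.1}, 150, 6.0,
                                 center=(800.0, 800.0))],
            min_cell_spacing_um=1.0, seed=13)
        _, truth = mm.simulate_cellmap(cfg)
        assert truth.intended_class[1] == "below_threshold"
        assert truth.intended_class[2] == "network"
        assert truth.intended_class[3] in ("large_network", "lymphoid_aggregate")

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            mm.AggregateSpec({"T": 0.6}, 10, 5.0)          # fractions != 1
        with pytest.raises(ValueError):
            mm.AggregateSpec({"T": 1.0}, -1, 5.0)          # negative count
        with pytest.raises(ValueError):
            mm.AggregateSpec({"T": 1.0}, 10, 0.0)          # sigma <= 0
        with pytest.raises(ValueError):
            mm.CellMapSimConfig(background_intensity={"T": -5.0})


@pytest.fixture(scope="module")
def reference():
    return mm.default_reference_profiles()


class TestSimulateMixtures:
    def test_one_hot_equals_scaled_column(self, reference):
        props = pd.DataFrame(np.eye(len(reference.columns)),
                             index=[f"P{i}" for i in range(len(reference.columns))],
                             columns=reference.columns)
        cfg = mm.MixtureSimConfig(signature=reference, true_proportions=props,
                                  library_scale=3.0, noise_model="none")
        expr, truth = mm.simulate_expression_mixtures(cfg)
        for i, ct in enumerate(reference.columns):
            np.testing.assert_allclose(expr[f"P{i}"], 3.0 * reference[ct])
        pd.testing.assert_frame_equal(truth, props)

    def test_fifty_fifty_linearity(self, reference):
        a, b = reference.columns[:2]
        props = pd.DataFrame([{a: 0.5, b: 0.5}], index=["m"]).reindex(
            columns=reference.columns, fill_value=0.0)
        cfg = mm.MixtureSimConfig(signature=reference, true_proportions=props)
        expr, _ = mm.simulate_expression_mixtures(cfg)
        np.testing.assert_allclose(expr["m"],
                                   0.5 * (reference[a] + reference[b]))

    def test_lognormal_noise_mean_corrected(self, reference):
        # mean-one lognormal factor: per-gene mean over 50 samples within
        # 10% of the noiseless value
        props = pd.DataFrame([[1.0 / len(reference.columns)] * len(reference.columns)] * 50,
                             index=[f"S{i}" for i in range(50)],
                             columns=reference.columns)
        cfg = mm.MixtureSimConfig(signature=reference, true_proportions=props,
                                  noise_model="lognormal", noise_sd=0.2, seed=8)
        expr, _ = mm.simulate_expression_mixtures(cfg)
        noiseless = reference.mean(axis=1)
        ratio = expr.mean(axis=1) / noiseless
        assert ((ratio - 1).abs() < 0.10).all()

    def test_determinism(self, reference):
        props = pd.DataFrame([[1 / 7.0] * 7], index=["s"],
                             columns=reference.columns)
        cfg = mm.MixtureSimConfig(signature=reference, true_proportions=props,
                                  noise_model="lognormal", noise_sd=0.3, seed=4)
        e1, _ = mm.simulate_expression_mixtures(cfg)
        e2, _ = mm.simulate_expression_mixtures(cfg)
        pd.testing.assert_frame_equal(e1, e2)

    def test_negative_signature_rejected(self, reference):
        bad = reference.copy()
        bad.iloc[0, 0] = -1.0
        props = pd.DataFrame([[1 / 7.0] * 7], index=["s"], columns=bad.columns)
        with pytest.raises(ValueError, match="negative"):
            mm.MixtureSimConfig(signature=bad, true_proportions=props)

    def test_proportions_must_sum_to_one(self, reference):
        props = pd.DataFrame([[0.5] * 7], index=["s"], columns=reference.columns)
        with pytest.raises(ValueError, match="sum to 1"):
            mm.MixtureSimConfig(signature=reference, true_proportions=props)


class TestSimulateRegions:
    def test_minimal_design(self):
        ds = mm.simulate_region_dataset(
            n_regions={"LA": 1, "MIXED1": 1, "MIXED2": 1, "CONTROL": 1}, seed=0)
        assert len(ds.annotations) == 4
        assert set(ds.annotations["region_type"]) == {"LA", "MIXED1", "MIXED2",
                                                      "CONTROL"}

    def test_default_design_counts(self):
        ds = mm.simulate_region_dataset(seed=1)
        counts = ds.annotations["region_type"].value_counts()
        assert counts["LA"] == 35 and counts["MIXED1"] == 48
        assert counts["MIXED2"] == 44 and counts["CONTROL"] == 16
        assert ds.annotations["cell_count"].between(126, 826).all()

    def test_mixed1_biopsies_contain_la(self):
        ds = mm.simulate_region_dataset(seed=2)
        ann = ds.annotations
        la_biopsies = set(ann.loc[ann["region_type"] == "LA", "biopsy_id"])
        m1_biopsies = set(ann.loc[ann["region_type"] == "MIXED1", "biopsy_id"])
        assert m1_biopsies <= la_biopsies
        m2_biopsies = set(ann.loc[ann["region_type"] == "MIXED2", "biopsy_id"])
        assert not (m2_biopsies & la_biopsies)

    def test_zero_effect_null_calibration(self):
        # with effect 0 all four region types are exchangeable: the
        # omnibus test on the chemokine score rejects at ~nominal rate
        effects = {k: 0.0 for k in ("T_CD4", "T_CD8", "B", "PLASMA", "MAC_M1")}
        n = {"LA": 8, "MIXED1": 8, "MIXED2": 8, "CONTROL": 8}
        sig = next(s for s in mm.default_signatures() if s.name == "12chem")
        reps = 300
        rejections = 0
        for seed in range(reps):
            ds = mm.simulate_region_dataset(n_regions=n, effect_sizes=effects,
                                            seed=seed)
            scores = mm.signature_zscore(ds.expression, sig).scores
            res = mm.compare_scores_by_region(scores, ds.annotations, alpha=0.05)
            rejections += res.omnibus.pvalue < 0.05
        assert abs(rejections / reps - 0.05) < 0.04

    def test_invalid_counts_fail(self):
        with pytest.raises(ValueError, match="n_regions"):
            mm.simulate_region_dataset(n_regions={"LA": 0, "MIXED2": 5}, seed=0)

    def test_negative_effect_fails(self):
        with pytest.raises(ValueError, match="effect"):
            mm.simulate_region_dataset(effect_sizes={"B": -1.0}, seed=0)

    def test_determinism(self):
        d1 = mm.simulate_region_dataset(seed=11)
        d2 = mm.simulate_region_dataset(seed=11)
        pd.testing.assert_frame_equal(d1.expression, d2.expression)
        pd.testing.assert_frame_equal(d1.annotations, d2.annotations)


class TestNoiselessIdentityWithDeconvolution:
    def test_mixture_identity(self, rng):
        # noiseless simulated mixtures deconvolve back to the planted
        # proportions against the same signature matrix
        ref = mm.default_reference_profiles()
        props = pd.DataFrame(rng.dirichlet(np.ones(7), size=5),
                             index=[f"S{i}" for i in range(5)],
                             columns=ref.columns)
        cfg = mm.MixtureSimConfig(signature=ref, true_proportions=props)
        expr, truth = mm.simulate_expression_mixtures(cfg)
        res = mm.nnls_deconvolve(expr, ref)
        assert (res.proportions - truth).abs().to_numpy().max() <= 1e-6
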