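"""Synthetic study generator: parcellation, cohort, dynamics, maps, expression."""

import numpy as np
import pytest
from scipy import stats

import connctl as cc
from connctl.controllability import modal_controllability, normalize_system
from connctl.synthetic import (
    GROUPS,
    POWER_NETWORK_SIZES,
    COHORT_SUMMARY_DEFAULTS,
    GroundTruth,
    GroundTruthEffect,
    cohort_frame,
    generate_annotation_maps,
    generate_expression,
)


class TestParcellation:
    def test_default_composition_matches_reference_atlas(self):
        p = cc.generate_parcellation(264, seed=0)
        counts = {k: int(np.sum(p.networks == k)) for k in POWER_NETWORK_SIZES}
        assert counts == POWER_NETWORK_SIZES
        assert p.n_nodes == 264

    def test_largest_remainder_allocation(self):
        p = cc.generate_parcellation(10, network_spec={"A": 0.55, "B": 0.45}, seed=0)
        assert int(np.sum(p.networks == "A")) == 6  # 5.5 rounds up first
        assert int(np.sum(p.networks == "B")) == 4

    def test_single_network(self):
        p = cc.generate_parcellation(10, network_spec={"X": 1.0}, seed=1)
        assert set(p.networks) == {"X"}

    def test_determinism_and_clustering(self):
        p1 = cc.generate_parcellation(50, seed=7)
        p2 = cc.generate_parcellation(50, seed=7)
        np.testing.assert_array_equal(p1.coords, p2.coords)
        np.testing.assert_array_equal(p1.networks, p2.networks)
        # same-network nodes are closer on average than different-network nodes
        d = np.linalg.norm(p1.coords[:, None] - p1.coords[None], axis=-1)
        same = p1.networks[:, None] == p1.networks[None]
        iu = np.triu_indices(50, 1)
        assert d[iu][same[iu]].mean() < d[iu][~same[iu]].mean()

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cc.generate_parcellation(10, network_spec={"A": 0.5, "B": 0.4})

    def test_roundtrip(self, tmp_path, parcellation):
        parcellation.write(tmp_path / "atlas.tsv")
        back = type(parcellation).read(tmp_path / "atlas.tsv")
        np.testing.assert_allclose(back.coords, parcellation.coords)
        np.testing.assert_array_equal(back.networks, parcellation.networks)


class TestCohort:
    def test_default_totals(self):
        cohort = cc.generate_cohort(seed=0)
        assert len(cohort) == 303
        sizes = {g: sum(1 for r in cohort if r.diagnosis == g) for g in GROUPS}
        assert sizes == {"SZ": 105, "BD": 67, "MDD": 51, "HC": 80}

    def test_minimal_groups(self):
        cohort = cc.generate_cohort({g: 2 for g in GROUPS}, seed=0)
        assert len(cohort) == 8

    def test_group_means_match_generator_distribution(self):
        """Monte-Carlo: empirical mean age per group ~ truncated-normal mean."""
        ages = {g: [] for g in GROUPS}
        for seed in range(100):
            for r in cc.generate_cohort({g: 10 for g in GROUPS}, seed=seed):
                ages[r.diagnosis].append(r.age)
        cfg = COHORT_SUMMARY_DEFAULTS["continuous"]["age"]
        lo, hi = cfg["bounds"]
        for g in GROUPS:
            mean, sd = cfg["params"][g]
            a, b = (lo - mean) / sd, (hi - mean) / sd
            expected = stats.truncnorm.mean(a, b, loc=mean, scale=sd)
            se = np.std(ages[g], ddof=1) / np.sqrt(len(ages[g]))
            assert abs(np.mean(ages[g]) - expected) < 3 * se

    def test_score_availability_mirrors_groups(self, small_cohort):
        df = cohort_frame(small_cohort)
        assert df.loc[df.diagnosis == "HC", "bprs"].isna().all()
        assert df.loc[df.diagnosis == "SZ", "ymrs"].isna().all()
        assert df.loc[df.diagnosis != "HC", "illness_duration"].notna().all()
        assert df["acc_2back"].between(0, 1).all()

    def test_severity_score_link(self):
        """Linked scores track latent severity at roughly the configured rho."""
        rs = []
        for seed in range(30):
            cohort = cc.generate_cohort({"SZ": 60, "BD": 2, "MDD": 2, "HC": 2}, seed=seed)
            sz = [r for r in cohort if r.diagnosis == "SZ"]
            sev = np.array([r.severity for r in sz])
            bprs = np.array([r.clinical["bprs"] for r in sz])
            rs.append(stats.spearmanr(sev, bprs).statistic)
        assert np.mean(rs) == pytest.approx(0.5, abs=0.1)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            cc.generate_cohort({"SZ": 1, "BD": 2, "MDD": 2, "HC": 2})


class TestGroundTruth:
    def test_template_ordering_on_affected_nodes(self, ground_truth):
        """Graded frontoparietal modal deficit: SZ < BD ~ MDD < HC."""
        aff = ground_truth.affected_nodes("mc", "2back")
        assert len(aff) > 0
        mc = {
            g: modal_controllability(
                normalize_system(ground_truth.group_coupling(g, "2back"))
            )[aff].mean()
            for g in GROUPS
        }
        assert mc["SZ"] < mc["BD"] < mc["HC"]
        assert mc["SZ"] < mc["MDD"] < mc["HC"]
        assert mc["BD"] == pytest.approx(mc["MDD"], abs=0.01)

    def test_ac_attenuation_lowers_average_controllability(self, ground_truth):
        from connctl.controllability import average_controllability

        aff = ground_truth.affected_nodes("ac", "2back")
        ac = {
            g: average_controllability(
                normalize_system(ground_truth.group_coupling(g, "2back"))
            )[aff].mean()
            for g in ("SZ", "HC")
        }
        assert ac["SZ"] < ac["HC"]

    def test_stability_asserted_for_all_groups_and_severities(self, ground_truth):
        for g in GROUPS:
            for load in ("0back", "2back"):
                for sev in (-2.5, 0.0, 2.5):
                    a = ground_truth.coupling(g, load, sev)
                    assert np.max(np.abs(np.linalg.eigvalsh(a))) < 1.0

    def test_unstable_baseline_rejected(self):
        m = np.array([[0.0, 1.2], [1.2, 0.0]])
        with pytest.raises(ValueError, match="spectral radius"):
            GroundTruth(m, np.zeros(2))

    def test_effect_nodes_validated(self):
        m = np.zeros((3, 3))
        eff = GroundTruthEffect("x", np.array([5]), "2back", {"SZ": 2.0})
        with pytest.raises(ValueError, match="outside"):
            GroundTruth(m, np.zeros(3), (eff,))


class TestTimeseries:
    def test_shape_and_determinism(self, ground_truth, small_cohort):
        ts1 = cc.generate_timeseries(small_cohort[0], "2back", ground_truth, seed=5)
        ts2 = cc.generate_timeseries(small_cohort[0], "2back", ground_truth, seed=5)
        assert ts1.data.shape == (4, 20, ground_truth.n_nodes)
        np.testing.assert_array_equal(ts1.data, ts2.data)

    def test_zero_coupling_tiny_noise_is_flat(self, small_cohort):
        truth = GroundTruth(np.zeros((5, 5)), np.zeros(5))
        ts = cc.generate_timeseries(small_cohort[0], "0back", truth, noise_sd=1e-12, seed=0)
        assert np.max(np.abs(ts.data)) < 1e-10

    def test_stationary_variance_zero_coupling(self, small_cohort):
        """With A = 0 the marginal SD equals the innovation SD."""
        truth = GroundTruth(np.zeros((4, 4)), np.zeros(4))
        draws = [
            cc.generate_timeseries(small_cohort[0], "0back", truth, noise_sd=2.0, seed=s).data
            for s in range(40)
        ]
        sd = np.std(np.concatenate([d.ravel() for d in draws]))
        assert sd == pytest.approx(2.0, rel=0.05)

    def test_invalid_noise_rejected(self, ground_truth, small_cohort):
        with pytest.raises(ValueError, match="noise_sd"):
            cc.generate_timeseries(small_cohort[0], "0back", ground_truth, noise_sd=0.0)


class TestAnnotationMaps:
    def test_rho_one_reproduces_target(self, parcellation, rng):
        target = rng.normal(size=parcellation.n_nodes)
        (m,) = generate_annotation_maps(parcellation, 1, target, rho=1.0, seed=0)
        r = np.corrcoef(m.values, target)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_realized_correlation_equals_rho(self, parcellation, rng):
        target = rng.normal(size=parcellation.n_nodes)
        for rho in (0.0, 0.4, 0.9, -0.6):
            (m,) = generate_annotation_maps(parcellation, 1, target, rho=rho, seed=3)
            r = np.corrcoef(m.values, target)[0, 1]
            assert r == pytest.approx(rho, abs=1e-10)

    def test_nine_tracer_names(self, parcellation):
        maps = generate_annotation_maps(parcellation, 9, seed=0)
        assert len({m.name for m in maps}) == 9
        assert maps[0].name == "dopamine"

    def test_constant_target_rejected(self, parcellation):
        with pytest.raises(ValueError, match="constant"):
            generate_annotation_maps(parcellation, 1, np.ones(parcellation.n_nodes), rho=0.5)

    def test_invalid_rho_rejected(self, parcellation, rng):
        with pytest.raises(ValueError, match="rho"):
            generate_annotation_maps(
                parcellation, 1, rng.normal(size=parcellation.n_nodes), rho=1.5
            )

    def test_spatial_autocorrelation_present(self, parcellation):
        (m,) = generate_annotation_maps(parcellation, 1, smoothing_scale=20.0, seed=4)
        d = np.linalg.norm(parcellation.coords[:, None] - parcellation.coords[None], axis=-1)
        iu = np.triu_indices(parcellation.n_nodes, 1)
        z = (m.values - m.values.mean()) / m.values.std()
        prods = (z[:, None] * z[None])[iu]
        near = prods[d[iu] < np.quantile(d[iu], 0.2)].mean()
        far = prods[d[iu] > np.quantile(d[iu], 0.8)].mean()
        assert near > far


class TestExpression:
    def test_determinism(self, parcellation):
        e1 = generate_expression(parcellation, n_genes=10, seed=5)
        e2 = generate_expression(parcellation, n_genes=10, seed=5)
        np.testing.assert_array_equal(e1.values, e2.values)

    def test_planted_effect_recovered(self, parcellation):
        """Region-minus-background mean difference matches the planted shift."""
        region = np.arange(parcellation.n_nodes // 2)
        deltas = []
        for seed in range(50):
            expr = generate_expression(
                parcellation, n_genes=1, de_spec=[([0], region, 2.0)], seed=seed
            )
            col = expr.values[:, 0]
            deltas.append(col[region].mean() - np.delete(col, region).mean())
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas) - 2.0) < 3 * se

    def test_zero_effect_no_shift(self, parcellation):
        region = np.arange(5)
        expr = generate_expression(parcellation, n_genes=3, de_spec=[([0], region, 0.0)], seed=1)
        base = generate_expression(parcellation, n_genes=3, seed=1)
        np.testing.assert_array_equal(expr.values, base.values)

    def test_empty_region_with_effect_rejected(self, parcellation):
        with pytest.raises(ValueError, match="empty region"):
            generate_expression(parcellation, n_genes=2, de_spec=[([0], [], 1.0)], seed=0)

    def test_unique_gene_ids(self, parcellation):
        expr = generate_expression(parcellation, n_genes=7, seed=0)
        assert len(set(expr.gene_ids)) == 7
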