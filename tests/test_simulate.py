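"""Synthetic-data generator: structure, determinism, calibration, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import smallarea as sa
from _oracles import logit_normal_prevalence


class TestGenerateHierarchy:
    def test_fixed_counts(self, toy_hierarchy):
        h = toy_hierarchy
        assert len(h) == 16
        assert h["cluster_id"].nunique() == 8
        assert h["district_id"].nunique() == 4
        assert h["state_id"].nunique() == 2

    def test_single_district_state(self):
        h = sa.generate_hierarchy(1, 1, 5, 22, seed=1)
        assert h["district_id"].nunique() == 1
        assert h["cluster_id"].nunique() == 5
        assert len(h) == 5 * 22

    def test_profile_recount(self):
        """Realised totals match an independent recount of the emitted index."""
        h = sa.generate_hierarchy(**sa.PROFILES["nfhs-small"], seed=5)
        per_cluster = h.groupby("cluster_id").size()
        assert (per_cluster == 22).all()
        d_per_s = h.groupby("state_id")["district_id"].nunique()
        assert d_per_s.between(5, 15).all() and len(d_per_s) == 30
        c_per_d = h.groupby("district_id")["cluster_id"].nunique()
        assert c_per_d.between(4, 8).all()
        assert len(h) == 22 * h["cluster_id"].nunique()

    def test_strict_nesting(self):
        h = sa.generate_hierarchy(5, (2, 6), (2, 5), (10, 25), seed=9)
        assert (h.groupby("cluster_id")["district_id"].nunique() == 1).all()
        assert (h.groupby("district_id")["state_id"].nunique() == 1).all()
        assert h["child_id"].is_unique

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_states=0), "n_states"),
            (dict(districts_per_state=0), "districts_per_state"),
            (dict(clusters_per_district=(3, 1)), "clusters_per_district"),
            (dict(children_per_cluster=-2), "children_per_cluster"),
        ],
    )
    def test_bad_counts_rejected(self, kwargs, msg):
        base = dict(n_states=2, districts_per_state=2, clusters_per_district=2,
                    children_per_cluster=2, seed=0)
        with pytest.raises(ValueError, match=msg):
            sa.generate_hierarchy(**{**base, **kwargs})

    def test_children_range_does_not_perturb_hierarchy(self):
        a = sa.generate_hierarchy(3, (2, 4), (2, 4), 5, seed=3)
        b = sa.generate_hierarchy(3, (2, 4), (2, 4), (5, 30), seed=3)
        assert a["cluster_id"].unique().tolist() == b["cluster_id"].unique().tolist()


class TestSimulateOutcomes:
    def test_identity_case_probability_half(self):
        h = sa.generate_hierarchy(5, 4, 5, 60, seed=2)
        truth = sa.SimulationTruth(beta0=0.0, sigma2_state=0, sigma2_district=0,
                                   sigma2_cluster=0, seed=1)
        rec = sa.simulate_outcomes(h, truth)
        p = rec["outcome"].mean()
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / len(rec))

    def test_marginal_prevalence_matches_quadrature(self):
        """MC prevalence matches the logit-normal integral at n=50,000."""
        h = sa.generate_hierarchy(50, 5, 10, 20, seed=11)
        assert len(h) == 50_000
        truth = sa.SimulationTruth(beta0=float(logit(0.176)), sigma2_state=0.18,
                                   sigma2_district=0.07, sigma2_cluster=0.28, seed=12)
        rec = sa.simulate_outcomes(h, truth)
        expected = logit_normal_prevalence(truth.beta0, 0.53)
        # the cluster-level mixture has finite design, so allow design effect
        # on top of binomial error: ~2500 effective units
        assert abs(rec["outcome"].mean() - expected) < 4 * np.sqrt(
            expected * (1 - expected) / 2500
        )

    def test_consistency_of_weight_and_size_with_outcome(self, sim_records):
        rec = sim_records
        assert ((rec["birth_weight_g"] < 2500) == (rec["outcome"] == 1)).all()
        small = rec["birth_size"].isin(["very_small", "smaller_than_average"])
        assert (small == (rec["outcome"] == 1)).all()

    def test_seed_determinism(self, toy_hierarchy):
        truth = sa.SimulationTruth(beta0=-1.0, sigma2_state=0.1, sigma2_district=0.1,
                                   sigma2_cluster=0.3, seed=77)
        a = sa.simulate_outcomes(toy_hierarchy, truth)
        b = sa.simulate_outcomes(toy_hierarchy, truth)
        pd.testing.assert_frame_equal(a, b)

    def test_row_order_invariance(self, toy_hierarchy):
        truth = sa.SimulationTruth(beta0=-1.0, sigma2_state=0.1, sigma2_district=0.1,
                                   sigma2_cluster=0.3, seed=77)
        a = sa.simulate_outcomes(toy_hierarchy, truth)
        shuffled = toy_hierarchy.sample(frac=1.0, random_state=0)
        b = sa.simulate_outcomes(shuffled, truth).sort_values("child_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a.sort_values("child_id").reset_index(drop=True), b)

    def test_empty_hierarchy_rejected(self, toy_hierarchy):
        truth = sa.SimulationTruth(beta0=0, sigma2_state=0, sigma2_district=0,
                                   sigma2_cluster=0, seed=1)
        with pytest.raises(ValueError, match="empty"):
            sa.simulate_outcomes(toy_hierarchy.iloc[:0], truth)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError, match="sigma2_district"):
            sa.SimulationTruth(beta0=0, sigma2_state=0, sigma2_district=-0.1,
                               sigma2_cluster=0, seed=1)

    def test_cluster_logit_variance_monotone_in_sigma2_cluster(self):
        """Empirical variance of cluster logits grows with the latent variance."""
        h = sa.generate_hierarchy(10, 4, 6, 50, seed=21)
        spreads = []
        for s2c in (0.05, 0.4, 1.5):
            truth = sa.SimulationTruth(beta0=-1.0, sigma2_state=0.1, sigma2_district=0.05,
                                       sigma2_cluster=s2c, seed=22)
            rec = sa.simulate_outcomes(h, truth)
            g = rec.groupby("cluster_id")["outcome"].agg(["sum", "size"])
            el = np.log((g["sum"] + 0.5) / (g["size"] - g["sum"] + 0.5))
            spreads.append(el.var())
        assert spreads[0] < spreads[1] < spreads[2]


class TestApplyMissingness:
    def test_all_zero_is_identity(self, sim_records):
        out = sa.apply_missingness(sim_records, sa.MissingnessSpec(seed=1))
        pd.testing.assert_frame_equal(out, sim_records)

    def test_marginal_rate(self):
        h = sa.generate_hierarchy(10, 5, 4, 100, seed=31)
        truth = sa.SimulationTruth(beta0=-1.5, sigma2_state=0.1, sigma2_district=0.05,
                                   sigma2_cluster=0.2, seed=32)
        rec = sa.simulate_outcomes(h, truth)
        assert len(rec) == 20_000
        out = sa.apply_missingness(rec, sa.MissingnessSpec(p_missing_weight=0.254, seed=33))
        frac = out["birth_weight_g"].isna().mean()
        # 99% binomial bounds around 0.254
        half = 2.576 * np.sqrt(0.254 * 0.746 / len(out))
        assert abs(frac - 0.254) < half

    def test_gradient_targets_deprived_clusters(self, sim_records):
        spec = sa.MissingnessSpec(p_missing_weight=0.25, cluster_gradient=2.0, seed=5)
        out = sa.apply_missingness(sim_records, spec)
        miss = out["birth_weight_g"].isna()
        assert out.loc[miss, "deprivation_score"].mean() > out.loc[~miss, "deprivation_score"].mean()
        # marginal rate still on target despite the tilt
        assert abs(miss.mean() - 0.25) < 0.02

    def test_forced_whole_cluster_missingness(self, sim_records):
        spec = sa.MissingnessSpec(p_cluster_all_missing=0.2, seed=5)
        out = sa.apply_missingness(sim_records, spec)
        frac_missing = out.groupby("cluster_id")["birth_weight_g"].agg(lambda s: s.isna().mean())
        n_clusters = sim_records["cluster_id"].nunique()
        assert (frac_missing == 1.0).sum() == round(0.2 * n_clusters)

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValueError, match="p_missing_weight"):
            sa.MissingnessSpec(p_missing_weight=1.2)


class TestSerialisation:
    def test_csv_round_trip(self, sim_records, tmp_path):
        spec = sa.MissingnessSpec(p_missing_weight=0.2, p_missing_size=0.05, seed=3)
        rec = sa.apply_missingness(sim_records, spec)
        path = tmp_path / "data.csv"
        sa.write_records_csv(rec, path)
        fields = {f for line in path.read_text().splitlines() for f in line.split(",")}
        assert "." not in fields  # missing is the empty string, never "."
        back = sa.read_records_csv(path)
        assert len(back) == len(rec)
        assert back["birth_weight_g"].isna().sum() == rec["birth_weight_g"].isna().sum()
        assert (back["child_id"] == rec["child_id"].to_numpy()).all()

    def test_truth_json_round_trip(self, tmp_path):
        truth = sa.SimulationTruth(beta0=-1.54, sigma2_state=0.18, sigma2_district=0.07,
                                   sigma2_cluster=0.28, seed=9)
        sa.simulate.write_truth_json(truth, tmp_path / "t.json")
        assert sa.simulate.read_truth_json(tmp_path / "t.json") == truth
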