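"""Generator properties: determinism, conservation, capture-model shape."""

import numpy as np
import pandas as pd
import pytest

from capmeth import synthetic as sd
from capmeth.aux import bulk_percent_unmethylated


class TestGroundTruth:
    def test_rejects_empty_transcriptome(self):
        with pytest.raises(ValueError):
            sd.generate_ground_truth(0, "starvation", seed=1)

    def test_rich_medium_is_near_fully_methylated(self):
        t = sd.generate_ground_truth(100, "rich_only", seed=1)
        assert (t["meth_frac_rich"] >= 0.95).all()
        assert t["meth_frac_min"].equals(t["meth_frac_rich"])

    @pytest.mark.parametrize("scenario", ["rich_only", "starvation"])
    def test_seed_determinism(self, scenario):
        a = sd.generate_ground_truth(100, scenario, seed=1)
        b = sd.generate_ground_truth(100, scenario, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_fields_within_bounds(self, truth_small):
        t = truth_small
        assert ((t["meth_frac_min"] >= 0) & (t["meth_frac_min"] <= 1)).all()
        assert ((t["meth_frac_rich"] >= 0) & (t["meth_frac_rich"] <= 1)).all()
        assert (t["abundance_rich"] > 0).all() and (t["abundance_min"] > 0).all()
        assert ((t["intron_frac"] >= 0) & (t["intron_frac"] <= 1)).all()
        assert (t["intron_frac"] > 0).any()

    def test_starvation_mixture_mean_recovered(self):
        t = sd.generate_ground_truth(1000, "starvation", seed=7)
        target = sd.GroundTruthParams().unmethylated_mean
        assert abs((1.0 - t["meth_frac_min"]).mean() - target) < 0.05

    def test_planted_term_genes_drawn_from_high_mode(self):
        p = sd.GroundTruthParams(planted_term="PLANTED", planted_term_frac=0.1)
        t = sd.generate_ground_truth(500, "starvation", seed=2, params=p)
        planted = t["gene_sets"].str.contains("PLANTED")
        assert 0.05 < planted.mean() < 0.15
        assert t.loc[planted, "meth_frac_min"].mean() > t.loc[~planted, "meth_frac_min"].mean()


class TestLibraries:
    def test_seed_determinism(self, truth_small):
        cfg = sd.AssayConfig(depth=1e5, seed=4)
        a = sd.simulate_libraries(truth_small, cfg)
        b = sd.simulate_libraries(truth_small, cfg)
        assert a == b

    def test_capture_model_boundaries(self, truth_small):
        """m=1 with no background gives IP mean = A*eta and zero pulldown;
        m=0 gives zero IP signal."""
        truth = truth_small.copy()
        cfg = sd.AssayConfig(beta_ip=0.0, beta_tag=0.0, dispersion=0.0)
        for m_val in (1.0, 0.0):
            truth["meth_frac_min"] = m_val
            exp = sd.expected_libraries(truth, cfg)
            ip_col = exp.counts["ip_min_ip_1"].loc[truth.index]
            pull_col = exp.counts["captag_min_pulldown_1"].loc[truth.index]
            if m_val == 1.0:
                scaled = truth["abundance_min"] * cfg.eta_ip
                np.testing.assert_allclose(
                    ip_col / scaled, (ip_col / scaled).iloc[0], rtol=1e-12
                )
                np.testing.assert_allclose(pull_col, 0.0, atol=1e-12)
            else:
                np.testing.assert_allclose(ip_col, 0.0, atol=1e-12)

    def test_conservation_pre_noise(self, truth_small):
        """Methylated + unmethylated expected molecules sum to A_g exactly:
        the input library mean is proportional to abundance alone."""
        cfg = sd.AssayConfig(dispersion=0.0)
        exp = sd.expected_libraries(truth_small, cfg)
        inp = exp.counts["ip_min_input_1"].loc[truth_small.index]
        ratio = inp / truth_small["abundance_min"]
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-12)

    def test_monotonicity_in_methylation(self):
        """Higher m strictly raises expected IP signal and lowers pulldown."""
        t = sd.generate_ground_truth(50, "starvation", seed=8)
        t["abundance_min"] = 100.0
        t["meth_frac_min"] = np.linspace(0.0, 1.0, 50)
        exp = sd.expected_libraries(t, sd.AssayConfig(dispersion=0.0))
        ip_col = exp.counts["ip_min_ip_1"].loc[t.index].to_numpy()
        pull = exp.counts["captag_min_pulldown_1"].loc[t.index].to_numpy()
        assert (np.diff(ip_col) > 0).all()
        assert (np.diff(pull) < 0).all()

    def test_spike_rows_independent_of_methylation(self, truth_small):
        t2 = truth_small.copy()
        t2["meth_frac_min"] = 0.123
        cfg = sd.AssayConfig(dispersion=0.0)
        a = sd.expected_libraries(truth_small, cfg)
        b = sd.expected_libraries(t2, cfg)
        # expected spike molecules (pre library scaling) are identical; compare
        # spike-to-spike proportions, which do not depend on truth methylation
        sa = a.counts.loc[a.spike_flag, "ip_min_input_1"]
        sb = b.counts.loc[b.spike_flag, "ip_min_input_1"]
        np.testing.assert_allclose(sa / sa.sum(), sb / sb.sum(), rtol=1e-12)

    def test_zero_dispersion_matches_poisson_means(self):
        """With dispersion 0 the per-gene sample mean over 200 replicate
        libraries stays within 3 standard errors of the analytic mean."""
        params = sd.GroundTruthParams()
        t = sd.generate_ground_truth(50, "rich_only", seed=3, params=params)
        cfg = sd.AssayConfig(
            depth=1e4, dispersion=0.0, n_replicates=200, conditions=("rich",), seed=3
        )
        sim = sd.simulate_libraries(t, cfg)
        exp = sd.expected_libraries(t, cfg)
        cols = [f"ip_rich_input_{r}" for r in range(1, 201)]
        mu = exp.counts[cols[0]].loc[t.index]
        sample_mean = sim.counts[cols].loc[t.index].mean(axis=1)
        se = np.sqrt(mu / 200.0)
        assert (np.abs(sample_mean - mu) <= 3 * se).all()

    def test_missing_spike_configuration_rejected(self):
        with pytest.raises(Exception):
            sd.AssayConfig(n_spikes_ercc=0)


class TestBulkCap:
    def test_fully_methylated_has_no_gpppn(self, truth_small):
        t = truth_small.copy()
        t["meth_frac_min"] = 1.0
        s = sd.simulate_bulk_cap(t, noise_cv=0.0)
        assert s["GpppA"] == 0.0 and s["GpppG"] == 0.0

    def test_noiseless_percent_matches_definition(self, truth_small):
        s = sd.simulate_bulk_cap(truth_small, noise_cv=0.0)
        t = truth_small
        expect = (
            (t["abundance_min"] * (1 - t["meth_frac_min"])).sum()
            / t["abundance_min"].sum()
            * 100.0
        )
        assert bulk_percent_unmethylated(s) == pytest.approx(expect, rel=1e-12)

    def test_monte_carlo_mean_matches_preset(self):
        """Preset tuned to 50% unmethylated caps: 50-seed mean within 2 pp."""
        params = sd.GroundTruthParams(mixture_means=(0.4, 0.9))
        assert params.unmethylated_mean == pytest.approx(0.5)
        vals = []
        for seed in range(50):
            t = sd.generate_ground_truth(1000, "starvation", seed=seed, params=params)
            s = sd.simulate_bulk_cap(t, noise_cv=0.05, seed=seed)
            vals.append(bulk_percent_unmethylated(s))
        assert abs(np.mean(vals) - 50.0) < 2.0

    def test_seed_determinism(self, truth_small):
        a = sd.simulate_bulk_cap(truth_small, noise_cv=0.1, seed=9)
        b = sd.simulate_bulk_cap(truth_small, noise_cv=0.1, seed=9)
        pd.testing.assert_series_equal(a, b)
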