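import math

import numpy as np
import pytest

from mutevol import simulate as sim
from mutevol.filtering import filter_pipeline
from mutevol.rates import rate_table


class TestGenGenome:
    def test_deterministic(self):
        a = sim.gen_genome(10, seed=3)
        b = sim.gen_genome(10, seed=3)
        assert a.sequences == b.sequences

    def test_seed_changes_sequence(self):
        assert sim.gen_genome(50, seed=1) != sim.gen_genome(50, seed=2)

    def test_gc_content_binomial_bound(self):
        g = sim.gen_genome(1_000_000, gc_fraction=0.5, seed=9)
        seq = g["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.497 <= gc <= 0.503  # 6 sigma of Binomial(1e6, .5)

    def test_minimum_length_has_interior_site(self):
        g = sim.gen_genome(3, seed=0)
        index = sim.ContextIndex(g)
        assert index.n_callable == 1

    def test_invalid_gc(self):
        with pytest.raises(ValueError):
            sim.gen_genome(10, gc_fraction=0.0)
        with pytest.raises(ValueError):
            sim.gen_genome(10, gc_fraction=1.5)

    def test_too_short(self):
        with pytest.raises(ValueError):
            sim.gen_genome(2)


class TestSimulateMA:
    def test_zero_rates_zero_calls(self, small_genome):
        truth = sim.MATruth(snm_rate=0.0, n_lines=3)
        calls, lines = sim.simulate_ma(truth, small_genome, seed=1)
        assert calls == []
        assert len(lines) == 3

    def test_poisson_mean_recovery(self, small_genome):
        # mean per-line SNM count should sit within 3 SE of u*G*n
        truth = sim.MATruth(
            snm_rate=2.4e-7, n_lines=25, generations_per_line=1500
        )
        calls, lines = sim.simulate_ma(truth, small_genome, seed=4)
        n = lines[0].covered_sites
        expected = truth.snm_rate * 1500 * n
        counts = np.zeros(25)
        ids = {ln.line_id: i for i, ln in enumerate(lines)}
        for c in calls:
            counts[ids[c.line_id]] += 1
        se = math.sqrt(expected / 25)
        assert abs(counts.mean() - expected) < 3 * se

    def test_shared_artifact_construction(self, small_genome):
        truth = sim.MATruth(snm_rate=0.0, n_lines=5)
        plan = sim.ArtifactPlan(n_shared_snm=2, shared_in_lines=3)
        calls, _ = sim.simulate_ma(truth, small_genome, plan, seed=6)
        shared = [c for c in calls if c.info.get("ARTIFACT") == "shared"]
        loci = {}
        for c in shared:
            loci.setdefault(c.key, set()).add(c.line_id)
        assert len(loci) == 2
        assert all(len(lines) == 3 for lines in loci.values())

    def test_lowdepth_artifacts_below_threshold(self, small_genome):
        truth = sim.MATruth(snm_rate=0.0, n_lines=4)
        plan = sim.ArtifactPlan(n_lowdepth=7)
        calls, _ = sim.simulate_ma(truth, small_genome, plan, seed=6)
        low = [c for c in calls if c.info.get("ARTIFACT") == "lowdepth"]
        assert len(low) == 7
        assert all(c.depth < 4 for c in low)

    def test_deterministic_given_seed(self, small_genome):
        truth = sim.MATruth(snm_rate=1e-7, n_lines=3)
        a, _ = sim.simulate_ma(truth, small_genome, seed=8)
        b, _ = sim.simulate_ma(truth, small_genome, seed=8)
        assert a == b

    def test_snm_ref_matches_genome(self, small_genome):
        truth = sim.MATruth(snm_rate=1e-7, n_lines=3)
        calls, _ = sim.simulate_ma(truth, small_genome, seed=8)
        for c in calls:
            if c.mclass == "SNM":
                assert small_genome[c.chrom][c.pos - 1] == c.ref
                assert c.ref != c.alt

    def test_absent_context_renormalized_with_warning(self):
        # a 3-mer genome has exactly one collapsed context, so weight on
        # the other 31 contexts must trigger renormalization
        genome = sim.gen_genome(3, seed=0)
        index = sim.ContextIndex(genome)
        with pytest.warns(UserWarning, match="renormaliz"):
            w = index.class_weights_available(np.full(96, 1 / 96))
        assert w.sum() == pytest.approx(1.0)
        assert (w > 0).sum() == 3  # one context, three possible alts


class TestEndToEndRecovery:
    def test_rates_recovered_through_filter(self, small_genome):
        truth = sim.MATruth(
            snm_rate=3e-7,
            sim_rate=6e-8,
            svm_rate=3e-4,
            n_lines=25,
            generations_per_line=1500,
        )
        calls, lines = sim.simulate_ma(truth, small_genome, seed=13)
        kept, _ = filter_pipeline(calls)
        table = rate_table(kept, lines, zscore_cutoff=None)
        n = lines[0].covered_sites
        G = 1500
        for mclass, rate, scale in [
            ("SNM", truth.snm_rate, G * n),
            ("SIM", truth.sim_rate, G * n),
            ("SV", truth.svm_rate, G),
        ]:
            mean_u = table[table.mclass == mclass]["u"].mean()
            total_m = table[table.mclass == mclass]["m"].sum()
            se = math.sqrt(max(total_m, 1)) / (25 * scale)
            assert abs(mean_u - rate) < 3 * se, mclass

    def test_outlier_line_excluded_by_zscore(self, small_genome):
        truth = sim.MATruth(
            snm_rate=2e-7, n_lines=12, generations_per_line=1500
        )
        plan = sim.ArtifactPlan(n_outlier_lines=1, inflation_factor=12.0)
        calls, lines = sim.simulate_ma(truth, small_genome, plan, seed=21)
        table = rate_table(calls, lines, zscore_cutoff=2.5)
        snm = table[table.mclass == "SNM"]
        excluded = set(snm[snm.excluded].line_id)
        assert excluded == {lines[0].line_id}


class TestSimulateFluctuation:
    def test_zero_rate_all_zero(self):
        assay = sim.simulate_fluctuation(0.0, 1e6, 30, seed=1)
        assert (assay.counts == 0).all()

    def test_p0_fraction_matches_poisson(self):
        # P(no mutants) = P(no mutation events) = exp(-m) at m = 1
        assay = sim.simulate_fluctuation(1e-6, 1e6, 10_000, seed=2)
        f0 = (assay.counts == 0).mean()
        p0 = math.exp(-1)
        se = math.sqrt(p0 * (1 - p0) / 10_000)
        assert abs(f0 - p0) < 3 * se

    def test_deterministic(self):
        a = sim.simulate_fluctuation(5e-9, 1e9, 40, seed=7)
        b = sim.simulate_fluctuation(5e-9, 1e9, 40, seed=7)
        assert (a.counts == b.counts).all()

    def test_clone_sizes_capped(self):
        assay = sim.simulate_fluctuation(1e-4, 100, 2000, seed=3)
        assert assay.counts.max() <= 100 * 50  # events * cap, loose bound

    def test_invalid_mu(self):
        with pytest.raises(ValueError):
            sim.simulate_fluctuation(1.5, 1e6, 10)


class TestSimulateDivergence:
    def test_noiseless_exact_line(self):
        s = sim.simulate_divergence(0.02, [0, 10, 20], 0.0, seed=0)
        assert np.allclose(s.divergence, [0.0, 0.2, 0.4])

    def test_single_origin_point(self):
        s = sim.simulate_divergence(1.0, [0], 0.0, seed=0)
        assert s.divergence.tolist() == [0.0]

    def test_truncation_at_zero(self):
        s = sim.simulate_divergence(0.0, list(range(50)), 1.0, seed=5)
        assert (s.divergence >= 0).all()

    def test_non_increasing_timepoints_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_divergence(1.0, [0, 5, 5], 0.0, seed=0)
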