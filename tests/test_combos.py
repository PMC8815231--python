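"""Combination-survival scan: enumeration, background sampler, q-values."""

import numpy as np
import pandas as pd
import pytest

import colmut as cm
from colmut.combos import CombinationConfig
from colmut.errors import InsufficientBackgroundError
from colmut.mutations import GeneMutationProfile, MutationClass


def profile(gene, n_mut, length=3000, family=False):
    return GeneMutationProfile(gene=gene, n_mutations=n_mut,
                               n_mutated_samples=min(n_mut, 3),
                               coding_length=length, in_family=family)


def small_config(**kw):
    defaults = dict(subset_sizes=(2,), n_background=100, seed=0)
    defaults.update(kw)
    return CombinationConfig(**defaults)


class TestEligibleGenes:
    def test_strict_threshold(self):
        expr = {"A": 200.0, "B": 200.01, "C": 1000.0}
        out = cm.eligible_genes(expr, ["A", "B", "C"], small_config())
        assert out == ["B", "C"]  # exactly 200 is excluded

    def test_zero_threshold_keeps_positives(self):
        expr = {"A": 0.5, "B": 3.0, "C": 0.0}
        cfg = small_config(expression_threshold=1e-9)
        assert cm.eligible_genes(expr, ["A", "B", "C"], cfg) == ["A", "B"]

    def test_hand_built_table(self):
        expr = {"G1": 500.0, "G2": 50.0, "G3": 201.0, "G4": 10.0, "G5": 150.0}
        out = cm.eligible_genes(expr, list(expr), small_config())
        assert out == ["G1", "G3"]

    def test_empty_result_raises(self):
        with pytest.raises(ValueError, match="threshold"):
            cm.eligible_genes({"A": 1.0}, ["A"], small_config())

    def test_missing_expression_excluded_with_warning(self, caplog):
        out = cm.eligible_genes({"A": 500.0}, ["A", "B"], small_config())
        assert out == ["A"]


def toy_matrix(samples, genes, hits):
    recs = [cm.MutationRecord(gene=g, sample=s, variant_class="Missense_Mutation")
            for s, g in hits]
    return cm.build_mutation_matrix(recs, samples, genes,
                                    {MutationClass.MISSENSE, MutationClass.TRUNCATION})


class TestEnumerate:
    def test_pair_count_before_prevalence(self):
        samples = [f"S{i}" for i in range(4)]
        matrix = toy_matrix(samples, ["A", "B", "C"],
                            [("S0", "A"), ("S1", "B"), ("S2", "C")])
        cfg = small_config(prevalence_threshold=1e-9)
        cands = cm.enumerate_candidates(["A", "B", "C"], matrix, cfg, size=2)
        assert len(cands) == 3  # C(3,2)

    def test_unmutated_subset_dropped(self):
        samples = [f"S{i}" for i in range(4)]
        matrix = toy_matrix(samples, ["A", "B", "C"], [("S0", "C")])
        cands = cm.enumerate_candidates(["A", "B"], matrix, small_config(), size=2)
        assert cands == []

    def test_boundary_prevalence_retained(self):
        # pair mutated in exactly 1 of 20 samples = 5%: kept at threshold 0.05
        samples = [f"S{i}" for i in range(20)]
        matrix = toy_matrix(samples, ["A", "B"], [("S0", "A")])
        cands = cm.enumerate_candidates(["A", "B"], matrix, small_config(), size=2)
        assert len(cands) == 1
        assert cands[0].prevalence == pytest.approx(0.05)

    def test_exclusion_never_increases_candidates(self):
        samples = [f"S{i}" for i in range(10)]
        hits = [(f"S{i}", g) for i, g in enumerate("ABCD")]
        matrix = toy_matrix(samples, list("ABCD"), hits)
        cfg = small_config(prevalence_threshold=1e-9)
        full = cm.enumerate_candidates(list("ABCD"), matrix, cfg, size=3)
        excl = cm.enumerate_candidates(list("ABCD"), matrix, cfg, size=3,
                                       excluded_subsets=[frozenset({"A", "B"})])
        assert len(excl) < len(full)
        assert all(not {"A", "B"} <= set(c.genes) for c in excl)


class TestBackgroundSampler:
    def test_total_in_window(self, rng):
        pool = [profile(f"G{i}", n) for i, n in enumerate(
            rng.integers(1, 40, size=60))]
        for _ in range(200):
            draw = cm.sample_background(pool, 100, 5, rng)
            assert 95 <= draw.total_mutations <= 105

    def test_exact_singleton_target(self, rng):
        pool = [profile("A", 17), profile("B", 1000)]
        draw = cm.sample_background(pool, 17, 0, rng)
        assert draw.genes == ("A",) and draw.total_mutations == 17

    def test_unreachable_target_raises(self, rng):
        pool = [profile("A", 50), profile("B", 60)]
        with pytest.raises(InsufficientBackgroundError):
            cm.sample_background(pool, 10, 2, rng, max_restarts=50)

    def test_mean_total_near_window_center(self, rng):
        pool = [profile(f"G{i}", n) for i, n in enumerate(
            rng.integers(1, 30, size=80))]
        totals = [cm.sample_background(pool, 200, 5, rng).total_mutations
                  for _ in range(1000)]
        assert abs(np.mean(totals) - 200) <= 10  # center +/- window width


def scan_inputs(config_kw=None, sim_kw=None):
    sim = dict(n_samples=120, n_genes=80, n_family_genes=12,
               mut_rate_mss=10.0, mut_rate_msih=40.0, frac_msih=0.4, seed=17)
    sim.update(sim_kw or {})
    config = cm.SimulationConfig(**sim)
    mut, clin, expr, genes, truth = cm.simulate_cohort(config)
    recs = cm.records_from_frame(mut)
    lengths = dict(zip(genes["gene"], genes["coding_length"]))
    expr_map = expr.set_index("gene")["mean_rsem"]
    scan_cfg = small_config(**(config_kw or {}))
    return recs, clin.set_index("sample"), expr_map, lengths, config, scan_cfg


class TestScan:
    def test_determinism(self):
        recs, clin, expr, lengths, sim_cfg, cfg = scan_inputs()
        fam = sim_cfg.family_gene_names()
        a = cm.run_combination_scan(recs, clin, expr, lengths, fam, cfg)
        b = cm.run_combination_scan(recs, clin, expr, lengths, fam, cfg)
        assert a.to_frame().equals(b.to_frame())
        assert a.inclusion == b.inclusion

    def test_q_monotone_in_p(self):
        recs, clin, expr, lengths, sim_cfg, cfg = scan_inputs()
        fam = sim_cfg.family_gene_names()
        scan = cm.run_combination_scan(recs, clin, expr, lengths, fam, cfg)
        df = scan.to_frame().sort_values("logrank_p")
        assert (np.diff(df["q_value"]) >= -1e-12).all()

    def test_candidate_scored_like_background_draw(self):
        """A gene set scored as a candidate and scored by the background
        procedure yields the identical log-rank p (same computation)."""
        recs, clin, expr, lengths, sim_cfg, cfg = scan_inputs()
        fam = sim_cfg.family_gene_names()
        samples = list(clin.index)
        matrix = cm.build_mutation_matrix(recs, samples, sorted(lengths), cfg.classes)
        from colmut.survival import PrecomputedLogRank
        t = clin["os_months"].to_numpy(float)
        e = clin["os_event"].to_numpy(int)
        pre = PrecomputedLogRank(t, e)
        genes = (fam[0], fam[1])
        p_indicator = pre.p_value(matrix.set_indicator(genes))
        mut = matrix.set_indicator(genes).astype(bool)
        p_public = cm.logrank_test((t[mut], e[mut]), (t[~mut], e[~mut])).p_value
        assert p_indicator == pytest.approx(p_public, abs=1e-12)

    def test_planted_pair_recovered(self):
        effect = [(frozenset({"FAM001", "FAM002"}), np.log(0.35))]
        recs, clin, expr, lengths, sim_cfg, cfg = scan_inputs(
            config_kw=dict(n_background=200, seed=4),
            sim_kw=dict(n_samples=300, effect_sets=effect, seed=23,
                        expression_range=(300.0, 2000.0)))
        fam = sim_cfg.family_gene_names()
        scan = cm.run_combination_scan(recs, clin, expr, lengths, fam, cfg)
        hits = [r for r in scan.results
                if set(r.genes) == {"FAM001", "FAM002"}]
        assert len(hits) == 1
        assert hits[0].direction == "longer_OS"
        assert hits[0].logrank_p < 0.01

    def test_metadata_records_thresholds(self):
        recs, clin, expr, lengths, sim_cfg, cfg = scan_inputs()
        fam = sim_cfg.family_gene_names()
        scan = cm.run_combination_scan(recs, clin, expr, lengths, fam, cfg)
        md = scan.metadata
        assert md["n_background"] == cfg.n_background
        assert md["prevalence_threshold"] == cfg.prevalence_threshold
        assert md["seed"] == cfg.seed


class TestInclusion:
    def res(self, genes, q, direction="longer_OS"):
        return cm.CombinationResult(genes=tuple(genes), n_mutated=5,
                                    prevalence=0.1, logrank_p=0.001,
                                    direction=direction, q_value=q)

    def test_no_significant_combinations(self):
        out = cm.inclusion_frequencies([self.res("AB", 0.5)], 0.05)
        assert out == {"longer_OS": {}, "shorter_OS": {}}

    def test_counts(self):
        results = [self.res(("A", "B"), 0.01), self.res(("A", "C"), 0.02),
                   self.res(("D", "E"), 0.01, "shorter_OS")]
        out = cm.inclusion_frequencies(results, 0.05)
        assert out["longer_OS"] == {"A": 2, "B": 1, "C": 1}
        assert out["shorter_OS"] == {"D": 1, "E": 1}

    def test_count_sum_equals_total_membership(self):
        results = [self.res(("A", "B", "C"), 0.01), self.res(("A", "D"), 0.04)]
        out = cm.inclusion_frequencies(results, 0.05)
        assert sum(out["longer_OS"].values()) == 5


def test_config_validation():
    with pytest.raises(ValueError):
        CombinationConfig(subset_sizes=(4,)).validate()
    with pytest.raises(ValueError):
        CombinationConfig(n_background=10).validate()
    with pytest.raises(ValueError):
        CombinationConfig(prevalence_threshold=0.0).validate()
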