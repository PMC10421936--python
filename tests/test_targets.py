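"""Seed extraction, site scanning, target-set statistics, GSEA, Jaccard."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import MIR34C_MATURE
from mirtriad.targets import (
    Seed,
    anticorrelated_overlap,
    categorize_genes,
    correlate_targets,
    extract_seed,
    gsea_preranked,
    jaccard_module_cluster,
    reverse_complement,
    scan_target_sites,
    spearman_profile,
    tabulate_eqtl_summary,
)

DNA = st.text(alphabet="ACGT", min_size=0, max_size=200)


class TestSeeds:
    def test_canonical_mir34c_seed(self):
        assert extract_seed(MIR34C_MATURE, 0).sequence == "GGCAGTG"

    def test_one_base_left_shift_seed(self):
        assert extract_seed(MIR34C_MATURE, -1).sequence == "AGGCAGT"

    def test_upstream_shift_uses_extended_sequence(self):
        extended = "TT" + MIR34C_MATURE
        seed = extract_seed(MIR34C_MATURE, -2, extended_sequence=extended,
                            mature_start=2)
        assert seed.sequence == "TAGGCAG"

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            extract_seed("ACGTAC", 0)

    def test_seed_type_enforces_heptamer(self):
        with pytest.raises(ValueError):
            Seed("m", 0, "ACGT")


class TestSiteScan:
    def naive_oracle(self, seed, utr):
        """Brute-force substring scan implementing the same site grammar."""
        m8 = reverse_complement(seed)
        a1 = reverse_complement(seed[:6]) + "A"
        sites = []
        eight = set()
        for i in range(len(utr)):
            if utr[i:i + 7] == m8:
                if utr[i + 7:i + 8] == "A":
                    sites.append(("8mer", i))
                    eight.add(i)
                else:
                    sites.append(("7mer-m8", i))
        for i in range(len(utr)):
            if utr[i:i + 7] == a1 and (i - 1) not in eight:
                sites.append(("7mer-A1", i))
        return sorted(sites, key=lambda t: (t[1], t[0]))

    def test_hand_example_8mer(self):
        sites = scan_target_sites("GGCAGTG", "AAACACTGCCAAA")
        assert [(s.site_type, s.position) for s in sites] == [("8mer", 3)]

    def test_empty_utr_has_no_sites(self):
        assert scan_target_sites("GGCAGTG", "") == []

    def test_ambiguous_bases_never_match(self):
        utr = "AAACACTGCCNAA".replace("CC", "CN")  # corrupt the site
        assert scan_target_sites("GGCAGTG", utr) == []

    def test_seven_mer_m8_without_downstream_A(self):
        sites = scan_target_sites("GGCAGTG", "CACTGCCT")
        assert [(s.site_type, s.position) for s in sites] == [("7mer-m8", 0)]

    def test_seven_mer_a1_reported(self):
        # ACTGCC (revcomp of GGCAGT) + A, without the full m8 match upstream
        sites = scan_target_sites("GGCAGTG", "TTACTGCCATT")
        assert [(s.site_type, s.position) for s in sites] == [("7mer-A1", 2)]

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(DNA)
    def test_matches_naive_oracle_on_random_utrs(self, utr):
        seed = "GGCAGTG"
        got = [(s.site_type, s.position) for s in scan_target_sites(seed, utr)]
        assert sorted(got, key=lambda t: (t[1], t[0])) == self.naive_oracle(seed, utr)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(DNA)
    def test_planted_revcomp_always_found(self, flank):
        seed = "GGCAGTG"
        utr = flank + reverse_complement(seed) + flank
        assert len(scan_target_sites(seed, utr)) >= 1


class TestGroups:
    def test_partition_example(self):
        groups = categorize_genes({"g1", "g2"}, {"g2", "g3"},
                                  {"g1", "g2", "g3", "g4"})
        assert groups.canonical_only == {"g1"}
        assert groups.isomir_only == {"g3"}
        assert groups.both == {"g2"}
        assert groups.neither == {"g4"}

    def test_identical_and_disjoint_sets(self):
        g = categorize_genes({"a"}, {"a"}, {"a", "b"})
        assert g.canonical_only == set() and g.both == {"a"}
        g = categorize_genes({"a"}, {"b"}, {"a", "b"})
        assert g.both == set()

    def test_target_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            categorize_genes({"x"}, set(), {"a"})

    def test_partition_covers_universe_disjointly(self, rng):
        universe = {f"g{i}" for i in range(50)}
        canon = set(rng.choice(sorted(universe), 20, replace=False))
        iso = set(rng.choice(sorted(universe), 15, replace=False))
        g = categorize_genes(canon, iso, universe)
        parts = [g.canonical_only, g.isomir_only, g.both, g.neither]
        assert set().union(*parts) == universe
        assert sum(len(p) for p in parts) == len(universe)


class TestCorrelation:
    def test_perfect_anticorrelation(self, rng):
        x = pd.Series(rng.normal(size=20), index=[f"s{i}" for i in range(20)])
        genes = pd.DataFrame([-x.to_numpy()], index=["g"], columns=x.index)
        prof = spearman_profile(x, genes)
        assert prof.loc["g", "rho"] == pytest.approx(-1.0)

    def test_constant_gene_excluded(self, rng):
        x = pd.Series(rng.normal(size=10), index=[f"s{i}" for i in range(10)])
        genes = pd.DataFrame([np.ones(10), x.to_numpy()], index=["flat", "ok"],
                             columns=x.index)
        prof = spearman_profile(x, genes)
        assert list(prof.index) == ["ok"]

    def test_planted_shift_detected_by_rank_sum(self, rng):
        n_samp, n_genes = 60, 100
        x = pd.Series(rng.normal(size=n_samp), index=[f"s{i}" for i in range(n_samp)])
        target_rows = [-0.6 * x.to_numpy() + rng.normal(0, 1, n_samp)
                       for _ in range(n_genes)]
        null_rows = [rng.normal(size=n_samp) for _ in range(n_genes)]
        genes = pd.DataFrame(
            target_rows + null_rows,
            index=[f"t{i}" for i in range(n_genes)] + [f"n{i}" for i in range(n_genes)],
            columns=x.index,
        )
        from mirtriad.targets import TargetGroups
        groups = TargetGroups(
            canonical_only={f"t{i}" for i in range(n_genes)},
            isomir_only=set(), both=set(),
            neither={f"n{i}" for i in range(n_genes)},
        )
        out = correlate_targets(x, genes, groups)
        assert out.loc["canonical_only", "p_vs_neither"] < 0.01
        assert out.loc["canonical_only", "median_rho"] < out.loc["neither", "median_rho"]


class TestOverlap:
    def test_half_distinct(self):
        out = anticorrelated_overlap({"g2", "g3"}, {"g1", "g2"})
        assert out["percent_distinct_a"] == 50.0
        assert out["percent_distinct_b"] == 50.0

    def test_identical_and_disjoint(self):
        same = anticorrelated_overlap({"a", "b"}, {"a", "b"})
        assert same["percent_distinct_a"] == 0.0 and same["jaccard"] == 1.0
        disj = anticorrelated_overlap({"a"}, {"b"})
        assert disj["percent_distinct_a"] == 100.0 and disj["jaccard"] == 0.0

    def test_empty_set_gives_nan(self):
        assert np.isnan(anticorrelated_overlap(set(), {"a"})["percent_distinct_a"])

    def test_inclusion_exclusion_consistency(self, rng):
        a = set(rng.choice(100, 30, replace=False))
        b = set(rng.choice(100, 40, replace=False))
        out = anticorrelated_overlap(a, b)
        inter = len(a) * (1 - out["percent_distinct_a"] / 100)
        assert inter == pytest.approx(len(a & b))


class TestGsea:
    def brute_es(self, scores, gene_set, weight):
        order = scores.sort_values(ascending=False, kind="mergesort")
        hit_w = np.array([abs(order[g]) ** weight if g in gene_set else 0.0
                          for g in order.index])
        miss = np.array([0.0 if g in gene_set else 1.0 for g in order.index])
        running, best = 0.0, 0.0
        total_hit, total_miss = hit_w.sum(), miss.sum()
        for hw, ms in zip(hit_w, miss):
            running += hw / total_hit - ms / total_miss
            if abs(running) > abs(best):
                best = running
        return best

    def test_top_gene_hand_example(self):
        scores = pd.Series([0.9, 0.5, -0.4, -0.8], index=list("abcd"))
        out = gsea_preranked(scores, {"a"}, n_perm=50, seed=0)
        assert out["es"] == pytest.approx(1.0)

    def test_bottom_set_has_negative_es(self):
        scores = pd.Series(np.linspace(1, -1, 10), index=[f"g{i}" for i in range(10)])
        out = gsea_preranked(scores, {"g8", "g9"}, n_perm=50, seed=0)
        assert out["es"] < 0

    def test_matches_brute_force_running_sum(self, rng):
        for trial in range(10):
            n = int(rng.integers(8, 50))
            scores = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
            k = int(rng.integers(1, n // 2 + 1))
            gene_set = set(rng.choice(scores.index, k, replace=False))
            out = gsea_preranked(scores, gene_set, n_perm=10, seed=trial)
            assert out["es"] == pytest.approx(
                self.brute_es(scores, gene_set, 1.0), abs=1e-12
            )

    def test_es_invariant_to_monotone_rescale_at_weight_zero(self, rng):
        scores = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        gene_set = set(scores.index[:5])
        a = gsea_preranked(scores, gene_set, weight=0.0, n_perm=5, seed=0)["es"]
        b = gsea_preranked(scores * 10 + 3, gene_set, weight=0.0, n_perm=5, seed=0)["es"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_set_equal_to_universe_rejected(self):
        scores = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError):
            gsea_preranked(scores, {"a", "b"})


class TestJaccardModules:
    def test_identical_sets_merge_first(self):
        sets = {"A": {"g1", "g2"}, "B": {"g1", "g2"}, "C": {"g9"}}
        diss, Z, order = jaccard_module_cluster(sets)
        assert diss.loc["A", "B"] == 0.0
        assert diss.loc["A", "C"] == 1.0
        ab = {order.index("A"), order.index("B")}
        assert ab in ({0, 1}, {1, 2})  # A and B adjacent leaves

    def test_ninety_percent_shared_merge_before_outsider(self):
        shared = {f"g{i}" for i in range(9)}
        sets = {"A": shared | {"x"}, "B": shared | {"y"}, "C": {"z1", "z2"}}
        _, Z, order = jaccard_module_cluster(sets)
        assert abs(order.index("A") - order.index("B")) == 1

    def test_two_empty_sets_defined(self):
        diss, _, _ = jaccard_module_cluster({"A": set(), "B": set(), "C": {"g"}})
        assert diss.loc["A", "B"] == 1.0  # Jaccard defined as 0


class TestEqtlTabulation:
    def frame(self, n_unique, rel, prefix):
        return pd.DataFrame({
            "snp": [f"s{i}" for i in range(n_unique)],
            "feature": [f"{prefix}{i}" for i in range(n_unique)],
            "relationship": rel,
        })

    def test_cross_condition_unique_trans_ratios(self):
        copd = pd.concat([self.frame(6629, "trans", "gene"),
                          self.frame(221, "trans", "mir")])
        ild = pd.concat([self.frame(4249, "trans", "gene"),
                         self.frame(144, "trans", "mir")])
        ftypes = pd.Series(
            {**{f"gene{i}": "gene" for i in range(6629)},
             **{f"mir{i}": "mirna" for i in range(221)}}
        )
        summary, ratios = tabulate_eqtl_summary({"COPD": copd, "ILD": ild}, ftypes)
        key = ratios.set_index(["numerator", "denominator", "feature_type",
                                "relationship"])["unique_ratio"]
        assert key[("COPD", "ILD", "gene", "trans")] == 1.56
        assert key[("COPD", "ILD", "mirna", "trans")] == 1.53

    def test_identical_conditions_unit_ratios(self):
        rec = self.frame(10, "cis", "gene")
        ftypes = pd.Series({f"gene{i}": "gene" for i in range(10)})
        _, ratios = tabulate_eqtl_summary({"a": rec, "b": rec.copy()}, ftypes)
        vals = ratios.dropna(subset=["unique_ratio"])["unique_ratio"]
        assert (vals == 1.0).all()

    def test_unique_counts_bounded_by_pairs(self):
        rec = pd.DataFrame({"snp": ["s1", "s2"], "feature": ["g1", "g1"],
                            "relationship": ["cis", "cis"]})
        summary, _ = tabulate_eqtl_summary({"a": rec}, pd.Series({"g1": "gene"}))
        row = summary[(summary["feature_type"] == "gene")
                      & (summary["relationship"] == "cis")].iloc[0]
        assert row["n_unique_features"] == 1 <= row["n_pairs"] == 2
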