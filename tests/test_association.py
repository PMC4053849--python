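"""Feature-frequency binning, rank tests, motif scanning, correlations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from thiorate.association import (
    DEFAULT_Q10_BINS,
    bin_feature_frequency,
    compare_groups,
    intronless_halflife_split,
    iupac_regex,
    rate_feature_correlation,
    scan_promoter_motif,
)
from thiorate.core_model import GeneSetCollection, ValidationError
from thiorate.kinetics import GeneKinetics
from thiorate.thermal_response import ThermalProfile

LN2 = math.log(2.0)


def make_profile(gene_id, q10_syn, q10_dec=2.0):
    return ThermalProfile(
        gene_id=gene_id,
        q10_syn=q10_syn,
        q10_dec=q10_dec,
        fold_change=q10_syn / q10_dec,
        sig_flag=False,
        change_class="UG",
        change_class_1p5="unchanged",
    )


def make_kin(gene_id, half_life=2.0, syn_rate=100.0, temp=27.0):
    return GeneKinetics(
        gene_id=gene_id,
        temperature=temp,
        A0=100.0,
        A_end=100.0,
        P=50.0,
        N=50.0,
        half_life=half_life,
        lam=LN2 / half_life,
        syn_rate=syn_rate,
    )


class TestBinFeatureFrequency:
    def fixture_profiles(self):
        q10s = [0.5, 1.2, 1.8, 2.5, 2.9, 3.3, 4.4, 5.5, 6.6, 9.5]
        return [make_profile(f"g{i}", q) for i, q in enumerate(q10s)]

    def test_percentages_match_direct_counting(self):
        profiles = self.fixture_profiles()
        features = GeneSetCollection.from_mapping(
            {"mark": ["g1", "g2", "g3", "g6"]}
        )
        table = bin_feature_frequency(profiles, features)
        # bin [1,2): g1, g2 -> both marked; bin [2,3): g3, g4 -> one of two
        assert table.percent.loc["[1,2)", "mark"] == pytest.approx(100.0)
        assert table.percent.loc["[2,3)", "mark"] == pytest.approx(50.0)
        assert table.percent.loc["[5,6)", "mark"] == pytest.approx(0.0)
        assert table.counts["[0,1)"] == 1
        assert table.n_out_of_range == 1  # q10 = 9.5 beyond [0, 8)

    def test_saturating_feature_hits_100_everywhere(self):
        profiles = self.fixture_profiles()
        features = GeneSetCollection.from_mapping(
            {"all": [p.gene_id for p in profiles]}
        )
        table = bin_feature_frequency(profiles, features)
        nonempty = table.counts > 0
        assert (table.percent.loc[nonempty, "all"] == 100.0).all()

    def test_disjoint_feature_is_zero_everywhere(self):
        profiles = self.fixture_profiles()
        features = GeneSetCollection.from_mapping({"other": ["x1", "x2"]})
        table = bin_feature_frequency(profiles, features)
        nonempty = table.counts > 0
        assert (table.percent.loc[nonempty, "other"] == 0.0).all()

    def test_empty_bins_are_nan_not_zero(self):
        profiles = [make_profile("g1", 0.5)]
        features = GeneSetCollection.from_mapping({"m": ["g1"]})
        table = bin_feature_frequency(profiles, features)
        assert math.isnan(table.percent.loc["[5,6)", "m"])

    def test_conservation_of_gene_counts(self):
        profiles = self.fixture_profiles()
        features = GeneSetCollection.from_mapping({"m": ["g1"]})
        table = bin_feature_frequency(profiles, features)
        assert table.counts.sum() + table.n_out_of_range == len(profiles)

    def test_invariant_to_gene_order(self):
        profiles = self.fixture_profiles()
        features = GeneSetCollection.from_mapping({"m": ["g1", "g4", "g7"]})
        a = bin_feature_frequency(profiles, features)
        b = bin_feature_frequency(profiles[::-1], features)
        pd.testing.assert_frame_equal(a.percent, b.percent)

    def test_unsorted_edges_rejected(self):
        with pytest.raises(ValidationError, match="increasing"):
            bin_feature_frequency(
                self.fixture_profiles(),
                GeneSetCollection.from_mapping({"m": ["g1"]}),
                bin_edges=[0, 2, 1],
            )


def exact_mw_p(a, b):
    """Brute-force two-sided permutation p-value for the rank-sum statistic."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_of(sample_a):
        ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
        r_a = sum(ranks[v] for v in sample_a)
        return r_a - n_a * (n_a + 1) / 2

    u_obs = u_of(a)
    mean_u = len(a) * len(b) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = u_of([pooled[i] for i in combo])
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestCompareGroups:
    def test_textbook_extreme_case(self):
        # {1,2,3} vs {4,5,6}: U = 0, the most extreme of C(6,3)=20
        # arrangements, doubled for two sides
        profiles = [make_profile(f"g{i}", q) for i, q in enumerate([1, 2, 3, 4, 5, 6])]
        cmp = compare_groups(
            profiles, ["g0", "g1", "g2"], ["g3", "g4", "g5"]
        )
        assert cmp.u_statistic == 0.0
        assert cmp.p_value == pytest.approx(0.1)
        assert cmp.median_a == 2.0 and cmp.median_b == 5.0

    def test_identical_groups_not_significant(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        profiles = [make_profile(f"a{i}", v) for i, v in enumerate(vals)] + [
            make_profile(f"b{i}", v) for i, v in enumerate(vals)
        ]
        cmp = compare_groups(
            profiles, [f"a{i}" for i in range(4)], [f"b{i}" for i in range(4)]
        )
        assert cmp.p_value >= 0.99

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            a = rng.normal(0, 1, 5).round(3)
            b = rng.normal(0.5, 1, 4).round(3)
            profiles = [make_profile(f"a{i}", v) for i, v in enumerate(a)] + [
                make_profile(f"b{i}", v) for i, v in enumerate(b)
            ]
            cmp = compare_groups(
                profiles,
                [f"a{i}" for i in range(5)],
                [f"b{i}" for i in range(4)],
            )
            assert cmp.p_value == pytest.approx(exact_mw_p(a, b), abs=1e-9)

    def test_separated_cohorts_are_detected(self):
        rng = np.random.default_rng(23)
        a = rng.lognormal(math.log(2.0), 0.4, 200)
        b = rng.lognormal(math.log(4.0), 0.4, 200)
        profiles = [make_profile(f"a{i}", v) for i, v in enumerate(a)] + [
            make_profile(f"b{i}", v) for i, v in enumerate(b)
        ]
        cmp = compare_groups(
            profiles,
            [f"a{i}" for i in range(200)],
            [f"b{i}" for i in range(200)],
        )
        assert cmp.p_value < 1e-6

    def test_empty_intersection_rejected(self):
        profiles = [make_profile("g1", 2.0)]
        with pytest.raises(ValidationError, match="empty"):
            compare_groups(profiles, ["g1"], ["nope"])


class TestMotifScan:
    def test_palindrome_matches_either_strand(self):
        seqs = {"g1": "TTTTCACGTGTTTT", "g2": "AAAAAAAA"}
        fwd = scan_promoter_motif(seqs, "CACGTG", both_strands=False)
        both = scan_promoter_motif(seqs, "CACGTG", both_strands=True)
        assert fwd == both == {"g1"}

    def test_reverse_strand_hit_needs_both_strands(self):
        # evening element AAATATCT present only as reverse complement
        seqs = {"g1": "CCCCAGATATTTCCCC"}
        assert scan_promoter_motif(seqs, "AAATATCT", both_strands=False) == frozenset()
        assert scan_promoter_motif(seqs, "AAATATCT", both_strands=True) == {"g1"}

    def test_degenerate_codes_expand(self):
        seqs = {"g1": "AACGTGGCA", "g2": "AACGTGACA"}  # ABRE ACGTGKC: K = G/T
        hits = scan_promoter_motif(seqs, "ACGTGKC", both_strands=False)
        assert hits == {"g1"}

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValidationError, match="IUPAC"):
            iupac_regex("ACGTX")

    def test_invalid_sequence_rejected(self):
        with pytest.raises(ValidationError, match="non-ACGTN"):
            scan_promoter_motif({"g1": "ACGU"}, "ACGT")

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        seqs = {
            f"g{i}": "".join(rng.choice(bases, 1000)) for i in range(50)
        }
        motif = "CACGTG"
        hits = scan_promoter_motif(seqs, motif, both_strands=False)
        comp = str.maketrans("ACGT", "TGCA")
        oracle = set()
        for gene, seq in seqs.items():
            windows = [seq[i : i + 6] for i in range(len(seq) - 5)]
            if motif in windows:
                oracle.add(gene)
        assert hits == oracle

    def test_fasta_input(self, tmp_path):
        fasta = tmp_path / "promoters.fa"
        fasta.write_text(">gA\nTTCACGTGTT\n>gB\nAAAAAAAAAA\n")
        assert scan_promoter_motif(fasta, "CACGTG") == {"gA"}


def spearman_oracle(x, y):
    """Textbook rank formula (no ties): rho = 1 - 6*sum(d^2)/(n(n^2-1))."""
    rank = lambda v: {val: r for r, val in enumerate(sorted(v), start=1)}
    rx, ry = rank(x), rank(y)
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    n = len(x)
    return 1 - 6 * d2 / (n * (n**2 - 1))


class TestRateFeatureCorrelation:
    def annotation(self, n, rng=None, intron0=()):
        rng = rng or np.random.default_rng(0)
        return pd.DataFrame(
            {
                "cdna_length": rng.integers(500, 5000, n),
                "utr5_length": rng.integers(10, 500, n),
                "utr3_length": rng.integers(10, 500, n),
                "gc_content": rng.uniform(0.3, 0.6, n),
                "u_content": rng.uniform(0.1, 0.4, n),
                "intron_count": [0 if i in intron0 else 3 for i in range(n)],
            },
            index=[f"g{i}" for i in range(n)],
        )

    def test_perfect_monotone_feature(self):
        kin = [make_kin(f"g{i}", half_life=1.0 + i) for i in range(12)]
        ann = self.annotation(12)
        ann["cdna_length"] = [100 * (i + 1) for i in range(12)]  # = rank of rate
        out = rate_feature_correlation(kin, ann)
        row = out[(out.feature == "cdna_length") & (out.rate_type == "half_life")]
        assert row["spearman_rho"].iloc[0] == pytest.approx(1.0)

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(3)
        rates = rng.permutation(12) + 1.0
        lengths = rng.permutation(12) * 100.0 + 100
        kin = [make_kin(f"g{i}", half_life=rates[i]) for i in range(12)]
        ann = self.annotation(12)
        ann["cdna_length"] = lengths
        out = rate_feature_correlation(kin, ann)
        row = out[(out.feature == "cdna_length") & (out.rate_type == "half_life")]
        assert row["spearman_rho"].iloc[0] == pytest.approx(
            spearman_oracle(rates, lengths), abs=1e-12
        )

    def test_independent_feature_has_small_rho(self):
        rng = np.random.default_rng(9)
        kin = [
            make_kin(f"g{i}", half_life=float(h))
            for i, h in enumerate(rng.lognormal(1, 0.5, 1000))
        ]
        ann = self.annotation(1000, rng)
        out = rate_feature_correlation(kin, ann)
        rho = out[(out.feature == "gc_content") & (out.rate_type == "half_life")][
            "spearman_rho"
        ].iloc[0]
        assert abs(rho) < 0.1

    def test_constant_feature_reported_as_nan(self):
        kin = [make_kin(f"g{i}", half_life=1.0 + i) for i in range(12)]
        ann = self.annotation(12)
        ann["gc_content"] = 0.5
        out = rate_feature_correlation(kin, ann)
        row = out[(out.feature == "gc_content") & (out.rate_type == "half_life")]
        assert math.isnan(row["spearman_rho"].iloc[0])

    def test_too_few_genes_rejected(self):
        kin = [make_kin(f"g{i}") for i in range(5)]
        with pytest.raises(ValidationError, match=">= 10"):
            rate_feature_correlation(kin, self.annotation(5))


class TestIntronlessSplit:
    def test_all_intronless_is_degenerate(self):
        kin = [make_kin(f"g{i}") for i in range(20)]
        ann = TestRateFeatureCorrelation().annotation(20, intron0=range(20))
        with pytest.raises(ValidationError, match="degenerate"):
            intronless_halflife_split(kin, ann)

    def test_shorter_intronless_halflives_detected(self):
        rng = np.random.default_rng(13)
        n = 400
        intron0 = set(range(200))
        # intronless genes drawn at half the half-life scale
        t12 = [
            float(rng.lognormal(math.log(1.0), 0.4))
            if i in intron0
            else float(rng.lognormal(math.log(2.0), 0.4))
            for i in range(n)
        ]
        kin = [make_kin(f"g{i}", half_life=t12[i]) for i in range(n)]
        ann = TestRateFeatureCorrelation().annotation(n, intron0=intron0)
        hist, cmp = intronless_halflife_split(kin, ann)
        assert cmp.p_value < 0.001
        assert cmp.median_a < cmp.median_b  # intronless shorter
        assert hist["intronless"].sum() == 200

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(29)
        n = 400
        t12 = rng.lognormal(math.log(2.0), 0.4, n)
        kin = [make_kin(f"g{i}", half_life=float(t12[i])) for i in range(n)]
        ann = TestRateFeatureCorrelation().annotation(n, intron0=range(0, n, 2))
        _, cmp = intronless_halflife_split(kin, ann)
        assert cmp.p_value > 0.05
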