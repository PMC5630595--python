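"""Enrichment statistics against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from famvar.enrichment import (
    PositionEnrichment,
    analytic_shuffle_prior,
    bh_fdr,
    binomial_pvalue,
    codon_cg_fraction,
    enriched_positions,
    expected_count,
    gene_fraction_by_subgroup,
    identical_spectrum_pairs,
    log_odds,
    population_fraction,
    position_zscores,
    shuffle_prior,
)


class TestExpectedCount:
    def test_direct_arithmetic(self):
        assert expected_count(1000, 10000, 10, 1) == 1.0
        assert expected_count(1000, 10000, 10, 50) == 50.0

    def test_zero_length_proteome_rejected(self):
        with pytest.raises(ValueError):
            expected_count(10, 0, 1, 1)

    def test_matches_uniform_placement_oracle(self, toy_proteome):
        """Expected equals the mean column count under uniform placement."""
        rng = np.random.default_rng(42)
        total_alleles = 200
        # concatenate the proteome; residue -> column indicator for famX col 3
        offsets = {}
        cursor = 0
        for pid, seq in toy_proteome.sequences.items():
            offsets[pid] = cursor
            cursor += len(seq)
        target = np.zeros(cursor, dtype=bool)
        fa = toy_proteome.family("famX")
        for inst in fa.members:
            pos = inst.residue_of(3)
            target[offsets[inst.protein] + pos - 1] = True
        hits = [
            target[rng.integers(cursor, size=total_alleles)].sum()
            for _ in range(1000)
        ]
        expected = expected_count(total_alleles, cursor,
                                  len(fa.instances_with_column(3)), 1)
        mc = np.mean(hits)
        assert abs(mc - expected) < 4 * np.std(hits) / math.sqrt(1000)


class TestLogOdds:
    def test_examples(self):
        assert log_odds(5, 5) == 0.0
        assert log_odds(10, 5) == 1.0  # doubling = the enrichment threshold
        assert log_odds(0, 5) == -math.inf

    def test_nonpositive_expected_rejected(self):
        with pytest.raises(ValueError):
            log_odds(1, 0)

    @given(st.integers(1, 1000), st.integers(1, 1000))
    def test_strictly_increasing_in_observed(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert log_odds(lo, 7.5) < log_odds(hi, 7.5)


class TestShufflePrior:
    def test_single_column_domain_prior_is_one_over_length(self, toy_proteome):
        """A one-residue target in a length-L protein draws prior 1/L."""
        from famvar.containers import VariantRecord, VariantTable

        seqs = toy_proteome.sequences
        table = VariantTable(
            [VariantRecord("pA", 2, seqs["pA"][1], "G", "missense",
                           np.array([2, 2, 2], dtype=np.int8))],
            ["i1", "i2", "i3"],
        )
        prior = shuffle_prior(table, toy_proteome, ("famX", 3),
                              n_shuffles=20000, seed=0)
        # all 6 alleles are in pA (length 10): one mapped residue -> 1/10
        assert prior == pytest.approx(0.1, rel=0.05)
        assert analytic_shuffle_prior(table, toy_proteome,
                                      ("famX", 3)) == pytest.approx(0.1)

    def test_shuffles_converge_to_closed_form(self, toy_proteome, toy_variants):
        analytic = analytic_shuffle_prior(toy_variants, toy_proteome,
                                          ("famX", 3))
        mc = shuffle_prior(toy_variants, toy_proteome, ("famX", 3),
                           n_shuffles=10000, seed=1)
        assert mc == pytest.approx(analytic, rel=0.05)

    def test_seeded_prior_is_reproducible(self, toy_proteome, toy_variants):
        a = shuffle_prior(toy_variants, toy_proteome, "famX", 50, seed=9)
        b = shuffle_prior(toy_variants, toy_proteome, "famX", 50, seed=9)
        assert a == b


class TestBinomialPvalue:
    def test_zero_successes_gives_one(self):
        assert binomial_pvalue(0, 100, 0.3) == 1.0

    def test_closed_form_two_trials(self):
        assert binomial_pvalue(2, 2, 0.5) == pytest.approx(0.25)

    def test_matches_direct_summation(self):
        exact = sum(
            comb(10, i) * 0.1 ** i * 0.9 ** (10 - i) for i in range(5, 11)
        )
        assert binomial_pvalue(5, 10, 0.1) == pytest.approx(exact, rel=1e-12)


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_computation(self):
        # p*m/rank = [.03, .03, .03]; cumulative min leaves them equal
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_order_preserving_and_bounded(self, ps):
        q = bh_fdr(ps)
        assert q.shape == (len(ps),)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestFilters:
    def _row(self, **kw):
        import pandas as pd

        base = dict(observed_alleles=100, expected_alleles=10.0,
                    log_odds=2.0, q_value=0.001, n_genes_with_variants=15)
        base.update(kw)
        return pd.DataFrame([base])

    def test_count_floor_excludes_regardless_of_q(self):
        row = self._row(observed_alleles=49, expected_alleles=4.9,
                        q_value=1e-30)
        assert len(enriched_positions(row)) == 0

    def test_thresholds_are_inclusive(self):
        row = self._row(observed_alleles=50, log_odds=1.0, q_value=0.01)
        assert len(enriched_positions(row)) == 1

    def test_or_semantics_of_count_floor(self):
        assert len(enriched_positions(
            self._row(observed_alleles=0, expected_alleles=5.0,
                      log_odds=1.5))) == 1
        assert len(enriched_positions(
            self._row(observed_alleles=50, expected_alleles=0.1))) == 1

    def test_min_genes_filter_is_optional(self):
        row = self._row(n_genes_with_variants=3)
        assert len(enriched_positions(row)) == 0
        assert len(enriched_positions(row, min_genes=None)) == 1


class TestDescriptiveStats:
    def test_population_fraction_hand_counts(self):
        assert population_fraction(np.zeros((0, 5))) == 0.0
        block = np.array([[0, 1, 0], [0, 2, 1]])
        assert population_fraction(block) == pytest.approx(2 / 3)
        assert population_fraction(np.array([[1, 1, 2]])) == 1.0

    def test_identical_pairs_trivial_cases(self):
        assert identical_spectrum_pairs(np.zeros((0, 10))) == 45
        distinct = np.array([[0, 1, 2]])
        assert identical_spectrum_pairs(distinct) == 0

    def test_identical_pairs_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 3, size=(4, 100))
        brute = sum(
            (block[:, i] == block[:, j]).all()
            for i in range(100) for j in range(i + 1, 100)
        )
        assert identical_spectrum_pairs(block) == brute

    def test_gene_fraction_by_subgroup(self):
        groups = {"OR": {"g1", "g2", "g3"}, "nonOR": {"g4"}, "empty": set()}
        out = gene_fraction_by_subgroup({"g1", "g4"}, groups)
        assert out["OR"] == pytest.approx(1 / 3)
        assert out["nonOR"] == 1.0
        assert math.isnan(out["empty"])

    def test_position_zscores(self):
        np.testing.assert_allclose(position_zscores([4, 4, 4]), [0, 0, 0])
        z = position_zscores([0, 0, 0, 10])
        assert z[-1] == pytest.approx(7.5 / math.sqrt(18.75))
        with pytest.raises(ValueError):
            position_zscores([5])

    def test_codon_cg_fraction(self):
        coding = {"p": "CGCCGCAGA"}  # codons CGC CGC AGA
        residues = [("p", 1), ("p", 2)]
        assert codon_cg_fraction(residues, coding) == 100.0
        assert codon_cg_fraction([("p", 3)], coding) == 0.0
        coding = {"q": "CGAAGGCGGAGA"}
        assert codon_cg_fraction(
            [("q", i) for i in range(1, 5)], coding) == 50.0


class TestModelAgainstBruteForce:
    def test_counts_and_log_odds_match_enumeration(self, toy_proteome,
                                                   toy_variants):
        """Explicit allele placement reproduces the fitted table exactly."""
        results = PositionEnrichment(toy_variants, toy_proteome).fit(
            n_shuffles=50, seed=0
        )
        # brute force: place every missense allele explicitly
        idx = toy_proteome.instances_by_protein()
        observed = {}
        total = 0
        for v in toy_variants.missense():
            total += v.pooled_count
            for inst in idx.get(v.protein, []):
                col = inst.column_of(v.position)
                if col is not None:
                    key = (inst.family, col)
                    observed[key] = observed.get(key, 0) + v.pooled_count
        length = toy_proteome.total_length
        for _, row in results.table.iterrows():
            key = (row["family"], row["column"])
            obs = observed.get(key, 0)
            assert row["observed_alleles"] == obs
            exp = total / length * row["n_instances"]
            assert row["expected_alleles"] == pytest.approx(exp, abs=1e-12)
            if obs > 0:
                assert row["log_odds"] == pytest.approx(
                    math.log2(obs / exp), abs=1e-12)

    def test_family_counts_conserved(self, toy_proteome, toy_variants):
        """Sum of column counts equals the family's total mapped alleles."""
        results = PositionEnrichment(toy_variants, toy_proteome).fit(
            n_shuffles=10, seed=0
        )
        per_family = results.table.groupby("family")["observed_alleles"].sum()
        fam = results.family_table.set_index("family")["observed_alleles"]
        for name in per_family.index:
            assert per_family[name] == fam[name]

    def test_stop_gain_variants_excluded_from_counting(self, toy_proteome,
                                                       toy_variants):
        results = PositionEnrichment(toy_variants, toy_proteome).fit(
            n_shuffles=10, seed=0
        )
        # pB:9 is a stop gain outside counting; famX column 7 does not exist,
        # and no stop allele contributes anywhere
        missense_total = sum(v.pooled_count
                             for v in toy_variants.missense())
        assert results.total_alleles == missense_total
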