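"""Column mapping, consensus calling and variant-table I/O."""

import numpy as np
import pytest

from famvar import io as fio
from famvar.containers import (
    DomainInstance,
    FamilyAlignment,
    VariantRecord,
    VariantTable,
)
from famvar.mapping import (
    CANONICAL,
    NON_CANONICAL,
    UNKNOWN,
    canonical_check,
    canonical_status_table,
    compute_consensus,
    map_variant_to_column,
    motif_string,
)


def _variant(protein, pos, ref="A", alt="V", counts=(1,)):
    return VariantRecord(protein, pos, ref, alt, "missense",
                         np.array(counts, dtype=np.int8))


class TestMapping:
    def test_identity_mapping(self):
        inst = DomainInstance("f", "p", 1, 10, {i: i for i in range(1, 11)})
        hits = map_variant_to_column(_variant("p", 5), {"p": [inst]})
        assert hits == [("f", 5)]

    def test_insertion_residue_maps_nowhere(self):
        # residue 5 is an insertion: inside the domain but unmapped
        cmap = {3: 1, 4: 2, 6: 3, 7: 4}
        inst = DomainInstance("f", "p", 3, 7, cmap)
        assert map_variant_to_column(_variant("p", 5), {"p": [inst]}) == []
        assert map_variant_to_column(_variant("p", 6), {"p": [inst]}) == [("f", 3)]

    def test_two_instances_of_same_family_give_two_hits(self):
        # overlapping instances: one hit per instance for a shared residue
        a = DomainInstance("f", "p", 1, 5, {i: i for i in range(1, 6)})
        b = DomainInstance("f", "p", 3, 7, {i: i - 2 for i in range(3, 8)})
        hits = map_variant_to_column(_variant("p", 4), {"p": [a, b]})
        assert hits == [("f", 4), ("f", 2)]
        # disjoint tandem instances each map their own residues
        c = DomainInstance("f", "q", 11, 15,
                           {i: i - 10 for i in range(11, 16)})
        assert map_variant_to_column(_variant("q", 13), {"q": [c]}) == [("f", 3)]

    def test_unknown_protein_is_no_hit(self):
        assert map_variant_to_column(_variant("q", 3), {}) == []

    def test_mapping_is_injective_per_instance(self, small_study):
        _, proteome, _ = small_study
        for fa in proteome.families:
            for inst in fa.members:
                cols = list(inst.column_map.values())
                assert len(cols) == len(set(cols))

    def test_planted_coordinates_recovered_exactly(self, small_study):
        """Generator column maps invert map_variant_to_column for non-insertions."""
        _, proteome, variants = small_study
        idx = proteome.instances_by_protein()
        checked = 0
        for v in variants:
            for inst in idx.get(v.protein, []):
                col = inst.column_of(v.position)
                if col is not None:
                    assert (inst.family, col) in map_variant_to_column(v, idx)
                    checked += 1
        assert checked > 0


def _family_of_rows(rows, start=1):
    """Build a family from equal-length residue strings (no gaps)."""
    length = len(rows[0])
    members = []
    seqs = {}
    for i, row in enumerate(rows):
        pid = f"m{i}"
        seqs[pid] = row
        members.append(DomainInstance(
            "fam", pid, start, start + length - 1,
            {start + j: j + 1 for j in range(length)}))
    return FamilyAlignment("fam", length, members), seqs


class TestConsensus:
    def test_unanimous_column_is_conserved(self):
        fa, seqs = _family_of_rows(["R"] * 10)
        cons = compute_consensus(fa, seqs, threshold=0.5)
        assert cons.loc[1, "residue"] == "R"
        assert cons.loc[1, "conserved"]
        assert cons.loc[1, "frequency"] == 1.0

    def test_tie_breaks_alphabetically_and_threshold_is_inclusive(self):
        fa, seqs = _family_of_rows(["R"] * 5 + ["K"] * 5)
        cons = compute_consensus(fa, seqs, threshold=0.5)
        assert cons.loc[1, "residue"] == "K"  # alphabetical among ties
        assert cons.loc[1, "conserved"]       # 0.5 >= 0.5
        cons6 = compute_consensus(fa, seqs, threshold=0.6)
        assert not cons6.loc[1, "conserved"]

    def test_motif_casing_marks_conservation(self):
        # D conserved, R conserved, Y not: the "DRy" rendering
        rows = ["DRY"] * 6 + ["DRF", "DRW", "DRC", "DRH"]
        fa, seqs = _family_of_rows(rows)
        cons = compute_consensus(fa, seqs, threshold=0.9)
        assert motif_string(cons, [1, 2, 3]) == "DRy"

    def test_consensus_is_member_order_invariant(self):
        rows = ["ARN", "AKN", "GRN", "ARQ", "ARN"]
        fa1, s1 = _family_of_rows(rows)
        fa2, s2 = _family_of_rows(rows[::-1])
        c1 = compute_consensus(fa1, s1)
        c2 = compute_consensus(fa2, s2)
        assert (c1["residue"] == c2["residue"]).all()
        assert (c1["frequency"] == c2["frequency"]).all()

    def test_empty_column_is_undefined(self):
        fa, seqs = _family_of_rows(["AB"])
        fa.members[0].column_map.pop(2)
        cons = compute_consensus(fa, seqs)
        assert cons.loc[2, "residue"] is None
        assert not cons.loc[2, "conserved"]


class TestCanonicalCheck:
    def test_canonical_and_noncanonical_calls(self):
        fa, seqs = _family_of_rows(["R"] * 9 + ["C"])
        assert canonical_check("m0", fa, seqs, [1])[1] == CANONICAL
        assert canonical_check("m9", fa, seqs, [1])[1] == NON_CANONICAL

    def test_unmapped_column_is_unknown(self):
        fa, seqs = _family_of_rows(["RK", "RK", "RK"])
        fa.members[0].column_map.pop(2)
        assert canonical_check("m0", fa, seqs, [2])[2] == UNKNOWN

    def test_planted_noncanonical_receptors_recovered_exactly(self):
        """24 members built with a non-consensus residue are all recovered."""
        rows = ["R" * 3] * 76 + ["RCR"] * 24
        fa, seqs = _family_of_rows(rows)
        status = canonical_status_table(fa, seqs, [2])
        noncanon = status[status[2] == NON_CANONICAL].index
        assert sorted(noncanon) == sorted(f"m{i}" for i in range(76, 100))


class TestVariantIO:
    def _table(self):
        records = [
            VariantRecord("pX", 5, "R", "C", "missense",
                          np.array([0, 1, 2], dtype=np.int8)),
            VariantRecord("pX", 9, "K", "*", "stop_gain",
                          np.array([0, 0, 1], dtype=np.int8)),
            VariantRecord("pY", 2, "L", "fs", "frameshift",
                          np.array([1, 0, 0], dtype=np.int8)),
        ]
        return VariantTable(records, ["a", "b", "c"])

    @pytest.mark.parametrize("fmt", ["vcf", "tsv"])
    def test_round_trip(self, tmp_path, fmt):
        table = self._table()
        path = tmp_path / f"v.{fmt}"
        if fmt == "vcf":
            fio.write_vcf(table, path)
        else:
            fio.write_variants_tsv(table, path)
        back = fio.read_variants(path, fmt)
        assert back.individuals == table.individuals
        for v, w in zip(table.variants, back.variants):
            assert v.key == w.key
            assert v.consequence == w.consequence
            assert (v.allele_counts == w.allele_counts).all()

    def test_empty_vcf_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.vcf"
        fio.write_vcf(VariantTable([], ["a", "b"]), path)
        back = fio.read_vcf(path)
        assert len(back) == 0
        assert back.individuals == ["a", "b"]

    def test_unknown_consequence_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        fio.write_vcf(self._table(), path)
        text = path.read_text().replace("CSQ=stop_gain", "CSQ=sstop")
        path.write_text(text)
        with pytest.raises(fio.ParseError, match="consequence"):
            fio.read_vcf(path)

    def test_nondiploid_genotype_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.vcf"
        fio.write_vcf(self._table(), path)
        text = path.read_text().replace("0|1", "1")
        path.write_text(text)
        with pytest.raises(fio.ParseError, match="GT"):
            fio.read_vcf(path)


class TestAlignmentIO:
    def test_round_trip_preserves_column_maps(self, tmp_path, small_study):
        _, proteome, _ = small_study
        fa = proteome.families[0]
        path = tmp_path / "fam.afa"
        fio.write_alignment_fasta(fa, proteome.sequences, path)
        back = fio.read_alignment_fasta(path, fa.family)
        assert back.model_length == fa.model_length
        orig = {m.protein: m for m in fa.members}
        for m in back.members:
            assert m.column_map == orig[m.protein].column_map
            assert (m.start, m.end) == (orig[m.protein].start,
                                        orig[m.protein].end)

    def test_stockholm_parsing(self, tmp_path):
        text = (
            "# STOCKHOLM 1.0\n"
            "p1/3-7    ARN-E\n"
            "p2/1-5    ARnD-\n"
            "//\n"
        )
        path = tmp_path / "fam.sto"
        path.write_text(text)
        fa = fio.read_alignment_stockholm(path, "fam")
        assert fa.model_length == 5
        p1 = next(m for m in fa.members if m.protein == "p1")
        # column 4 is deleted in p1: residue 6 skips to column 5
        assert p1.column_map == {3: 1, 4: 2, 5: 3, 6: 5}
        p2 = next(m for m in fa.members if m.protein == "p2")
        # lowercase n is an insertion residue: consumes sequence, no column
        assert p2.column_map == {1: 1, 2: 2, 4: 3}
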