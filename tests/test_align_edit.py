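"""Alignment editing: cleaning, renaming, masking, extraction,
concatenation, translation, codon alignment, bootstrapping."""

import numpy as np
import pytest

from phylokit.alignio import Alignment, SequenceSet
from phylokit.align_edit import (
    GENETIC_CODES,
    RenameMap,
    clean_seqs,
    clean_sites,
    codon_align,
    concat,
    extract,
    mask,
    rename_seqs,
    sanitize_names,
    seqboot,
    translate,
)
from phylokit.fixtures import random_alignment
from phylokit.tree import PhyloError


class TestClean:
    def test_strict_gap_cutoff_on_sites(self):
        aln = Alignment([("s1", "A-A"), ("s2", "AA-"), ("s3", "A-A")])
        out, removed = clean_sites(aln, 0.5)
        assert removed == 1  # column 2 at 2/3 gaps; column 3 at 1/3 kept
        assert [s for _, s in out] == ["AA", "A-", "AA"]

    def test_cutoff_one_keeps_everything(self):
        aln = Alignment([("s1", "A-"), ("s2", "--")])
        out, removed = clean_sites(aln, 1.0)
        assert removed == 0 and out.length == 2

    def test_no_gaps_identity(self):
        aln = random_alignment(5, 30, seed=3)
        out, removed = clean_sites(aln, 0.0)
        assert removed == 0 and out == aln

    def test_clean_seqs(self):
        aln = Alignment([("s1", "----"), ("s2", "ACGT")])
        out, removed = clean_seqs(aln, 0.5)
        assert removed == 1 and out.names == ["s2"]

    def test_clean_seqs_cutoff_zero_drops_any_gapped(self):
        aln = Alignment([("s1", "AC-T"), ("s2", "ACGT")])
        out, _ = clean_seqs(aln, 0.0)
        assert out.names == ["s2"]

    def test_bad_cutoff(self):
        with pytest.raises(PhyloError):
            clean_sites(random_alignment(2, 4, seed=1), 1.5)

    def test_order_preserved(self):
        aln = Alignment([("s1", "A-C-G"), ("s2", "AAC-G")])
        out, _ = clean_sites(aln, 0.4)
        assert out.sequence("s1") == "ACG"  # kept columns in original order


class TestRename:
    def test_substitution(self):
        aln = Alignment([("A", "AC"), ("B", "GT")])
        out = rename_seqs(aln, RenameMap([("A", "X")]))
        assert out.names == ["X", "B"]

    def test_collision_rejected(self):
        aln = Alignment([("A", "AC"), ("B", "GT")])
        with pytest.raises(PhyloError):
            rename_seqs(aln, RenameMap([("A", "B")]))

    def test_missing_entry_errors_unless_allowed(self):
        aln = Alignment([("A", "AC"), ("B", "GT")])
        with pytest.raises(PhyloError):
            rename_seqs(aln, RenameMap([("C", "Y")]))
        out = rename_seqs(aln, RenameMap([("C", "Y")]), allow_missing=True)
        assert out.names == ["A", "B"]

    def test_map_text_round_trip(self):
        rmap = RenameMap([("old name", "new_name"), ("x", "y")])
        assert RenameMap.from_text(rmap.to_text()).pairs == rmap.pairs

    def test_sanitize(self):
        aln = Alignment([("Homo sapiens", "AC"), ("a b", "GT"), ("a_b", "CC")])
        out, rmap = sanitize_names(aln)
        assert out.names == ["Homo_sapiens", "a_b", "a_b_2"]
        # the returned map reverses the rename
        back = rename_seqs(out, rmap.inverted())
        assert back.names == aln.names

    def test_sanitize_clean_names_identity(self):
        aln = Alignment([("ok.name-1", "AC")])
        out, rmap = sanitize_names(aln)
        assert out.names == aln.names
        assert rmap.mapping == {"ok.name-1": "ok.name-1"}


class TestMaskExtract:
    def test_mask_window(self):
        aln = Alignment([("s1", "ACGT")])
        assert mask(aln, 1, 2).sequence("s1") == "ANNT"

    def test_mask_preserves_gaps(self):
        aln = Alignment([("s1", "A-GT"), ("s2", "ACGT")])
        assert mask(aln, 1, 2).sequence("s1") == "A-NT"

    def test_mask_protein_fill_and_empty_window(self):
        aln = Alignment([("s1", "MKLW")], "amino-acid")
        assert mask(aln, 0, 2).sequence("s1") == "XXLW"
        assert mask(aln, 1, 0) == aln

    def test_mask_out_of_range(self):
        with pytest.raises(PhyloError):
            mask(Alignment([("s1", "ACGT")]), 2, 5)

    def test_extract_blocks(self):
        aln = Alignment([("s1", "ACGTAC")])
        assert extract(aln, [(0, 2), (4, 6)]).sequence("s1") == "ACAC"

    def test_extract_full_range_identity(self):
        aln = random_alignment(3, 12, seed=5)
        assert extract(aln, [(0, 12)]) == aln

    @pytest.mark.parametrize("ranges", [[], [(0, 2), (1, 3)], [(2, 1)], [(0, 99)]])
    def test_extract_bad_ranges(self, ranges):
        with pytest.raises(PhyloError):
            extract(Alignment([("s1", "ACGTAC")]), ranges)


class TestConcat:
    def test_lengths_add(self):
        a = Alignment([("x", "ACG"), ("y", "TTT")])
        b = Alignment([("x", "AAAA"), ("y", "CCCC")])
        assert concat([a, b]).length == 7

    def test_fill_missing(self):
        a = Alignment([("x", "ACG"), ("y", "TTT")])
        b = Alignment([("x", "AAAA")])
        out = concat([a, b], fill_missing=True)
        assert out.sequence("y") == "TTT----"
        with pytest.raises(PhyloError):
            concat([a, b], fill_missing=False)

    def test_associative(self):
        blocks = [random_alignment(3, 5, seed=s) for s in (1, 2, 3)]
        left = concat([concat(blocks[:2]), blocks[2]])
        right = concat([blocks[0], concat(blocks[1:])])
        assert left == right


class TestTranslate:
    def test_standard_code(self):
        aln = SequenceSet([("s1", "ATGAAA")])
        out, dropped = translate(aln)
        assert out.sequence("s1") == "MK" and dropped == 0

    def test_gap_codon_and_partial_gap(self):
        out, _ = translate(SequenceSet([("s1", "ATG---AAA"), ("s2", "ATGA--AAA")]))
        assert out.sequence("s1") == "M-K"
        assert out.sequence("s2") == "MXK"

    def test_trailing_remainder_dropped(self):
        out, dropped = translate(SequenceSet([("s1", "ATGA")]))
        assert out.sequence("s1") == "M" and dropped == 1

    def test_phase_and_stop(self):
        out, _ = translate(SequenceSet([("s1", "CATGTAA")]), phase=1)
        assert out.sequence("s1") == "M*"

    def test_vertebrate_mito_differs(self):
        # AGA: Arg in the standard code, stop in vertebrate mito
        std, _ = translate(SequenceSet([("s", "AGA")]))
        mito, _ = translate(SequenceSet([("s", "AGA")]), code=GENETIC_CODES["vertebrate-mito"])
        assert (std.sequence("s"), mito.sequence("s")) == ("R", "*")

    def test_amino_acid_input_rejected(self):
        with pytest.raises(PhyloError):
            translate(Alignment([("s1", "MKLW")], "amino-acid"))


class TestCodonAlign:
    def test_gap_expansion(self):
        prot = Alignment([("s1", "M-K"), ("s2", "MLK")], "amino-acid")
        cds = SequenceSet([("s1", "ATGAAA"), ("s2", "ATGCTGAAA")])
        out = codon_align(prot, cds)
        assert out.sequence("s1") == "ATG---AAA"
        assert out.sequence("s2") == "ATGCTGAAA"
        assert out.length == 3 * prot.length

    def test_translation_mismatch_reports_position(self):
        prot = Alignment([("s1", "MK")], "amino-acid")
        cds = SequenceSet([("s1", "ATGCAA")])  # codes MQ
        with pytest.raises(PhyloError, match="residue 2"):
            codon_align(prot, cds)

    def test_name_mismatch(self):
        prot = Alignment([("s1", "MK")], "amino-acid")
        with pytest.raises(PhyloError):
            codon_align(prot, SequenceSet([("s2", "ATGAAA")]))

    def test_trailing_stop_tolerated(self):
        prot = Alignment([("s1", "MK")], "amino-acid")
        out = codon_align(prot, SequenceSet([("s1", "ATGAAATAA")]))
        assert out.sequence("s1") == "ATGAAA"

    def test_translate_inverts_codon_align(self):
        rng = np.random.default_rng(8)
        codons = [c for c in GENETIC_CODES["standard"].table if
                  GENETIC_CODES["standard"].table[c] != "*"]
        for rep in range(20):
            n_res = int(rng.integers(3, 15))
            rows = []
            cds_rows = []
            for s in range(3):
                picked = rng.choice(len(codons), size=n_res)
                aas = []
                nts = []
                for k in picked:
                    aas.append(GENETIC_CODES["standard"].table[codons[k]])
                    nts.append(codons[k])
                # sprinkle gaps into the protein alignment
                gaps = rng.random(n_res) < 0.2
                prot_row = "".join(
                    "-" if g else a for g, a in zip(gaps, aas)
                )
                cds_row = "".join(
                    nt for g, nt in zip(gaps, nts) if not g
                )
                rows.append((f"s{s}", prot_row))
                cds_rows.append((f"s{s}", cds_row))
            prot = Alignment(rows, "amino-acid")
            out = codon_align(prot, SequenceSet(cds_rows))
            back, _ = translate(out)
            assert back == prot


class TestSeqboot:
    def test_shape_and_names(self):
        aln = random_alignment(4, 50, seed=2)
        reps = seqboot(aln, 5, seed=9)
        assert len(reps) == 5
        for rep in reps:
            assert rep.names == aln.names and rep.length == aln.length

    def test_columns_come_from_original(self):
        aln = random_alignment(4, 20, seed=2)
        originals = {aln.column(i) for i in range(aln.length)}
        for rep in seqboot(aln, 3, seed=1):
            for i in range(rep.length):
                assert rep.column(i) in originals

    def test_deterministic_under_seed(self):
        aln = random_alignment(3, 30, seed=4)
        assert seqboot(aln, 4, seed=7) == seqboot(aln, 4, seed=7)
        assert seqboot(aln, 4, seed=7) != seqboot(aln, 4, seed=8)

    def test_replicates_independent_of_generation_order(self):
        aln = random_alignment(3, 30, seed=4)
        assert seqboot(aln, 5, seed=7)[4] == seqboot(aln, 9, seed=7)[4]

    def test_two_column_resampling_frequency(self):
        # both-columns-equal-column-1 has probability 1/4
        aln = Alignment([("s1", "AC"), ("s2", "AC")])
        target = aln.column(0) + aln.column(0)
        hits = 0
        for rep in seqboot(aln, 1000, seed=13):
            if rep.column(0) + rep.column(1) == target:
                hits += 1
        assert abs(hits / 1000 - 0.25) <= 0.05

    def test_bad_replicate_count(self):
        with pytest.raises(PhyloError):
            seqboot(random_alignment(2, 5, seed=0), 0, seed=1)
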