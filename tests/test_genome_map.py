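"""Coordinate annotation and substitution-effect classification."""

import itertools

import pytest
from Bio.Seq import Seq

from mthet.errors import CoordinateError, ReferenceMismatchError, ValidationError
from mthet.genome_map import (
    COMPLEMENT,
    RCRS_LENGTH,
    GenomeMap,
    classify_substitution,
    locate_position,
    structural_context,
    translate_mito,
)


class TestLocatePosition:
    @pytest.mark.parametrize(
        "pos, region, feature, ftype, complex_",
        [
            (16189, "HVRI", None, None, None),
            (152, "HVRII", None, None, None),
            (310, "HVRII", None, None, None),
            (520, "HVRIII", None, None, None),
            (16500, "D-loop", None, None, None),  # control region outside HVRs
            (15908, "coding", "tRNA-Thr", "tRNA", None),
            (7754, "coding", "MT-CO2", "protein", "IV"),
            (3014, "coding", "16S rRNA", "rRNA", None),
            (1552, "coding", "12S rRNA", "rRNA", None),
            (8280, "intergenic", None, None, None),  # between MT-CO2 and tRNA-Lys
        ],
    )
    def test_examples(self, gmap, pos, region, feature, ftype, complex_):
        ann = locate_position(pos, gmap)
        assert ann.region == region
        if feature is not None:
            assert feature in ann.features
        assert ann.ftype == ftype
        assert ann.complex == complex_

    @pytest.mark.parametrize("pos", [0, -3, RCRS_LENGTH + 1])
    def test_out_of_range(self, gmap, pos):
        with pytest.raises(CoordinateError):
            locate_position(pos, gmap)

    def test_region_tiling(self, gmap):
        """Every position gets exactly one region label; labels tile the genome."""
        counts = {}
        for pos in range(1, gmap.length + 1):
            counts[locate_position(pos, gmap).region] = (
                counts.get(locate_position(pos, gmap).region, 0) + 1
            )
        assert sum(counts.values()) == RCRS_LENGTH
        # HVR bounds and the origin-spanning control region
        assert counts["HVRI"] == 16383 - 16024 + 1
        assert counts["HVRII"] == 372 - 57 + 1
        assert counts["HVRIII"] == 576 - 438 + 1
        assert set(counts) == {
            "HVRI", "HVRII", "HVRIII", "D-loop", "coding", "intergenic"
        }

    def test_overlapping_genes_all_reported(self, gmap):
        ann = locate_position(8530, gmap)  # ATP8/ATP6 overlap
        assert set(ann.features) >= {"MT-ATP8", "MT-ATP6"}
        # priority = feature-file order
        assert ann.features[0] == "MT-ATP8"


class TestTranslateMito:
    @pytest.mark.parametrize(
        "codon, aa", [("ATA", "Met"), ("TGA", "Trp"), ("AGA", "STOP"),
                      ("AGG", "STOP"), ("TAA", "STOP"), ("ATG", "Met"),
                      ("GAC", "Asp"), ("AAC", "Asn")],
    )
    def test_vertebrate_mito_code(self, codon, aa):
        assert translate_mito(codon) == aa

    def test_light_strand_codon_is_reverse_complemented(self):
        # GTC on the heavy strand is GAC (Asp) read on the light strand
        assert translate_mito("GTC", strand="L") == "Asp"

    @pytest.mark.parametrize("codon", ["AT", "ATAA", "ANX", "AUG"])
    def test_invalid_codons(self, codon):
        with pytest.raises(ValidationError):
            translate_mito(codon)


def _oracle_effect(gene, pos, alt_heavy, reference):
    """Independent re-translation oracle: rebuild the whole CDS, mutate the
    position, translate with Biopython (table 2) and diff the one codon."""
    pad = (3 - gene.length % 3) % 3
    seq = list(reference[gene.start - 1 : gene.end])
    mutated = list(seq)
    mutated[pos - gene.start] = alt_heavy

    def cds(s):
        s = "".join(s)
        if gene.strand == "L":
            s = str(Seq(s).reverse_complement())
        return s + "A" * pad

    ref_aa = str(Seq(cds(seq)).translate(table=2))
    alt_aa = str(Seq(cds(mutated)).translate(table=2))
    diffs = [i for i, (a, b) in enumerate(zip(ref_aa, alt_aa)) if a != b]
    if not diffs:
        return "synonymous", None
    (i,) = diffs
    if alt_aa[i] == "*":
        return "stop-gain", i + 1
    if ref_aa[i] == "*":
        return "stop-loss", i + 1
    return "non-synonymous", i + 1


class TestClassifySubstitution:
    def test_asp_to_asn_at_7754(self, gmap, reference):
        s = classify_substitution(7754, "G", "A", gmap, reference)
        assert (s.change_kind, s.base_class) == ("transition", "purine")
        e = s.coding_effect
        assert (e.gene, e.codon_index) == ("MT-CO2", 57)
        assert (e.aa_ref, e.aa_alt, e.effect) == ("Asp", "Asn", "non-synonymous")
        assert e.polarity_change == "acidic->neutral"

    def test_ile_to_thr_at_11253(self, gmap, reference):
        s = classify_substitution(11253, "T", "C", gmap, reference)
        assert (s.change_kind, s.base_class) == ("transition", "pyrimidine")
        e = s.coding_effect
        assert e.gene == "MT-ND4"
        assert (e.aa_ref, e.aa_alt, e.effect) == ("Ile", "Thr", "non-synonymous")

    def test_control_region_has_no_coding_effect(self, gmap, reference):
        s = classify_substitution(152, "T", "C", gmap, reference)
        assert s.coding_effect is None
        assert s.change_kind == "transition"

    def test_identical_alleles_rejected(self, gmap, reference):
        with pytest.raises(ValidationError):
            classify_substitution(7754, "G", "G", gmap, reference)

    def test_reference_mismatch_rejected(self, gmap, reference):
        # reference holds G at 7754; neither allele matches
        with pytest.raises(ReferenceMismatchError):
            classify_substitution(7754, "C", "T", gmap, reference)

    def test_transition_transversion_partition(self, gmap, reference):
        kinds = {}
        for a, b in itertools.permutations("ACGT", 2):
            ref = reference[151]  # position 152
            seq = reference[:151] + a + reference[152:]
            s = classify_substitution(152, a, b, gmap, seq)
            kinds[(a, b)] = s.change_kind
        assert sum(1 for k in kinds.values() if k == "transition") == 4
        assert sum(1 for k in kinds.values() if k == "transversion") == 8

    @pytest.mark.parametrize("gene_name", ["MT-CO2", "MT-ND3", "MT-ND6"])
    def test_exhaustive_retranslation_oracle(self, gmap, reference, gene_name):
        """Every substitution in the gene matches the CDS re-translation oracle
        (covers heavy and light strands and incomplete stop codons)."""
        gene = gmap.feature(gene_name)
        for pos in range(gene.start, gene.end + 1):
            ref_base = reference[pos - 1]
            for alt in "ACGT":
                if alt == ref_base:
                    continue
                s = classify_substitution(pos, ref_base, alt, gmap, reference)
                effect, codon_i = _oracle_effect(gene, pos, alt, reference)
                e = s.coding_effect
                assert e.gene == gene_name
                assert e.effect == effect, (pos, ref_base, alt)
                if codon_i is not None:
                    assert e.codon_index == codon_i

    def test_light_strand_equals_complemented_alleles(self, gmap, reference):
        """For MT-ND6 the heavy-strand alleles must be classified on the
        complemented light-strand codon."""
        gene = gmap.feature("MT-ND6")
        pos = gene.start + 31
        ref_base = reference[pos - 1]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
        s = classify_substitution(pos, ref_base, alt, gmap, reference)
        e = s.coding_effect
        assert COMPLEMENT[ref_base] in e.codon_ref
        assert translate_mito(e.codon_ref) == e.aa_ref

    def test_incomplete_stop_completed_with_poly_a(self, gmap, reference):
        """The last, incomplete codon of MT-CYB is classified against the
        polyadenylation-completed TAA codon."""
        s = classify_substitution(
            15887, reference[15886], COMPLEMENT[reference[15886]], gmap, reference
        )
        e = s.coding_effect
        assert e.codon_ref == reference[15886] + "AA"
        assert e.codon_ref == "TAA"  # generator ends the gene in its partial stop
        assert e.aa_ref == "STOP"
        assert e.effect == "stop-loss"


class TestStructuralContext:
    @pytest.mark.parametrize(
        "pos, table, expected",
        [
            (1552, {1552: "stem"}, "stem"),
            (2887, {2887: "loop"}, "loop"),
            (5000, {}, "unknown"),
        ],
    )
    def test_lookup(self, pos, table, expected):
        assert structural_context(pos, table) == expected

    def test_bad_table_value(self):
        with pytest.raises(ValidationError):
            structural_context(1, {1: "bulge"})


class TestGenomeMapIO:
    def test_tsv_round_trip(self, gmap, tmp_path):
        p = tmp_path / "features.tsv"
        gmap.to_tsv(p)
        again = GenomeMap.from_tsv(p)
        assert again.features == gmap.features

    def test_json_round_trip(self, gmap, tmp_path):
        p = tmp_path / "features.json"
        gmap.to_json(p)
        again = GenomeMap.from_json(p)
        assert again.features == gmap.features

    def test_protein_lengths_whole_codons(self, gmap):
        for f in gmap.features:
            if f.ftype == "protein":
                assert (f.length + (3 - f.incomplete_stop) % 3) % 3 == 0
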