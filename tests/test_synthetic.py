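"""Seed contracts, planted ground truth and parameter recovery."""

import json

import numpy as np
import pytest
from Bio.Seq import Seq

from mthet.errors import ValidationError
from mthet.heteroplasmy import detect_mixed_base, estimate_level
from mthet.stability import conservation_index
from mthet.synthetic import (
    AlignmentSimSpec,
    CohortSimSpec,
    simulate_alignment,
    simulate_cohort,
    simulate_hit_table,
    simulate_peaks,
    simulate_reference,
)


class TestSimulateReference:
    def test_anchored_positions(self, gmap):
        ref = simulate_reference(gmap, seed=1)
        assert len(ref) == gmap.length
        assert ref[152 - 1] == "T"
        assert ref[16189 - 1] == "T"
        assert ref[7754 - 1 : 7754 + 2] == "GAC"  # COXII codon 57 (Asp)
        assert ref[11252 - 1 : 11252 + 2] == "ATC"  # ND4 codon 165 (Ile)

    @pytest.mark.parametrize("gene_name", ["MT-CO2", "MT-ND6"])
    def test_protein_genes_are_open_reading_frames(self, gmap, gene_name):
        ref = simulate_reference(gmap, seed=2)
        g = gmap.feature(gene_name)
        cds = ref[g.start - 1 : g.end]
        if g.strand == "L":
            cds = str(Seq(cds).reverse_complement())
        cds += "A" * ((3 - g.incomplete_stop) % 3 if g.incomplete_stop else 0)
        aa = str(Seq(cds).translate(table=2))
        assert aa[0] == "M"
        assert aa[-1] == "*"
        assert "*" not in aa[:-1]

    def test_seed_contract(self, gmap):
        assert simulate_reference(gmap, seed=3) == simulate_reference(gmap, seed=3)
        assert simulate_reference(gmap, seed=3) != simulate_reference(gmap, seed=4)


class TestSimulateCohort:
    def test_zero_rates_yield_homoplasmic_cohort(self, gmap, reference):
        spec = CohortSimSpec(n_individuals=20, p_point_carrier=0.0,
                             p_length_carrier=0.0, seed=0)
        records, truth = simulate_cohort(spec, gmap, reference)
        assert len(records) == 20
        assert all(not r.point_calls and not r.length_calls for r in records)
        assert truth["events"] == []

    def test_reproducible_and_seed_sensitive(self, gmap, reference):
        spec = CohortSimSpec(seed=42)
        r1, t1 = simulate_cohort(spec, gmap, reference)
        r2, t2 = simulate_cohort(CohortSimSpec(seed=42), gmap, reference)
        r3, _ = simulate_cohort(CohortSimSpec(seed=43), gmap, reference)
        assert json.dumps(t1, sort_keys=True) == json.dumps(t2, sort_keys=True)
        assert [r.individual_id for r in r1] == [r.individual_id for r in r2]
        assert _strip(r1) == _strip(r2)
        assert _strip(r1) != _strip(r3)

    def test_carrier_fraction_within_binomial_interval(self, gmap, reference):
        """The heteroplasmic-carrier fraction lands inside the 95% binomial
        interval implied by the planted carrier rates."""
        spec = CohortSimSpec(seed=9)
        records, _ = simulate_cohort(spec, gmap, reference)
        p_any = 1 - (1 - spec.p_point_carrier) * (1 - spec.p_length_carrier)
        carriers = sum(1 for r in records if r.point_calls or r.length_calls)
        n = spec.n_individuals
        half = 1.96 * np.sqrt(p_any * (1 - p_any) / n)
        assert p_any - half <= carriers / n <= p_any + half

    def test_transition_bias_recovered(self, gmap, reference):
        spec = CohortSimSpec(n_individuals=1000, p_point_carrier=1.0,
                             mean_point_events=1.0, p_length_carrier=0.0, seed=17)
        records, truth = simulate_cohort(spec, gmap, reference)
        events = truth["events"]
        assert len(events) >= 1000
        p_ts = sum(e["change_kind"] == "transition" for e in events) / len(events)
        expected = 15.5 / 16.5
        sd = np.sqrt(expected * (1 - expected) / len(events))
        assert abs(p_ts - expected) <= 3 * sd

    def test_truth_matches_records(self, gmap, reference):
        records, truth = simulate_cohort(CohortSimSpec(seed=5), gmap, reference)
        n_point = sum(len(r.point_calls) for r in records)
        n_length = sum(len(r.length_calls) for r in records)
        assert n_point == sum(1 for e in truth["events"] if e["type"] == "point")
        assert n_length == sum(1 for e in truth["events"] if e["type"] == "length")

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValidationError):
            CohortSimSpec(p_point_carrier=1.2).validate()
        with pytest.raises(ValidationError):
            CohortSimSpec(ts_bias=-1).validate()


def _strip(records):
    return [
        (
            r.individual_id,
            tuple((c.position, c.major_allele, c.minor_allele, c.level)
                  for c in r.point_calls),
            tuple((c.start, c.end) for c in r.length_calls),
        )
        for r in records
    ]


class TestSimulatePeaks:
    def test_zero_noise_is_exact(self):
        obs = simulate_peaks(0.10, 0.0, 6, seed=0)
        assert estimate_level(obs, track_base="G") == pytest.approx(0.10)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            simulate_peaks(0.1, -0.1, 6, seed=0)

    @pytest.mark.parametrize(
        "level, sd, expected_detected",
        [(0.02, 0.005, 0), (0.05, 0.005, 0), (0.10, 0.0, 20)],
    )
    def test_detection_sensitivity_pattern(self, level, sd, expected_detected):
        """In-silico analogue of the gradient-mixture validation: mixtures at
        2% and 5% fall below the 10% operational threshold, 10% mixtures are
        always detected."""
        detected = 0
        for rep in range(20):
            obs = simulate_peaks(level, sd, 1, seed=100 + rep)
            if detect_mixed_base(obs[0], threshold=0.10) is not None:
                detected += 1
        assert detected == expected_detected


class TestSimulateHitTable:
    def test_planted_enrichment_recovery(self):
        """Positions planted well above the hotspot boundary (20x the mean)
        are recovered by the hotspot rule at a >=80% rate."""
        from mthet.stability import hotspot_classify, mutation_probabilities

        planted = list(range(50, 16569, 400))
        table, truth = simulate_hit_table(
            hotspot_positions=planted, enrichment=20.0, total_hits=10000, seed=21
        )
        p = mutation_probabilities(table)
        recovered = sum(
            1
            for pos in planted
            if hotspot_classify(p.get(pos, 0.0), table.hits_at(pos), table.mean_p)
            == "hotspot"
        )
        assert recovered / len(planted) >= 0.8

    def test_total_and_bounds(self):
        table, _ = simulate_hit_table(
            n_positions=500, hotspot_positions=[5], enrichment=5.0,
            total_hits=2000, seed=1,
        )
        assert table.total_hits == 2000
        assert set(table.hits) <= set(range(1, 501))

    def test_invalid_parameters(self):
        with pytest.raises(ValidationError):
            simulate_hit_table(total_hits=0, seed=0)
        with pytest.raises(ValidationError):
            simulate_hit_table(enrichment=1.0, seed=0)
        with pytest.raises(ValidationError):
            simulate_hit_table(
                n_positions=100, hotspot_positions=range(1, 60),
                enrichment=2.0, seed=0,
            )


class TestSimulateAlignment:
    def test_full_conservation_is_exact(self):
        aln, truth = simulate_alignment(
            AlignmentSimSpec(n_species=10, conservation={7: 1.0}, seed=0)
        )
        wt = truth["wild_types"][7]
        assert conservation_index(aln, 7, wt) == 100.0

    def test_conservation_target_recovered(self):
        """At the emulated alignment depth the measured CI sits within three
        binomial standard deviations of the target."""
        target = 0.7711
        n = 1491
        aln, truth = simulate_alignment(
            AlignmentSimSpec(n_species=n, conservation={1: target}, seed=13)
        )
        ci = conservation_index(aln, 1, truth["wild_types"][1])
        sd = 100 * np.sqrt(target * (1 - target) / n)
        assert abs(ci - 100 * target) <= 3 * sd

    def test_seed_contract(self):
        spec = dict(n_species=50, conservation={1: 0.5, 2: 0.9})
        a1, _ = simulate_alignment(AlignmentSimSpec(**spec, seed=1))
        a2, _ = simulate_alignment(AlignmentSimSpec(**spec, seed=1))
        a3, _ = simulate_alignment(AlignmentSimSpec(**spec, seed=2))
        assert (a1.matrix == a2.matrix).all()
        assert (a1.matrix != a3.matrix).any()

    def test_gaps_and_amino_acid_alphabet(self):
        aln, truth = simulate_alignment(
            AlignmentSimSpec(
                n_species=200, conservation={3: 0.9}, alphabet="aa",
                gap_fraction=0.2, seed=4,
            )
        )
        col = aln.column(3)
        assert (col == "-").sum() > 0
        assert set(col) <= set("ACDEFGHIKLMNPQRSTVWY-")
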