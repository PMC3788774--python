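"""Seeded generators for every input the pipeline consumes.

Every stage of the package can be exercised offline: the generators emit a
synthetic rCRS-like reference, cohorts of individuals with planted point and
length heteroplasmies, electropherogram peak tables, phylogeny hit tables,
population allele databases and cross-species alignments — each with a
ground-truth record, full reproducibility (one explicit seed per call, no
global random state), and defaults matching the source cohort's printed
rates (101 individuals; 23.76% point and 48.51% length carriers; 70.9% of
length events in the HVRII poly-C tract; transition:transversion bias
15.5:1; haplogroup H at 42.58%).

The reference produced by :func:`simulate_reference` is synthetic: it has
the real rCRS length, the standard gene layout and valid mitochondrial open
reading frames, and a small set of anchored positions carrying their
documented reference state, but its remaining sequence is random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .genome_map import COMPLEMENT, GenomeMap, RCRS_LENGTH
from .heteroplasmy import (
    DEFAULT_TRACTS,
    IndividualRecord,
    LengthHeteroplasmyCall,
    PeakObservation,
    PointHeteroplasmyCall,
)
from .stability import AlignmentMatrix, HitTable

_STOPS = ("TAA", "TAG", "AGA", "AGG")
_NON_STOP = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

#: documented reference bases at positions discussed in the source study
DEFAULT_BASE_ANCHORS = {152: "T", 16189: "T"}

#: documented codons: COXII codon 57 is GAC (Asp; G at 7754), ND4 codon 165
#: is ATC (Ile; T at 11253)
DEFAULT_CODON_ANCHORS = (("MT-CO2", 57, "GAC"), ("MT-ND4", 165, "ATC"))

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

#: haplogroup label frequencies of the emulated cohort
DEFAULT_HAPLOGROUP_FREQS = {
    "H": 43 / 101, "HV": 4 / 101, "V": 4 / 101, "R0": 1 / 101,
    "J": 13 / 101, "K": 7 / 101, "L": 3 / 101, "M": 1 / 101,
    "N": 1 / 101, "I": 1 / 101, "W": 2 / 101, "T": 4 / 101, "U": 17 / 101,
}

#: tract shares among length heteroplasmies ("free" = a non-catalogued
#: coding-region tract)
DEFAULT_TRACT_PROBS = {
    "HVRI poly-C (16184-16193)": 5 / 55,
    "HVRII poly-C (303-315)": 39 / 55,
    "HVRIII poly-AC (514-525)": 3 / 55,
    "HVRIII poly-C (568-573)": 5 / 55,
    "free": 3 / 55,
}


def simulate_reference(
    gmap: GenomeMap | None = None,
    seed: int = 0,
    base_anchors: dict[int, str] | None = None,
    codon_anchors=DEFAULT_CODON_ANCHORS,
) -> str:
    """Generate a synthetic rCRS-like reference sequence.

    Protein genes receive valid vertebrate-mitochondrial ORFs (start codon,
    no internal stops in their own frame, stop or poly-A-completed partial
    stop); all other positions are uniform random bases.  ``base_anchors``
    and ``codon_anchors`` then pin selected positions/codons to their
    documented reference state; where genes overlap, the later-listed gene's
    frame wins in the overlap.
    """
    gmap = gmap or GenomeMap.default()
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=gmap.length)

    for f in gmap.features:
        if f.ftype != "protein":
            continue
        n_coding = (f.length - f.incomplete_stop) // 3
        codons = ["ATG" if rng.random() < 0.8 else "ATA"]
        body_n = n_coding - (1 if f.incomplete_stop else 2)
        codons += list(rng.choice(_NON_STOP, size=body_n))
        cds = "".join(codons)
        if f.incomplete_stop:
            cds += "TA"[: f.incomplete_stop]
        else:
            cds += str(rng.choice(_STOPS))
        if f.strand == "H":
            seq[f.start - 1 : f.end] = list(cds)
        else:
            rc = [COMPLEMENT[b] for b in reversed(cds)]
            seq[f.start - 1 : f.end] = rc

    for gene_name, codon_index, codon in codon_anchors:
        g = gmap.feature(gene_name)
        if g.strand == "H":
            start = g.start + 3 * (codon_index - 1)
            seq[start - 1 : start + 2] = list(codon)
        else:
            start = g.end - 3 * (codon_index - 1)
            seq[start - 3 : start] = [COMPLEMENT[b] for b in reversed(codon)]

    for pos, base in (base_anchors or DEFAULT_BASE_ANCHORS).items():
        seq[pos - 1] = base
    return "".join(seq)


# -- cohort ----------------------------------------------------------------


@dataclass
class CohortSimSpec:
    """Study-condition parameters of the synthetic cohort."""

    n_individuals: int = 101
    p_point_carrier: float = 0.2376
    mean_point_events: float = 29 / 24  # events per point-heteroplasmy carrier
    p_length_carrier: float = 0.4851
    mean_length_events: float = 55 / 49
    tract_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRACT_PROBS)
    )
    control_region_share: float = 8 / 29  # share of point events in the D-loop
    ts_bias: float = 15.5  # transition:transversion odds
    haplogroup_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAPLOGROUP_FREQS)
    )
    female_fraction: float = 0.5
    level_range: tuple[float, float] = (0.10, 0.45)
    n_reads: int = 6
    seed: int = 0  # mandatory explicit seed; reproducibility contract

    def validate(self) -> None:
        probs = [
            self.p_point_carrier,
            self.p_length_carrier,
            self.control_region_share,
            self.female_fraction,
            *self.tract_probs.values(),
            *self.haplogroup_freqs.values(),
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if self.n_individuals < 0:
            raise ValidationError("n_individuals must be nonnegative")
        if self.mean_point_events < 1 or self.mean_length_events < 1:
            raise ValidationError("mean events per carrier must be >= 1")
        if self.ts_bias <= 0:
            raise ValidationError("ts_bias must be positive")
        lo, hi = self.level_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("level_range must be within [0, 1]")


def _control_positions():
    return list(range(16024, RCRS_LENGTH + 1)) + list(range(1, 577))


def simulate_cohort(
    spec: CohortSimSpec, gmap: GenomeMap | None = None, reference: str | None = None
) -> tuple[list[IndividualRecord], dict]:
    """Generate a cohort of individuals with planted heteroplasmies.

    Returns ``(records, truth)``; the truth dict records every planted
    event (position, alleles, level, region, tract) and the spec parameters.
    """
    spec.validate()
    gmap = gmap or GenomeMap.default()
    if reference is None:
        reference = simulate_reference(gmap, seed=spec.seed)
    rng = np.random.default_rng(spec.seed)
    control = _control_positions()
    coding = [p for p in range(1, gmap.length + 1) if not gmap.in_control_region(p)]
    hg_labels = list(spec.haplogroup_freqs)
    hg_p = np.array([spec.haplogroup_freqs[h] for h in hg_labels], dtype=float)
    hg_p = hg_p / hg_p.sum()
    tract_labels = list(spec.tract_probs)
    tract_p = np.array([spec.tract_probs[t] for t in tract_labels], dtype=float)
    tract_p = tract_p / tract_p.sum()
    tracts_by_label = {t.label: t for t in DEFAULT_TRACTS}

    records, events = [], []
    p_ts = spec.ts_bias / (spec.ts_bias + 1.0)
    for i in range(spec.n_individuals):
        iid = f"IND{i + 1:03d}"
        sex = "F" if rng.random() < spec.female_fraction else "M"
        hg = hg_labels[rng.choice(len(hg_labels), p=hg_p)]
        rec = IndividualRecord(individual_id=iid, sex=sex, haplogroup=hg)

        if spec.p_point_carrier and rng.random() < spec.p_point_carrier:
            n_ev = int(rng.geometric(min(1.0, 1.0 / spec.mean_point_events)))
            used = set()
            for _ in range(n_ev):
                while True:
                    if rng.random() < spec.control_region_share:
                        pos = int(control[rng.integers(len(control))])
                    else:
                        pos = int(coding[rng.integers(len(coding))])
                    if pos not in used:
                        used.add(pos)
                        break
                ref = reference[pos - 1]
                if rng.random() < p_ts:
                    alt = TRANSITION[ref]
                    kind = "transition"
                else:
                    alt = TRANSVERSIONS[ref][rng.integers(2)]
                    kind = "transversion"
                level = float(rng.uniform(*spec.level_range))
                call = PointHeteroplasmyCall(
                    individual_id=iid,
                    position=pos,
                    major_allele=ref,
                    minor_allele=alt,
                    level=level,
                    n_reads=spec.n_reads,
                )
                rec.point_calls.append(call)
                events.append(
                    {
                        "individual_id": iid,
                        "type": "point",
                        "position": pos,
                        "ref": ref,
                        "alt": alt,
                        "change_kind": kind,
                        "level": level,
                        "in_control_region": gmap.in_control_region(pos),
                    }
                )

        if spec.p_length_carrier and rng.random() < spec.p_length_carrier:
            n_ev = int(rng.geometric(min(1.0, 1.0 / spec.mean_length_events)))
            used_tracts: set[tuple[int, int]] = set()
            for _ in range(n_ev):
                start = end = None
                for _attempt in range(100):  # an individual holds distinct tracts
                    label = tract_labels[rng.choice(len(tract_labels), p=tract_p)]
                    if label in tracts_by_label:
                        t = tracts_by_label[label]
                        start, end = t.start, t.end
                    else:  # free tract at a random coding-region position
                        start = int(coding[rng.integers(len(coding))])
                        end = min(start + int(rng.integers(0, 10)), gmap.length)
                        label = (f"pos {start}" if start == end
                                 else f"pos {start}-{end}")
                    if (start, end) not in used_tracts:
                        break
                if (start, end) in used_tracts:
                    continue
                used_tracts.add((start, end))
                rec.length_calls.append(
                    LengthHeteroplasmyCall(
                        individual_id=iid, tract_label=label, start=start, end=end
                    )
                )
                events.append(
                    {
                        "individual_id": iid,
                        "type": "length",
                        "tract_label": label,
                        "start": start,
                        "end": end,
                    }
                )
        records.append(rec)

    truth = {
        "spec": {
            "n_individuals": spec.n_individuals,
            "p_point_carrier": spec.p_point_carrier,
            "mean_point_events": spec.mean_point_events,
            "p_length_carrier": spec.p_length_carrier,
            "mean_length_events": spec.mean_length_events,
            "tract_probs": spec.tract_probs,
            "control_region_share": spec.control_region_share,
            "ts_bias": spec.ts_bias,
            "female_fraction": spec.female_fraction,
            "level_range": list(spec.level_range),
            "n_reads": spec.n_reads,
            "seed": spec.seed,
        },
        "events": events,
    }
    return records, truth


# -- peak traces -----------------------------------------------------------


def simulate_peaks(
    true_level: float,
    noise_sd: float,
    n_reads: int,
    seed: int,
    position: int = 1,
    bases: tuple[str, str] = ("A", "G"),
    total_height: float = 1000.0,
) -> list[PeakObservation]:
    """Per-read peak pairs around a true minor-variant mixing level.

    Each read's minor fraction is drawn from a normal around ``true_level``
    truncated to [0, 1]; ``bases`` is (wild-type, minor variant).  When noise
    pushes the minor fraction above 0.5 the minor base becomes the primary
    peak of that read.
    """
    if not (0 <= true_level <= 1):
        raise ValidationError("true_level must lie in [0, 1]")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be nonnegative")
    if n_reads < 1:
        raise ValidationError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_reads):
        frac = true_level if noise_sd == 0 else float(
            np.clip(rng.normal(true_level, noise_sd), 0.0, 1.0)
        )
        h_minor = frac * total_height
        h_wild = total_height - h_minor
        if h_minor > h_wild:
            primary, secondary = (bases[1], h_minor), (bases[0], h_wild)
        else:
            primary, secondary = (bases[0], h_wild), (bases[1], h_minor)
        out.append(
            PeakObservation(
                position=position,
                read_id=f"read{r + 1}",
                base_primary=primary[0],
                height_primary=primary[1],
                base_secondary=secondary[0],
                height_secondary=secondary[1],
            )
        )
    return out


# -- hit tables ------------------------------------------------------------


def simulate_hit_table(
    n_positions: int = RCRS_LENGTH,
    hotspot_positions=(),
    enrichment: float = 10.0,
    total_hits: int = 10000,
    seed: int = 0,
) -> tuple[HitTable, dict]:
    """Multinomial hit counts with planted enriched positions.

    ``enrichment`` is the planted positions' mutation probability expressed
    as a multiple of the uniform mean probability 1/n_positions (the same
    scale the hotspot rule thresholds); the remaining probability mass is
    spread uniformly over the other positions.  Returns the table and a
    truth dict listing the planted positions.
    """
    if total_hits <= 0:
        raise ValidationError("total_hits must be positive")
    if enrichment <= 1:
        raise ValidationError("enrichment must exceed 1")
    hot = sorted(set(int(p) for p in hotspot_positions))
    if any(not (1 <= p <= n_positions) for p in hot):
        raise ValidationError("hotspot positions outside 1..n_positions")
    n_hot = len(hot)
    p_hot = enrichment / n_positions
    if n_hot * p_hot >= 1.0:
        raise ValidationError("planted probability mass reaches 1; reduce enrichment")
    p = np.full(n_positions, (1.0 - n_hot * p_hot) / (n_positions - n_hot))
    for pos in hot:
        p[pos - 1] = p_hot
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total_hits, p)
    table = HitTable(
        {i + 1: int(c) for i, c in enumerate(counts) if c > 0},
        n_positions=n_positions,
    )
    truth = {
        "hotspot_positions": hot,
        "enrichment": enrichment,
        "total_hits": total_hits,
        "n_positions": n_positions,
        "seed": seed,
    }
    return table, truth


# -- alignments ------------------------------------------------------------

_AA_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")
_NT_ALPHABET = tuple("ACGT")


@dataclass
class AlignmentSimSpec:
    """Parameters of a synthetic cross-species (or population) alignment."""

    n_species: int
    conservation: dict[int, float]  # position -> wild-type match probability
    wild_types: dict[int, str] | None = None  # position -> symbol; random if absent
    alphabet: str = "nt"  # "nt" or "aa"
    gap_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        if self.alphabet not in ("nt", "aa"):
            raise ValidationError("alphabet must be 'nt' or 'aa'")
        if any(not (0 <= c <= 1) for c in self.conservation.values()):
            raise ValidationError("conservation targets must lie in [0, 1]")
        if not (0 <= self.gap_fraction < 1):
            raise ValidationError("gap_fraction must lie in [0, 1)")


def simulate_alignment(spec: AlignmentSimSpec) -> tuple[AlignmentMatrix, dict]:
    """Columns with controlled wild-type conservation.

    Each column corresponds to one mapped position; each species carries the
    wild type with the column's conservation probability, a uniformly chosen
    other symbol otherwise, and a gap with probability ``gap_fraction``
    (applied first).  Returns the alignment and a truth dict with the
    wild-type symbols and targets.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alphabet = _NT_ALPHABET if spec.alphabet == "nt" else _AA_ALPHABET
    positions = sorted(spec.conservation)
    wild = {}
    for pos in positions:
        if spec.wild_types and pos in spec.wild_types:
            wild[pos] = spec.wild_types[pos].upper()
        else:
            wild[pos] = str(rng.choice(alphabet))
    matrix = np.empty((spec.n_species, len(positions)), dtype="<U1")
    for j, pos in enumerate(positions):
        others = [s for s in alphabet if s != wild[pos]]
        target = spec.conservation[pos]
        for i in range(spec.n_species):
            if spec.gap_fraction and rng.random() < spec.gap_fraction:
                matrix[i, j] = "-"
            elif rng.random() < target:
                matrix[i, j] = wild[pos]
            else:
                matrix[i, j] = others[rng.integers(len(others))]
    ids = [f"species{i + 1:04d}" for i in range(spec.n_species)]
    aln = AlignmentMatrix(ids, matrix, {pos: j for j, pos in enumerate(positions)})
    truth = {
        "wild_types": wild,
        "conservation": dict(spec.conservation),
        "alphabet": spec.alphabet,
        "seed": spec.seed,
    }
    return aln, truth
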