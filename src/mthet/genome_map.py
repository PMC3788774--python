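"""rCRS coordinate system, feature map and substitution-effect classification.

The human mitochondrial genome is annotated against the 16,569-bp revised
Cambridge Reference Sequence (rCRS).  Coordinates are 1-based and inclusive
throughout.  The control region spans the replication origin and is
represented as the two linear intervals 16024-16569 and 1-576; no circular
arithmetic is used elsewhere.

Protein-coding effects are evaluated under the vertebrate mitochondrial
genetic code (NCBI translation table 2), in which ATA encodes Met, TGA
encodes Trp and AGA/AGG are stop codons.  Genes encoded on the light strand
(MT-ND6 and several tRNAs) are classified on the light-strand codon after
complementing the observed alleles.  Genes ending in an incomplete stop
codon (T or TA, completed to TAA by polyadenylation of the mRNA) are
classified against the poly-A-completed codon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .errors import CoordinateError, ReferenceMismatchError, ValidationError

RCRS_LENGTH = 16569

#: control region as two linear intervals around the origin
CONTROL_REGION = ((16024, 16569), (1, 576))

#: default hypervariable-region bounds; chosen to contain the classical
#: length-variable tracts (16184-16193, 303-315, 514-525, 568-573)
DEFAULT_HVR_BOUNDS = {
    "HVRI": (16024, 16383),
    "HVRII": (57, 372),
    "HVRIII": (438, 576),
}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

#: polarity/acidity classes used to describe amino-acid replacements
_ACIDIC = frozenset("DE")
_BASIC = frozenset("KRH")


@dataclass(frozen=True)
class Feature:
    """One annotated interval of the mitochondrial genome.

    ``incomplete_stop`` is the number of bases (0, 1 or 2) of the stop codon
    present at the 3' end of a protein gene; the remainder is supplied by
    polyadenylation.
    """

    name: str
    start: int
    end: int
    strand: str  # "H" (heavy) or "L" (light)
    ftype: str  # protein | tRNA | rRNA | non-coding
    complex: str | None = None  # respiratory complex I/III/IV/V for proteins
    incomplete_stop: int = 0

    def __post_init__(self):
        if not (1 <= self.start <= self.end <= RCRS_LENGTH):
            raise ValidationError(
                f"feature {self.name}: bad interval {self.start}-{self.end}"
            )
        if self.strand not in ("H", "L"):
            raise ValidationError(f"feature {self.name}: strand must be H or L")
        if self.ftype == "protein":
            if (self.length + (3 - self.incomplete_stop) % 3) % 3:
                raise ValidationError(
                    f"protein feature {self.name}: length {self.length} not a "
                    f"whole number of codons (incomplete_stop={self.incomplete_stop})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class RegionAnnotation:
    """Answer to "what is position p?" on the rCRS."""

    position: int
    region: str  # D-loop | HVRI | HVRII | HVRIII | coding | intergenic
    features: tuple[str, ...]
    ftype: str | None  # ftype of the priority (first-listed) feature
    complex: str | None

    @property
    def in_control_region(self) -> bool:
        return self.region in ("D-loop", "HVRI", "HVRII", "HVRIII")


@dataclass(frozen=True)
class CodingEffect:
    gene: str
    codon_index: int  # 1-based within the gene
    codon_ref: str
    codon_alt: str
    aa_ref: str  # three-letter, or "STOP"
    aa_alt: str
    effect: str  # synonymous | non-synonymous | stop-gain | stop-loss
    polarity_change: str | None  # e.g. "acidic->neutral"; None when a stop is involved


@dataclass(frozen=True)
class SubstitutionClass:
    position: int
    allele_a: str
    allele_b: str
    change_kind: str  # transition | transversion
    base_class: str  # purine | pyrimidine | mixed
    coding_effect: CodingEffect | None = None


class GenomeMap:
    """Feature catalogue and region bounds of the rCRS.

    Parameters
    ----------
    features:
        Annotated intervals in priority order: when intervals overlap (e.g.
        ATP8/ATP6, ND4L/ND4) annotation reports every overlap, but tallies and
        coding-effect classification use the first-listed feature.
    length:
        Genome length; the rCRS is 16,569 bp.
    hvr_bounds:
        Mapping of hypervariable-region name to (start, end).
    """

    def __init__(
        self,
        features: Iterable[Feature],
        length: int = RCRS_LENGTH,
        hvr_bounds: dict[str, tuple[int, int]] | None = None,
        control_region: tuple[tuple[int, int], ...] = CONTROL_REGION,
    ):
        self.length = length
        self.features: tuple[Feature, ...] = tuple(features)
        self.hvr_bounds = dict(hvr_bounds or DEFAULT_HVR_BOUNDS)
        self.control_region = tuple(control_region)
        self._by_name = {f.name: f for f in self.features}

    # -- construction ------------------------------------------------------

    @classmethod
    def default(cls) -> "GenomeMap":
        """The packaged standard rCRS feature catalogue."""
        path = resources.files("mthet.data").joinpath("rcrs_features.tsv")
        with resources.as_file(path) as p:
            return cls.from_tsv(p)

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "GenomeMap":
        feats = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            required = {"name", "start", "end", "strand", "ftype", "complex"}
            missing = required - set(header)
            if missing:
                raise ValidationError(f"feature file missing columns: {sorted(missing)}")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                row = line.rstrip("\n").split("\t")
                cplx = row[idx["complex"]]
                feats.append(
                    Feature(
                        name=row[idx["name"]],
                        start=int(row[idx["start"]]),
                        end=int(row[idx["end"]]),
                        strand=row[idx["strand"]],
                        ftype=row[idx["ftype"]],
                        complex=None if cplx in ("none", "", "NA") else cplx,
                        incomplete_stop=int(row[idx["incomplete_stop"]])
                        if "incomplete_stop" in idx
                        else 0,
                    )
                )
        return cls(feats, **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        cols = ["name", "start", "end", "strand", "ftype", "complex", "incomplete_stop"]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for f in self.features:
                fh.write(
                    "\t".join(
                        [
                            f.name,
                            str(f.start),
                            str(f.end),
                            f.strand,
                            f.ftype,
                            f.complex or "none",
                            str(f.incomplete_stop),
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def from_json(cls, path: str | Path, **kwargs) -> "GenomeMap":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        feats = [Feature(**row) for row in data["features"]]
        return cls(feats, length=data.get("length", RCRS_LENGTH), **kwargs)

    def to_json(self, path: str | Path) -> None:
        data = {
            "length": self.length,
            "features": [
                {
                    "name": f.name,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "ftype": f.ftype,
                    "complex": f.complex,
                    "incomplete_stop": f.incomplete_stop,
                }
                for f in self.features
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1)

    # -- queries -----------------------------------------------------------

    def feature(self, name: str) -> Feature:
        return self._by_name[name]

    def features_at(self, pos: int) -> list[Feature]:
        self._check_pos(pos)
        return [f for f in self.features if f.contains(pos)]

    def in_control_region(self, pos: int) -> bool:
        self._check_pos(pos)
        return any(a <= pos <= b for a, b in self.control_region)

    def protein_gene_at(self, pos: int) -> Feature | None:
        for f in self.features:
            if f.ftype == "protein" and f.contains(pos):
                return f
        return None

    def _check_pos(self, pos: int) -> None:
        if not (1 <= pos <= self.length):
            raise CoordinateError(f"position {pos} outside 1..{self.length}")


def locate_position(pos: int, gmap: GenomeMap) -> RegionAnnotation:
    """Annotate a single rCRS coordinate.

    Region labels are assigned with priority HVRI > HVRII > HVRIII > D-loop
    within the control region; elsewhere a position in at least one feature
    is "coding" and a position in none is "intergenic".
    """
    gmap._check_pos(pos)
    feats = gmap.features_at(pos)
    if gmap.in_control_region(pos):
        region = "D-loop"
        for name in ("HVRI", "HVRII", "HVRIII"):
            lo, hi = gmap.hvr_bounds[name]
            if lo <= pos <= hi:
                region = name
                break
    elif feats:
        region = "coding"
    else:
        region = "intergenic"
    return RegionAnnotation(
        position=pos,
        region=region,
        features=tuple(f.name for f in feats),
        ftype=feats[0].ftype if feats else None,
        complex=feats[0].complex if feats else None,
    )


def translate_mito(codon: str, strand: str = "H") -> str:
    """Translate one codon under the vertebrate mitochondrial code.

    The codon is given on the heavy strand in genome orientation; for a
    light-strand gene pass ``strand="L"`` and the reverse complement is
    translated.  Returns the three-letter amino-acid code, or ``"STOP"``.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValidationError(f"invalid codon {codon!r}")
    if strand == "L":
        codon = "".join(COMPLEMENT[b] for b in reversed(codon))
    elif strand != "H":
        raise ValidationError("strand must be 'H' or 'L'")
    if codon in _MITO_TABLE.stop_codons:
        return "STOP"
    return seq3(_MITO_TABLE.forward_table[codon])


def polarity_class(aa3: str) -> str | None:
    """Coarse polarity/acidity class of a three-letter amino acid."""
    if aa3 == "STOP":
        return None
    return _polarity_from_aa3(aa3)


def _polarity_from_aa3(aa3: str) -> str:
    from Bio.SeqUtils import seq1

    one = seq1(aa3)
    if one in _ACIDIC:
        return "acidic"
    if one in _BASIC:
        return "basic"
    return "neutral"


def _codon_at(
    gene: Feature, pos: int, reference: str
) -> tuple[int, int, str]:
    """Return (codon_index 1-based, offset within codon 0-based, codon string).

    The codon string is in the gene's coding orientation; incomplete stop
    codons are completed with A (polyadenylation).
    """
    if gene.strand == "H":
        offset = pos - gene.start
    else:
        offset = gene.end - pos
    ci, within = divmod(offset, 3)
    bases = []
    for k in range(3):
        if gene.strand == "H":
            p = gene.start + 3 * ci + k
            if p > gene.end:
                bases.append("A")  # poly-A completion of incomplete stop
            else:
                bases.append(reference[p - 1].upper())
        else:
            p = gene.end - 3 * ci - k
            if p < gene.start:
                bases.append("A")
            else:
                bases.append(COMPLEMENT[reference[p - 1].upper()])
    return ci + 1, within, "".join(bases)


def classify_substitution(
    pos: int,
    allele_a: str,
    allele_b: str,
    gmap: GenomeMap,
    reference: str,
) -> SubstitutionClass:
    """Classify a biallelic substitution at an rCRS position.

    ``reference`` is the full genome sequence (heavy strand).  One of the two
    alleles must equal the reference base at ``pos``; the coding effect (for
    positions inside a protein gene) is obtained by substituting the
    non-reference allele into the codon containing the position.
    """
    allele_a, allele_b = allele_a.upper(), allele_b.upper()
    if allele_a not in BASES or allele_b not in BASES:
        raise ValidationError(f"alleles must be A/C/G/T, got {allele_a}/{allele_b}")
    if allele_a == allele_b:
        raise ValidationError("alleles are identical; not a substitution")
    gmap._check_pos(pos)
    ref_base = reference[pos - 1].upper()
    if ref_base not in (allele_a, allele_b):
        raise ReferenceMismatchError(
            f"reference base {ref_base} at {pos} matches neither allele "
            f"{allele_a}/{allele_b}"
        )
    alt = allele_b if ref_base == allele_a else allele_a

    if allele_a in PURINES and allele_b in PURINES:
        base_class = "purine"
    elif allele_a in PYRIMIDINES and allele_b in PYRIMIDINES:
        base_class = "pyrimidine"
    else:
        base_class = "mixed"
    change_kind = "transversion" if base_class == "mixed" else "transition"

    effect = None
    gene = gmap.protein_gene_at(pos)
    if gene is not None:
        ci, within, codon_ref = _codon_at(gene, pos, reference)
        if gene.strand == "H":
            sub = alt
        else:
            sub = COMPLEMENT[alt]
        codon_alt = codon_ref[:within] + sub + codon_ref[within + 1 :]
        aa_ref = translate_mito(codon_ref)
        aa_alt = translate_mito(codon_alt)
        if aa_ref == aa_alt:
            kind = "synonymous"
        elif aa_alt == "STOP":
            kind = "stop-gain"
        elif aa_ref == "STOP":
            kind = "stop-loss"
        else:
            kind = "non-synonymous"
        pol = None
        if "STOP" not in (aa_ref, aa_alt):
            pol = f"{_polarity_from_aa3(aa_ref)}->{_polarity_from_aa3(aa_alt)}"
        effect = CodingEffect(
            gene=gene.name,
            codon_index=ci,
            codon_ref=codon_ref,
            codon_alt=codon_alt,
            aa_ref=aa_ref,
            aa_alt=aa_alt,
            effect=kind,
            polarity_change=pol,
        )
    return SubstitutionClass(
        position=pos,
        allele_a=allele_a,
        allele_b=allele_b,
        change_kind=change_kind,
        base_class=base_class,
        coding_effect=effect,
    )


def structural_context(pos: int, structure_table: dict[int, str]) -> str:
    """Stem/loop context of a structured-RNA position; lookup only.

    Returns ``"unknown"`` when the table has no entry for the position.
    """
    value = structure_table.get(pos)
    if value is None:
        return "unknown"
    if value not in ("stem", "loop"):
        raise ValidationError(f"structure table value must be stem/loop, got {value!r}")
    return value
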