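"""Evolutionary-stability scoring of heteroplasmic positions.

Three complementary lines of evidence are combined per position:

* **hits in the phylogeny** — the number of independent occurrences of a
  mutation at the position across the human mtDNA phylogeny, a proxy for
  site mutability.  The per-position probability of mutation is
  hits / total hits; a position is a *hotspot* when that probability is at
  least ten times the mean per-position probability.
* **population-database frequencies** — per-allele frequencies of the
  position in a large alignment of complete mtDNA genomes; a high major-
  variant frequency indicates the position is effectively invariant in
  present-day populations.
* **conservation index (CI)** — the percentage of species in a cross-species
  reference alignment carrying the wild-type nucleotide (or amino acid) at
  the position.

A position is *stable* when it has few hits, a near-fixed major variant and
a high nucleotide CI, and *highly stable* when in addition the amino-acid CI
is high; default thresholds are the observed minima over the stable
positions of the source cohort and are fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoordinateError, ValidationError
from .genome_map import RCRS_LENGTH

GAP = "-"


# -- hit tables and mutation probability -----------------------------------


class HitTable:
    """Per-position phylogeny hit counts over a fixed set of positions.

    ``n_positions`` is the number of positions the probabilities are spread
    over (default: the rCRS length); positions absent from ``hits`` carry
    zero hits.
    """

    def __init__(self, hits: dict[int, int], n_positions: int = RCRS_LENGTH):
        for pos, h in hits.items():
            if h < 0 or h != int(h):
                raise ValidationError(f"hit count at {pos} must be a nonnegative int")
        self.hits = {int(p): int(h) for p, h in hits.items() if h > 0}
        self.n_positions = int(n_positions)

    @property
    def total_hits(self) -> int:
        return sum(self.hits.values())

    def hits_at(self, pos: int) -> int:
        return self.hits.get(pos, 0)

    @property
    def mean_p(self) -> float:
        """Mean per-position mutation probability, 1/n_positions."""
        return 1.0 / self.n_positions

    @classmethod
    def from_tsv(cls, path: str | Path, n_positions: int = RCRS_LENGTH) -> "HitTable":
        df = pd.read_csv(path, sep="\t")
        if not {"position", "hits"} <= set(df.columns):
            raise ValidationError("hit table needs columns: position, hits")
        return cls(dict(zip(df["position"].astype(int), df["hits"].astype(int))),
                   n_positions=n_positions)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.hits.items()), columns=["position", "hits"]
        ).to_csv(path, sep="\t", index=False)


def mutation_probabilities(table: HitTable) -> dict[int, float]:
    """Per-position probability of mutation, hits(i) / total hits.

    Positions with zero hits (probability 0) are omitted from the returned
    dict; together with them the probabilities sum to one.
    """
    total = table.total_hits
    if total == 0:
        raise ValidationError("degenerate hit table: total hits is zero")
    return {pos: h / total for pos, h in table.hits.items()}


def hotspot_classify(
    p_mut: float, hits: int, mean_p: float, factor: float = 10.0
) -> str:
    """Mutability class of a position given its mutation probability.

    Classes: ``zero_hits`` (never seen in the phylogeny), ``hotspot``
    (p_mut at least ``factor`` times the mean — boundary inclusive),
    ``no_hotspot_ge_mean`` and ``no_hotspot_lt_mean``.
    """
    if mean_p <= 0:
        raise ValidationError("mean_p must be positive")
    if hits == 0:
        return "zero_hits"
    if p_mut >= factor * mean_p:
        return "hotspot"
    if p_mut >= mean_p:
        return "no_hotspot_ge_mean"
    return "no_hotspot_lt_mean"


HOTSPOT_CLASSES = ("zero_hits", "hotspot", "no_hotspot_ge_mean", "no_hotspot_lt_mean")


# -- alignments: conservation index and population frequencies -------------


class AlignmentMatrix:
    """A rectangular multiple alignment with a column -> coordinate map.

    ``coord_map`` maps an rCRS position (or, for amino-acid alignments, the
    representative nucleotide position of the codon) to a 0-based column
    index; by default column i represents position i+1.
    """

    def __init__(self, ids, matrix, coord_map: dict[int, int] | None = None):
        self.ids = list(ids)
        self.matrix = np.asarray(matrix, dtype="<U1")
        if self.matrix.ndim != 2 or len(self.ids) != self.matrix.shape[0]:
            raise ValidationError("alignment matrix must be rectangular (ids x columns)")
        if coord_map is None:
            coord_map = {i + 1: i for i in range(self.matrix.shape[1])}
        if len(set(coord_map.values())) != len(coord_map):
            raise ValidationError("coordinate map must be injective")
        self.coord_map = dict(coord_map)

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column(self, position: int) -> np.ndarray:
        col = self.coord_map.get(position)
        if col is None:
            raise CoordinateError(f"position {position} not mapped in alignment")
        return self.matrix[:, col]

    @classmethod
    def from_fasta(
        cls, path: str | Path, coord_map: dict[int, int] | None = None
    ) -> "AlignmentMatrix":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(list(str(rec.seq).upper()))
        if not rows:
            raise ValidationError(f"no sequences in {path}")
        if len({len(r) for r in rows}) != 1:
            raise ValidationError("alignment sequences differ in length")
        return cls(ids, np.array(rows), coord_map)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for sid, row in zip(self.ids, self.matrix):
                fh.write(f">{sid}\n{''.join(row)}\n")


def conservation_index(
    aln: AlignmentMatrix,
    position: int,
    wild_type: str,
    count_gaps: bool = False,
) -> float:
    """Percentage of aligned species carrying the wild-type symbol.

    Gap entries are excluded from the denominator by default (the alignment
    offers no evidence either way there); with ``count_gaps`` they are
    treated as mismatches.
    """
    wild_type = wild_type.upper()
    if not wild_type or len(wild_type) != 1:
        raise ValidationError("wild_type must be a single symbol")
    col = aln.column(position)
    if count_gaps:
        counted = col
    else:
        counted = col[col != GAP]
    if counted.size == 0:
        raise ValidationError(f"no counted entries in column for position {position}")
    return 100.0 * float((counted == wild_type).sum()) / counted.size


def population_frequencies(db: AlignmentMatrix, position: int) -> dict[str, float]:
    """Per-allele frequencies (%) at a position of the population database.

    Frequencies are taken over the sequences carrying A/C/G/T or a gap at
    the position (other symbols are uncounted) and sum to 100%.
    """
    col = db.column(position)
    symbols = ("A", "C", "G", "T", GAP)
    counts = {s: int((col == s).sum()) for s in symbols}
    n = sum(counts.values())
    if n == 0:
        raise ValidationError(f"no counted sequences at position {position}")
    return {s: 100.0 * c / n for s, c in counts.items()}


def major_variant_frequency(db: AlignmentMatrix, position: int) -> float:
    """Frequency (%) of the most common base (gaps are not a variant)."""
    freqs = population_frequencies(db, position)
    return max(freqs[b] for b in "ACGT")


# -- combined stability classification -------------------------------------


@dataclass(frozen=True)
class StabilityThresholds:
    """Gates of the stable / highly-stable classification.

    Defaults are the observed minima across the stable positions of the
    source cohort: at most 2 phylogeny hits, major variant at >= 99.6% in
    the population database, nucleotide CI >= 77.11%, and (for highly
    stable) amino-acid CI >= 92.9%.
    """

    max_hits: int = 2
    min_major_freq: float = 99.6
    min_ci_nt: float = 77.11
    min_ci_aa: float = 92.9


STABILITY_CLASSES = ("unstable", "stable", "highly_stable")


@dataclass(frozen=True)
class PositionStabilityProfile:
    """All stability evidence gathered for one position."""

    position: int
    hits: int
    p_mut: float
    hotspot_class: str
    major_variant_freq: float
    ci_nt: float
    ci_aa: float | None = None  # absent outside protein genes or when no
    # amino-acid alignment covers the position
    is_protein: bool = False
    stability_class: str | None = None
    aa_assessed: bool = True  # False = highly-stable tier not assessable

    def __post_init__(self):
        if not (0 <= self.p_mut <= 1):
            raise ValidationError("p_mut outside [0, 1]")
        for v in (self.major_variant_freq, self.ci_nt, self.ci_aa):
            if v is not None and not (0 <= v <= 100):
                raise ValidationError("percentages must lie in [0, 100]")
        if (self.hits == 0) != (self.hotspot_class == "zero_hits"):
            raise ValidationError("zero_hits class must coincide with hits == 0")


def stability_classify(
    profile: PositionStabilityProfile,
    thresholds: StabilityThresholds = StabilityThresholds(),
) -> tuple[str, bool]:
    """Classify a position as unstable / stable / highly_stable.

    Returns ``(stability_class, aa_assessed)``.  For a protein position
    whose amino-acid CI is unavailable the highly-stable tier cannot be
    tested: the position is reported as ``stable`` with ``aa_assessed``
    False — an explicit "not assessable" outcome, never a silent pass.
    """
    t = thresholds
    stable = (
        profile.hits <= t.max_hits
        and profile.major_variant_freq >= t.min_major_freq
        and profile.ci_nt >= t.min_ci_nt
    )
    if not stable:
        return "unstable", True
    if profile.ci_aa is None:
        if profile.is_protein:
            return "stable", False  # highly-stable tier not assessable
        return "stable", True
    if profile.ci_aa >= t.min_ci_aa:
        return "highly_stable", True
    return "stable", True


def build_profiles(
    positions,
    hit_table: HitTable,
    popdb: AlignmentMatrix,
    aln_nt: AlignmentMatrix,
    reference: str,
    gmap,
    aln_aa: AlignmentMatrix | None = None,
    aa_wild_types: dict[int, str] | None = None,
    thresholds: StabilityThresholds = StabilityThresholds(),
    hotspot_factor: float = 10.0,
) -> list[PositionStabilityProfile]:
    """Assemble and classify stability profiles for a set of positions.

    The nucleotide wild type at each position is the reference base.  For
    protein positions the amino-acid CI column is looked up in ``aln_aa``
    via its coordinate map; ``aa_wild_types`` supplies the wild-type
    amino-acid symbol per position (one-letter, as stored in the alignment).
    """
    from .genome_map import translate_mito, _codon_at  # local import, no cycle

    total = hit_table.total_hits
    mean_p = hit_table.mean_p
    out = []
    for pos in positions:
        hits = hit_table.hits_at(pos)
        p = hits / total if total else 0.0
        hclass = hotspot_classify(p, hits, mean_p, factor=hotspot_factor)
        major = major_variant_frequency(popdb, pos)
        ci_nt = conservation_index(aln_nt, pos, reference[pos - 1])
        gene = gmap.protein_gene_at(pos)
        ci_aa = None
        if gene is not None and aln_aa is not None and pos in aln_aa.coord_map:
            if aa_wild_types and pos in aa_wild_types:
                wt = aa_wild_types[pos]
            else:
                from Bio.SeqUtils import seq1

                _, _, codon = _codon_at(gene, pos, reference)
                aa3 = translate_mito(codon)
                wt = "*" if aa3 == "STOP" else seq1(aa3)
            ci_aa = conservation_index(aln_aa, pos, wt)
        prof = PositionStabilityProfile(
            position=pos,
            hits=hits,
            p_mut=p,
            hotspot_class=hclass,
            major_variant_freq=major,
            ci_nt=ci_nt,
            ci_aa=ci_aa,
            is_protein=gene is not None,
        )
        sclass, assessed = stability_classify(prof, thresholds)
        out.append(
            PositionStabilityProfile(
                **{
                    **prof.__dict__,
                    "stability_class": sclass,
                    "aa_assessed": assessed,
                }
            )
        )
    return out


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Tabulate stability profiles (one row per position)."""
    return pd.DataFrame(
        [
            {
                "position": p.position,
                "hits": p.hits,
                "p_mut": p.p_mut,
                "hotspot_class": p.hotspot_class,
                "major_variant_freq": p.major_variant_freq,
                "ci_nt": p.ci_nt,
                "ci_aa": p.ci_aa,
                "is_protein": p.is_protein,
                "stability_class": p.stability_class,
                "aa_assessed": p.aa_assessed,
            }
            for p in profiles
        ]
    )
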