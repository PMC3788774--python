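"""Point/length heteroplasmy calls, level estimation and cohort classification.

A point heteroplasmy is a position where two bases coexist within one
individual (reported as an IUPAC two-base code in Sanger traces); a length
heteroplasmy is a homopolymer/repeat tract of variable length (recorded
categorically, tract present/absent).  The heteroplasmy level is estimated
from electropherogram peak heights as the secondary/(primary+secondary)
height ratio averaged over sequence reads; by default at least six reads are
required.  Candidate calls are screened at a mixed-base detection threshold
and accepted only if they appear in every independent validation step
(re-amplification, re-extraction).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import InsufficientReadsError, SignalError, ValidationError

#: two-base IUPAC ambiguity codes (unordered expansions)
IUPAC_TWO_BASE = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

_PAIR_TO_IUPAC = {v: k for k, v in IUPAC_TWO_BASE.items()}

#: screening threshold used by base-calling software and the validated
#: operational detection threshold (see package docs)
SCREENING_THRESHOLD = 0.02
DETECTION_THRESHOLD = 0.10

DEFAULT_MIN_READS = 6

#: classification categories, in reporting order
CATEGORIES = ("Homoplasmy", "1 PH", "1 LH", ">1 PH", ">1 LH", "One or more PH+LH")


def parse_mixed_base(code: str) -> tuple[str, str]:
    """Expand a two-base IUPAC ambiguity code into its base pair.

    Only the six two-base codes (R, Y, S, W, K, M) are mixtures of exactly
    two bases; anything else (plain bases, three/four-base codes) is
    rejected.
    """
    pair = IUPAC_TWO_BASE.get(code.upper())
    if pair is None:
        raise ValidationError(f"{code!r} is not a two-base IUPAC mixture code")
    a, b = sorted(pair)
    return a, b


def iupac_for_pair(base1: str, base2: str) -> str:
    """Inverse of :func:`parse_mixed_base`."""
    code = _PAIR_TO_IUPAC.get(frozenset((base1.upper(), base2.upper())))
    if code is None:
        raise ValidationError(f"no two-base IUPAC code for {base1}/{base2}")
    return code


@dataclass(frozen=True)
class PeakObservation:
    """Primary/secondary peak heights at one position in one sequence read."""

    position: int
    read_id: str
    base_primary: str
    height_primary: float
    base_secondary: str
    height_secondary: float

    def __post_init__(self):
        if not (self.height_primary >= self.height_secondary >= 0):
            raise ValidationError(
                "peak heights must satisfy primary >= secondary >= 0"
            )

    @property
    def total(self) -> float:
        return self.height_primary + self.height_secondary

    @property
    def secondary_fraction(self) -> float:
        if self.total == 0:
            raise SignalError(f"zero total peak height at {self.position}")
        return self.height_secondary / self.total


@dataclass(frozen=True)
class PointHeteroplasmyCall:
    individual_id: str
    position: int
    major_allele: str
    minor_allele: str
    level: float | None = None  # minor-variant proportion; may exceed 0.5 when
    # the level tracks a designated (e.g. mutant) base
    n_reads: int | None = None

    def __post_init__(self):
        if self.level is not None and not (0 <= self.level <= 1):
            raise ValidationError(f"level {self.level} outside [0, 1]")
        if self.n_reads is not None and self.n_reads < 1:
            raise ValidationError("n_reads must be >= 1")

    @property
    def iupac_code(self) -> str:
        return iupac_for_pair(self.major_allele, self.minor_allele)

    @property
    def allele_key(self) -> frozenset:
        return frozenset((self.major_allele, self.minor_allele))


@dataclass(frozen=True)
class LengthHeteroplasmyCall:
    individual_id: str
    tract_label: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError("tract start must be <= end")


@dataclass
class IndividualRecord:
    individual_id: str
    sex: str | None = None
    haplogroup: str | None = None
    point_calls: list[PointHeteroplasmyCall] = field(default_factory=list)
    length_calls: list[LengthHeteroplasmyCall] = field(default_factory=list)


def detect_mixed_base(
    obs: PeakObservation, threshold: float = DETECTION_THRESHOLD
) -> PointHeteroplasmyCall | None:
    """Screen one peak observation for a mixed base.

    A candidate call is emitted iff the secondary peak carries at least
    ``threshold`` of the total height; the minor allele is the secondary
    base.  Returns ``None`` below threshold.
    """
    if not (0 < threshold <= 0.5):
        raise ValidationError("detection threshold must lie in (0, 0.5]")
    frac = obs.secondary_fraction  # raises SignalError on zero signal
    if frac >= threshold and obs.height_secondary > 0:
        return PointHeteroplasmyCall(
            individual_id="",
            position=obs.position,
            major_allele=obs.base_primary,
            minor_allele=obs.base_secondary,
            level=frac,
            n_reads=1,
        )
    return None


def estimate_level(
    observations,
    min_reads: int = DEFAULT_MIN_READS,
    allow_fewer: bool = False,
    track_base: str | None = None,
) -> float:
    """Average peak-height ratio over the reads covering one position.

    By default the level is the mean secondary/(primary+secondary) fraction.
    When ``track_base`` is given, the level is the mean height fraction of
    that base instead, whichever peak it occupies in each read — a mutant
    variant tracked this way can exceed 0.5 when it is the primary peak.
    """
    obs = list(observations)
    if len({o.position for o in obs}) > 1:
        raise ValidationError("observations span more than one position")
    if len(obs) < min_reads and not allow_fewer:
        raise InsufficientReadsError(
            f"{len(obs)} reads < required {min_reads} (pass allow_fewer to override)"
        )
    if not obs:
        raise ValidationError("no observations supplied")
    fracs = []
    for o in obs:
        if track_base is None:
            fracs.append(o.secondary_fraction)
        elif track_base == o.base_primary:
            fracs.append(1.0 - o.secondary_fraction)
        elif track_base == o.base_secondary:
            fracs.append(o.secondary_fraction)
        else:
            fracs.append(0.0)
    return sum(fracs) / len(fracs)


def confirm_calls(step_calls) -> list[PointHeteroplasmyCall]:
    """Replicate-intersection authentication of point heteroplasmy.

    ``step_calls`` holds one call collection per independent validation step
    (amplification / extraction).  A call is confirmed iff its
    (individual, position, allele pair) appears in every step; the confirmed
    calls are returned as observed in the first step.
    """
    steps = [list(s) for s in step_calls]
    if len(steps) < 2:
        raise ValidationError("need at least two validation steps")
    keys = [
        {(c.individual_id, c.position, c.allele_key) for c in s} for s in steps
    ]
    common = set.intersection(*keys)
    return [
        c
        for c in steps[0]
        if (c.individual_id, c.position, c.allele_key) in common
    ]


def classify_individual(record: IndividualRecord) -> str:
    """Assign one heteroplasmy-presence category to an individual.

    Categories partition a cohort: carriers of at least one point AND at
    least one length heteroplasmy fall in "One or more PH+LH"; pure point or
    pure length carriers split on one-vs-more; everyone else is homoplasmic.
    """
    n_ph = len(record.point_calls)
    n_lh = len(record.length_calls)
    if n_ph == 0 and n_lh == 0:
        return "Homoplasmy"
    if n_ph >= 1 and n_lh >= 1:
        return "One or more PH+LH"
    if n_ph == 1:
        return "1 PH"
    if n_ph > 1:
        return ">1 PH"
    if n_lh == 1:
        return "1 LH"
    return ">1 LH"


def classify_cohort(records) -> Counter:
    """Category counts over a cohort (every category present, even at zero)."""
    counts = Counter({c: 0 for c in CATEGORIES})
    for r in records:
        counts[classify_individual(r)] += 1
    return counts


@dataclass(frozen=True)
class Tract:
    """A catalogued length-variable tract of the mitochondrial genome."""

    label: str
    start: int
    end: int


#: classical length-variable tracts of the control region
DEFAULT_TRACTS = (
    Tract("HVRI poly-C (16184-16193)", 16184, 16193),
    Tract("HVRII poly-C (303-315)", 303, 315),
    Tract("HVRIII poly-AC (514-525)", 514, 525),
    Tract("HVRIII poly-C (568-573)", 568, 573),
)


def tally_length_tracts(calls, tracts=DEFAULT_TRACTS) -> dict[str, int]:
    """Count length heteroplasmies per catalogued tract.

    A call is assigned to the first catalogue tract containing its bounds;
    calls outside the catalogue are tallied under their own coordinates
    (label "pos a-b" or "pos a"), as free positions.  The dict preserves
    catalogue order, then free positions by coordinate.
    """
    counts: dict[str, int] = {t.label: 0 for t in tracts}
    free: Counter = Counter()
    for c in calls:
        for t in tracts:
            if t.start <= c.start and c.end <= t.end:
                counts[t.label] += 1
                break
        else:
            label = f"pos {c.start}" if c.start == c.end else f"pos {c.start}-{c.end}"
            free[label] += 1
    for label in sorted(free, key=lambda s: int(s.split()[1].split("-")[0])):
        counts[label] = free[label]
    return counts
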