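"""Readers and writers for the package's plain-text interchange formats.

Interchange dialect: UTF-8 tab-separated values with a header row; FASTA for
sequences and alignments; JSON for truth records and machine-readable table
output; YAML for run configuration.  Percentages are rounded only at
serialization (2 decimals for point estimates, 1 for interval bounds); the
JSON output keeps full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ParseError, ValidationError
from .heteroplasmy import (
    IndividualRecord,
    LengthHeteroplasmyCall,
    PeakObservation,
    PointHeteroplasmyCall,
    iupac_for_pair,
)

CALL_REPORT_COLUMNS = [
    "individual_id", "sex", "haplogroup", "position", "type",
    "major_allele", "minor_allele", "iupac", "level", "n_reads",
    "tract_label", "tract_start", "tract_end",
]

_NA = ""


# -- call reports ----------------------------------------------------------


def write_call_report(records, path: str | Path) -> None:
    """Serialise a cohort to the call-report TSV.

    Individuals without any call are kept as a single ``type=none`` row so
    the cohort denominator survives a round trip.
    """
    rows = []

    def row(base, **kwargs):
        full = {c: _NA for c in CALL_REPORT_COLUMNS}
        full.update(base)
        full.update({k: str(v) for k, v in kwargs.items()})
        return full

    for rec in records:
        base = {
            "individual_id": rec.individual_id,
            "sex": rec.sex or _NA,
            "haplogroup": rec.haplogroup or _NA,
        }
        if not rec.point_calls and not rec.length_calls:
            rows.append(row(base, type="none"))
        for c in rec.point_calls:
            rows.append(
                row(
                    base,
                    position=c.position,
                    type="point",
                    major_allele=c.major_allele,
                    minor_allele=c.minor_allele,
                    iupac=c.iupac_code,
                    level="" if c.level is None else repr(c.level),
                    n_reads="" if c.n_reads is None else c.n_reads,
                )
            )
        for c in rec.length_calls:
            rows.append(
                row(
                    base,
                    position=c.start,
                    type="length",
                    tract_label=c.tract_label,
                    tract_start=c.start,
                    tract_end=c.end,
                )
            )
    df = pd.DataFrame(rows, columns=CALL_REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_call_report(path: str | Path) -> list[IndividualRecord]:
    """Parse and validate a call-report TSV into individual records.

    Malformed rows are reported with their 1-based file line number;
    duplicate (individual, position, type) rows are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(CALL_REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"call report missing columns: {sorted(missing)}")
    records: dict[str, IndividualRecord] = {}
    seen = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        iid = row["individual_id"].strip()
        if not iid:
            raise ParseError("empty individual_id", line=line)
        rec = records.setdefault(
            iid,
            IndividualRecord(
                individual_id=iid,
                sex=row["sex"] or None,
                haplogroup=row["haplogroup"] or None,
            ),
        )
        rtype = row["type"].strip()
        if rtype == "none":
            continue
        if rtype == "point":
            try:
                pos = int(row["position"])
            except ValueError:
                raise ParseError(f"bad position {row['position']!r}", line=line)
            if pos < 1:
                raise ParseError(f"position {pos} must be >= 1", line=line)
            key = (iid, pos, "point")
            if key in seen:
                raise ParseError(f"duplicate point call {iid}@{pos}", line=line)
            seen.add(key)
            major, minor = row["major_allele"].upper(), row["minor_allele"].upper()
            if not major or not minor:
                code = row["iupac"].strip()
                if not code:
                    raise ParseError("point call needs alleles or an IUPAC code",
                                     line=line)
                from .heteroplasmy import parse_mixed_base

                major, minor = parse_mixed_base(code)
            try:
                call = PointHeteroplasmyCall(
                    individual_id=iid,
                    position=pos,
                    major_allele=major,
                    minor_allele=minor,
                    level=float(row["level"]) if row["level"] else None,
                    n_reads=int(row["n_reads"]) if row["n_reads"] else None,
                )
            except (ValidationError, ValueError) as exc:
                raise ParseError(str(exc), line=line)
            rec.point_calls.append(call)
        elif rtype == "length":
            try:
                start = int(row["tract_start"])
                end = int(row["tract_end"])
            except ValueError:
                raise ParseError("length call needs integer tract bounds", line=line)
            key = (iid, start, end, "length")
            if key in seen:
                raise ParseError(f"duplicate length call {iid}@{start}-{end}",
                                 line=line)
            seen.add(key)
            try:
                call = LengthHeteroplasmyCall(
                    individual_id=iid,
                    tract_label=row["tract_label"] or f"pos {start}-{end}",
                    start=start,
                    end=end,
                )
            except ValidationError as exc:
                raise ParseError(str(exc), line=line)
            rec.length_calls.append(call)
        else:
            raise ParseError(f"unknown call type {rtype!r}", line=line)
    return list(records.values())


# -- peak tables -----------------------------------------------------------

PEAK_COLUMNS = [
    "position", "read_id", "base_primary", "height_primary",
    "base_secondary", "height_secondary",
]


def write_peak_table(observations, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "position": o.position,
                "read_id": o.read_id,
                "base_primary": o.base_primary,
                "height_primary": repr(float(o.height_primary)),
                "base_secondary": o.base_secondary,
                "height_secondary": repr(float(o.height_secondary)),
            }
            for o in observations
        ],
        columns=PEAK_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_peak_table(path: str | Path) -> list[PeakObservation]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"peak table missing columns: {sorted(missing)}")
    return [
        PeakObservation(
            position=int(r["position"]),
            read_id=str(r["read_id"]),
            base_primary=str(r["base_primary"]),
            height_primary=float(r["height_primary"]),
            base_secondary=str(r["base_secondary"]),
            height_secondary=float(r["height_secondary"]),
        )
        for _, r in df.iterrows()
    ]


# -- sequences -------------------------------------------------------------


def read_reference(path: str | Path) -> str:
    """Single-record FASTA -> uppercase sequence string."""
    from Bio import SeqIO

    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 1:
        raise ParseError(f"reference FASTA must hold exactly 1 record, got {len(recs)}")
    return str(recs[0].seq).upper()


def write_reference(sequence: str, path: str | Path, name: str = "synthetic_rCRS",
                    width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def write_coord_map(coord_map: dict[int, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(coord_map.items()), columns=["position", "column"]
    ).to_csv(path, sep="\t", index=False)


def read_coord_map(path: str | Path) -> dict[int, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["position"].astype(int), df["column"].astype(int)))


# -- summary tables --------------------------------------------------------


def _round_freq_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col.endswith("pct"):
            out[col] = out[col].round(2)
        elif "ci_" in col:
            out[col] = out[col].round(1)
    return out


def write_summary_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> None:
    """Emit each summary table as rounded TSV plus full-precision JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        _round_freq_frame(df).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        with open(outdir / f"{name}.json", "w", encoding="utf-8") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)


# -- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Paths, thresholds and the seed of one pipeline run."""

    reference: str | None = None
    features: str | None = None
    calls: str | None = None
    hits: str | None = None
    popdb: str | None = None
    aln_nt: str | None = None
    aln_aa: str | None = None
    structure_table: str | None = None
    outdir: str = "out"
    seed: int = 0
    detection_threshold: float = 0.10
    screening_threshold: float = 0.02
    min_reads: int = 6
    hotspot_factor: float = 10.0
    max_hits: int = 2
    min_major_freq: float = 99.6
    min_ci_nt: float = 77.11
    min_ci_aa: float = 92.9
    ci_method: str = "wilson"

    def validate(self) -> None:
        if not (0 < self.detection_threshold <= 0.5):
            raise ValidationError("detection_threshold must lie in (0, 0.5]")
        if not (0 < self.screening_threshold <= 0.5):
            raise ValidationError("screening_threshold must lie in (0, 0.5]")
        if self.min_reads < 1:
            raise ValidationError("min_reads must be >= 1")
        if self.hotspot_factor <= 0:
            raise ValidationError("hotspot_factor must be positive")
        if self.ci_method not in ("wilson", "jeffreys"):
            raise ValidationError("ci_method must be wilson or jeffreys")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logging."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
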