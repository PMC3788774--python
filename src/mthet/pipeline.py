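"""Cohort-level analysis: annotation joins and the five summary tables.

The summary layer reproduces the structure of the source study's result
tables: individual classification (heteroplasmy presence), length-tract
distribution, point-heteroplasmy distribution across genome regions,
mutational-spectrum ratios, and the stability/hotspot distribution.  All
percentages are carried unrounded; rounding happens at serialization.
"""

from __future__ import annotations

import pandas as pd

from .genome_map import GenomeMap, classify_substitution, locate_position
from .heteroplasmy import (
    CATEGORIES,
    DEFAULT_TRACTS,
    classify_cohort,
    tally_length_tracts,
)
from .stability import HOTSPOT_CLASSES, HitTable, hotspot_classify
from .stats import RatioSummary, freq_with_ci, ratio_summary

_TABLE6_LABELS = {
    "zero_hits": "0 Hits",
    "hotspot": "Hotspot",
    "no_hotspot_ge_mean": "No hotspot >= mean",
    "no_hotspot_lt_mean": "No hotspot < mean",
}


def _freq_rows(rows, method: str = "wilson") -> pd.DataFrame:
    """Build a frequency table from (label, k, n) triples; n = 0 yields zeros."""
    out = []
    for label, k, n in rows:
        if n == 0:
            out.append(
                {"label": label, "k": 0, "n": 0, "pct": 0.0,
                 "ci_low": 0.0, "ci_high": 0.0}
            )
        else:
            est = freq_with_ci(k, n, method=method)
            out.append(
                {"label": label, "k": k, "n": n, "pct": est.pct,
                 "ci_low": est.ci_low, "ci_high": est.ci_high}
            )
    return pd.DataFrame(out)


def annotate_point_calls(records, gmap: GenomeMap, reference: str) -> pd.DataFrame:
    """One row per point-heteroplasmy event with region and substitution class."""
    rows = []
    for rec in records:
        for call in rec.point_calls:
            ann = locate_position(call.position, gmap)
            sub = classify_substitution(
                call.position, call.major_allele, call.minor_allele, gmap, reference
            )
            eff = sub.coding_effect
            rows.append(
                {
                    "individual_id": rec.individual_id,
                    "position": call.position,
                    "major_allele": call.major_allele,
                    "minor_allele": call.minor_allele,
                    "iupac": call.iupac_code,
                    "level": call.level,
                    "region": ann.region,
                    "in_control_region": ann.in_control_region,
                    "features": ";".join(ann.features),
                    "ftype": ann.ftype,
                    "complex": ann.complex,
                    "change_kind": sub.change_kind,
                    "base_class": sub.base_class,
                    "gene": eff.gene if eff else None,
                    "codon_index": eff.codon_index if eff else None,
                    "aa_ref": eff.aa_ref if eff else None,
                    "aa_alt": eff.aa_alt if eff else None,
                    "effect": eff.effect if eff else None,
                    "polarity_change": eff.polarity_change if eff else None,
                }
            )
    cols = [
        "individual_id", "position", "major_allele", "minor_allele", "iupac",
        "level", "region", "in_control_region", "features", "ftype", "complex",
        "change_kind", "base_class", "gene", "codon_index", "aa_ref", "aa_alt",
        "effect", "polarity_change",
    ]
    return pd.DataFrame(rows, columns=cols)


def table_classification(records, method: str = "wilson") -> pd.DataFrame:
    """Individual-classification table (heteroplasmy presence categories).

    Adds the aggregate rows: Heteroplasmy (any), Total PH (individuals with
    at least one point event) and Total LH; denominators are the cohort
    size.
    """
    recs = list(records)
    n = len(recs)
    counts = classify_cohort(recs)
    hetero = n - counts["Homoplasmy"]
    total_ph = sum(1 for r in recs if r.point_calls)
    total_lh = sum(1 for r in recs if r.length_calls)
    rows = [("Homoplasmy", counts["Homoplasmy"], n), ("Heteroplasmy", hetero, n)]
    rows += [(c, counts[c], n) for c in CATEGORIES if c != "Homoplasmy"]
    rows += [("Total PH", total_ph, n), ("Total LH", total_lh, n)]
    return _freq_rows(rows, method=method)


def table_length_tracts(
    records, tracts=DEFAULT_TRACTS, method: str = "wilson"
) -> pd.DataFrame:
    """Length-heteroplasmy distribution over tracts; denominator = events."""
    calls = [c for r in records for c in r.length_calls]
    counts = tally_length_tracts(calls, tracts)
    total = sum(counts.values())
    return _freq_rows([(label, k, total) for label, k in counts.items()],
                      method=method)


def table_regions(annotated: pd.DataFrame, method: str = "wilson") -> pd.DataFrame:
    """Point-heteroplasmy distribution across genome regions.

    The D-loop row covers the whole control region (HVR rows are subsets of
    it); every non-control-region event — including the rare intergenic
    positions — is counted in the coding-region row, which then splits into
    tRNA/rRNA and respiratory-complex rows.  Denominator = point events.
    """
    n = len(annotated)
    in_ctrl = annotated["in_control_region"] if n else pd.Series(dtype=bool)
    rows = [
        ("D-loop", int(in_ctrl.sum()) if n else 0, n),
        ("HVRI", int((annotated["region"] == "HVRI").sum()) if n else 0, n),
        ("HVRII", int((annotated["region"] == "HVRII").sum()) if n else 0, n),
        ("HVRIII", int((annotated["region"] == "HVRIII").sum()) if n else 0, n),
        ("Coding region", int((~in_ctrl).sum()) if n else 0, n),
        ("tRNA", int((annotated["ftype"] == "tRNA").sum()) if n else 0, n),
        ("rRNA", int((annotated["ftype"] == "rRNA").sum()) if n else 0, n),
    ]
    for cx in ("I", "III", "IV", "V"):
        k = int((annotated["complex"] == cx).sum()) if n else 0
        rows.append((f"Complex {cx}", k, n))
    return _freq_rows(rows, method=method)


def table_ratios(records, gmap: GenomeMap, reference: str) -> dict[str, RatioSummary]:
    """Mutational-spectrum ratios, whole genome and control region."""
    whole, ctrl = [], []
    for rec in records:
        for call in rec.point_calls:
            sub = classify_substitution(
                call.position, call.major_allele, call.minor_allele, gmap, reference
            )
            whole.append(sub)
            if gmap.in_control_region(call.position):
                ctrl.append(sub)
    return {"whole_genome": ratio_summary(whole), "control_region": ratio_summary(ctrl)}


def ratios_frame(ratios: dict[str, RatioSummary]) -> pd.DataFrame:
    rows = []
    for scope, rs in ratios.items():
        rows.append(
            {
                "scope": scope,
                "ts": rs.ts, "tv": rs.tv,
                "ts_tv": rs.ts_tv_str,
                "purine_ts": rs.purine_ts, "pyrimidine_ts": rs.pyrimidine_ts,
                "purine_pyrimidine": rs.purine_pyrimidine_str,
                "ns": rs.ns, "syn": rs.syn,
                "ns_syn": rs.ns_syn_str,
            }
        )
    return pd.DataFrame(rows)


def table_stability(
    event_hotspot_classes,
    hit_table: HitTable | None = None,
    hotspot_factor: float = 10.0,
    method: str = "wilson",
) -> pd.DataFrame:
    """Hotspot-class distribution of heteroplasmic events vs fixed mutations.

    ``event_hotspot_classes`` holds one hotspot class per heteroplasmic
    event.  When a full hit table is supplied, the fixed-mutation columns
    distribute its hits over the same classes (the zero-hits class holds no
    hits by construction).
    """
    events = list(event_hotspot_classes)
    n_ev = len(events)
    bad = set(events) - set(HOTSPOT_CLASSES)
    if bad:
        raise ValueError(f"unknown hotspot classes: {sorted(bad)}")
    rows = []
    hits_by_class = {c: 0 for c in HOTSPOT_CLASSES}
    total_hits = 0
    if hit_table is not None:
        total_hits = hit_table.total_hits
        mean_p = hit_table.mean_p
        for pos, h in hit_table.hits.items():
            cls = hotspot_classify(h / total_hits, h, mean_p, factor=hotspot_factor)
            hits_by_class[cls] += h
    for cls in HOTSPOT_CLASSES:
        k_ev = sum(1 for e in events if e == cls)
        ev = _freq_rows([(cls, k_ev, n_ev)], method=method).iloc[0]
        fx = _freq_rows([(cls, hits_by_class[cls], total_hits)], method=method).iloc[0]
        rows.append(
            {
                "label": _TABLE6_LABELS[cls],
                "ph_k": int(ev["k"]), "ph_n": int(ev["n"]), "ph_pct": ev["pct"],
                "ph_ci_low": ev["ci_low"], "ph_ci_high": ev["ci_high"],
                "fixed_k": int(fx["k"]), "fixed_n": int(fx["n"]),
                "fixed_pct": fx["pct"],
                "fixed_ci_low": fx["ci_low"], "fixed_ci_high": fx["ci_high"],
            }
        )
    return pd.DataFrame(rows)
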