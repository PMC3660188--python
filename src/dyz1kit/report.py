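"""Report rendering: stage results as JSON and plain-text tables.

Tables mirror the layouts the field prints for this kind of analysis:
the pentamer-spectrum table lists the exact reference motif first, then
the fifteen single-base derivatives in their conventional order, then
aggregate counts per distance class and the array size; the digest table
lists per-enzyme site frequencies with lost/gained flags.
"""

from __future__ import annotations

import json
from typing import Mapping

import pandas as pd

from .digest import DigestSummary
from .pentamer import REFERENCE_MOTIF, PentamerSpectrum, hamming
from .qpcr import QuantResult, StandardCurve
from .variants import VariantTally

#: Conventional row order of the fifteen single-base derivatives.
ONE_BP_ROW_ORDER = [
    "ATCCA", "TACCA", "TTACA", "TTCAA", "TTTCA", "TTCTA", "TTCCT",
    "GTCCA", "TGCCA", "TTGCA", "TTCGA", "TTCCG", "CTCCA", "TCCCA", "TTCCC",
]

SECTION_ORDER = ["spectrum", "digest", "variants", "sts", "qpcr"]

__all__ = [
    "ONE_BP_ROW_ORDER",
    "SECTION_ORDER",
    "spectrum_table",
    "spectrum_to_dict",
    "digest_summary_to_dict",
    "tally_to_dict",
    "curve_to_dict",
    "quant_to_dict",
    "render_report",
]


def spectrum_table(spectra: Mapping[str, PentamerSpectrum]) -> pd.DataFrame:
    """One column per array, rows in the conventional spectrum layout."""
    if not spectra:
        raise ValueError("no spectra to tabulate")
    rows = (
        ["actual_size_bp", REFERENCE_MOTIF, "1bp_derivatives"]
        + ONE_BP_ROW_ORDER
        + ["2bp_derivatives", "3bp_derivatives", "4bp_derivatives", "5bp_derivatives",
           "residue_bases"]
    )
    table: dict[str, list[int]] = {}
    for name, spec in spectra.items():
        agg = spec.by_distance
        col = [spec.total_length, spec.counts.get(REFERENCE_MOTIF, 0), agg.get(1, 0)]
        col += [spec.counts.get(m, 0) for m in ONE_BP_ROW_ORDER]
        col += [agg.get(d, 0) for d in (2, 3, 4, 5)]
        col.append(spec.residue_bases)
        table[name] = col
    return pd.DataFrame(table, index=rows)


def spectrum_to_dict(spec: PentamerSpectrum) -> dict:
    return {
        "total_length": spec.total_length,
        "residue_bases": spec.residue_bases,
        "counts": dict(sorted(spec.counts.items())),
        "by_distance": {str(d): c for d, c in sorted(spec.by_distance.items())},
    }


def digest_summary_to_dict(summary: DigestSummary) -> dict:
    return {
        "reference": dict(summary.reference),
        "sample": dict(summary.sample),
        "lost": sorted(summary.lost),
        "gained": sorted(summary.gained),
        "changed": sorted(summary.changed),
    }


def tally_to_dict(tally: VariantTally) -> dict:
    return {
        "substitutions": tally.substitutions,
        "substitution_sites": [
            {"ref_position": p, "ref": r, "alt": a} for p, r, a in tally.substitution_sites
        ],
        "indels": [
            {"kind": e.kind, "ref_position": e.ref_position, "length": e.length}
            for e in tally.indels
        ],
        "net_length_change": tally.net_length_change,
    }


def curve_to_dict(curve: StandardCurve) -> dict:
    return {
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r_squared": curve.r_squared,
        "efficiency": curve.efficiency,
        "n_points": curve.n_points,
        "warnings": list(curve.warnings),
    }


def quant_to_dict(result: QuantResult) -> dict:
    return {
        "sample": result.sample,
        "ct": result.ct,
        "copies_per_reaction": result.copies_per_reaction,
        "input_mass_pg": result.input_mass_pg,
        "copies_per_genome_equivalent": result.copies_per_genome_equivalent,
    }


def _text_section(name: str, payload: dict) -> str:
    lines = [f"== {name} =="]
    df = pd.json_normalize(payload, sep=".")
    for col in df.columns:
        lines.append(f"{col}: {df[col].iloc[0]}")
    return "\n".join(lines)


def render_report(sections: Mapping[str, dict]) -> tuple[str, str]:
    """Combine stage outputs into (json_text, human_readable_text).

    Sections render in the fixed pipeline order; unknown section names
    are rejected.  The JSON round-trips to identical values.
    """
    if not sections:
        raise ValueError("report needs at least one stage output")
    unknown = set(sections) - set(SECTION_ORDER)
    if unknown:
        raise ValueError(f"unknown report sections: {sorted(unknown)}")
    ordered = {name: sections[name] for name in SECTION_ORDER if name in sections}
    json_text = json.dumps(ordered, indent=2, sort_keys=False)
    text = "\n\n".join(_text_section(name, payload) for name, payload in ordered.items())
    return json_text, text
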