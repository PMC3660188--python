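"""In-silico PCR and STS presence/absence deletion mapping of the MSY.

Sequence-tagged sites (sY markers) are short, uniquely amplifiable
landmarks on the male-specific region of the Y chromosome.  Recurrent
interstitial deletions (AZFa, P5/proximal-P1, P5/distal-P1, AZFc, gr/gr,
b1/b2, b2/b3, TSPY-TSPY) each leave a characteristic pattern of absent
markers; a profile is classified by matching configurable signatures.

Signature semantics: a deletion class is called iff *all* of its
``absent`` markers are absent from the profile AND all of its
``flanks`` (required-present) markers are present.  Overlapping or
nested signature matches are all reported, sorted by class name.

The shipped 51-marker panel and the deletion-signature config are
editable data assets; the signature file is a curated approximation of
deletion intervals from the clinical deletion-mapping literature, not a
hard-coded truth (see its ``comment`` fields).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .core_io import Region, SequenceRecord, read_table, reverse_complement

__all__ = [
    "PrimerPair",
    "StsMarker",
    "StsProfile",
    "DeletionSignature",
    "amplicon_length_from_coords",
    "predict_amplicon",
    "profile_sts",
    "profile_from_template",
    "classify_deletions",
    "load_sts_panel",
    "load_signatures",
    "default_sts_panel_path",
    "default_signatures_path",
]


@dataclasses.dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, optionally with template coordinates."""

    id: str
    forward: str = ""
    reverse: str = ""
    forward_region: Region | None = None
    reverse_region: Region | None = None

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if seq and len(seq) < 15:
                raise ValueError(
                    f"primer of pair {self.id!r} shorter than 15 bases: {seq!r}"
                )


@dataclasses.dataclass(frozen=True)
class StsMarker:
    id: str
    locus: str = ""
    multicopy: bool = False


@dataclasses.dataclass(frozen=True)
class StsProfile:
    """Presence/absence call for every marker of a panel, exactly once."""

    status: Mapping[str, bool]  # marker id -> present?

    @property
    def absent(self) -> frozenset[str]:
        return frozenset(m for m, present in self.status.items() if not present)

    @property
    def present(self) -> frozenset[str]:
        return frozenset(m for m, present in self.status.items() if present)


@dataclasses.dataclass(frozen=True)
class DeletionSignature:
    """Named deletion class: markers that must be absent, flanks that
    must be present."""

    name: str
    absent: frozenset[str]
    flanks: frozenset[str] = frozenset()
    comment: str = ""

    def __post_init__(self) -> None:
        if self.absent & self.flanks:
            raise ValueError(
                f"signature {self.name!r}: markers both absent and flanking: "
                f"{sorted(self.absent & self.flanks)}"
            )
        if not self.absent:
            raise ValueError(f"signature {self.name!r} has no absent markers")


def amplicon_length_from_coords(fwd: Region, rev: Region) -> int:
    """End-point PCR product length from primer template coordinates:
    from the 5' end of the forward primer to the 3' end of the reverse
    primer binding site, both inclusive."""
    if rev.end < fwd.start:
        raise ValueError(
            f"inverted primer coordinates: forward starts at {fwd.start}, "
            f"reverse ends at {rev.end}"
        )
    return rev.end - fwd.start + 1


def _mismatch_positions(template: str, probe: str, max_mismatch: int) -> list[int]:
    """0-based start positions where probe matches template with at most
    ``max_mismatch`` mismatches (exact matching when 0)."""
    hits = []
    if max_mismatch == 0:
        start = template.find(probe)
        while start != -1:
            hits.append(start)
            start = template.find(probe, start + 1)
        return hits
    k = len(probe)
    for i in range(len(template) - k + 1):
        mm = 0
        window = template[i : i + k]
        for x, y in zip(window, probe):
            if x != y:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            hits.append(i)
    return hits


def predict_amplicon(
    template: SequenceRecord, pair: PrimerPair, max_mismatch: int = 0
) -> tuple[int, Region] | None:
    """Predict the end-point PCR product on a template.

    The forward primer must match the forward strand and the reverse
    primer's reverse complement must occur downstream (strict
    orientation, the gel end-point analogue).  The smallest product is
    reported; ``None`` means no product (marker absent).
    """
    if not pair.forward or not pair.reverse:
        raise ValueError(f"pair {pair.id!r} lacks primer sequences")
    s = template.residues
    fwd_hits = _mismatch_positions(s, pair.forward.upper(), max_mismatch)
    rev_site = reverse_complement(pair.reverse)
    rev_hits = _mismatch_positions(s, rev_site, max_mismatch)
    if not fwd_hits or not rev_hits:
        return None
    best: tuple[int, Region] | None = None
    for f in fwd_hits:
        for r in rev_hits:
            if r < f:  # reverse site must lie downstream of the forward 5' end
                continue
            end = r + len(rev_site)  # 1-based inclusive end
            length = end - f
            if length < max(len(pair.forward), len(rev_site)):
                continue
            if best is None or length < best[0]:
                best = (length, Region(f + 1, end))
    return best


def load_sts_panel(path: str | Path | None = None) -> list[StsMarker]:
    """Load an STS panel TSV: sY_id, locus, multicopy [, primers...]."""
    df = read_table(path if path is not None else default_sts_panel_path())
    markers = [
        StsMarker(
            id=row.sY_id,
            locus=getattr(row, "locus", ""),
            multicopy=str(getattr(row, "multicopy", "")).strip() in ("1", "yes", "true", "*"),
        )
        for row in df.itertuples(index=False)
    ]
    ids = [m.id for m in markers]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker ids in panel")
    return markers


def profile_sts(
    results: Mapping[str, bool | str], panel: Iterable[StsMarker]
) -> StsProfile:
    """Validate a marker->present mapping against a panel.

    Values may be booleans or the gel notation '+'/'-'.  Every panel
    marker must be covered exactly once; extras are rejected.
    """
    panel_ids = [m.id for m in panel]
    missing = set(panel_ids) - set(results)
    if missing:
        raise ValueError(f"profile missing markers: {sorted(missing)}")
    extra = set(results) - set(panel_ids)
    if extra:
        raise ValueError(f"profile has markers outside the panel: {sorted(extra)}")
    status: dict[str, bool] = {}
    for marker in panel_ids:
        v = results[marker]
        if isinstance(v, str):
            if v.strip() not in ("+", "-"):
                raise ValueError(f"marker {marker}: status must be '+'/'-', got {v!r}")
            v = v.strip() == "+"
        status[marker] = bool(v)
    return StsProfile(status=status)


def profile_from_template(
    template: SequenceRecord,
    primer_pairs: Iterable[PrimerPair],
    panel: Iterable[StsMarker],
    max_mismatch: int = 0,
) -> StsProfile:
    """Profile a template by in-silico PCR: a marker is present iff its
    primer pair yields a product."""
    calls = {
        pair.id: predict_amplicon(template, pair, max_mismatch) is not None
        for pair in primer_pairs
    }
    return profile_sts(calls, panel)


def classify_deletions(
    profile: StsProfile, signatures: Iterable[DeletionSignature]
) -> list[str]:
    """All deletion classes whose signature the profile matches,
    sorted by class name; empty when nothing matches (e.g. the
    all-present profile of an intact MSY)."""
    known = set(profile.status)
    calls = []
    for sig in signatures:
        unknown = (sig.absent | sig.flanks) - known
        if unknown:
            raise ValueError(
                f"signature {sig.name!r} references markers outside the "
                f"profile's panel: {sorted(unknown)}"
            )
        if sig.absent <= profile.absent and sig.flanks <= profile.present:
            calls.append(sig.name)
    return sorted(calls)


def default_sts_panel_path() -> Path:
    return Path(str(resources.files("dyz1kit").joinpath("data/sts_panel.tsv")))


def default_signatures_path() -> Path:
    return Path(str(resources.files("dyz1kit").joinpath("data/deletion_signatures.json")))


def load_signatures(path: str | Path | None = None) -> list[DeletionSignature]:
    """Load deletion signatures from JSON:
    [{"class": ..., "absent": [...], "flanks": [...], "comment": ...}]"""
    raw = json.loads(Path(path if path is not None else default_signatures_path()).read_text())
    sigs = []
    for entry in raw:
        sigs.append(
            DeletionSignature(
                name=entry["class"],
                absent=frozenset(entry["absent"]),
                flanks=frozenset(entry.get("flanks", [])),
                comment=entry.get("comment", ""),
            )
        )
    if len({s.name for s in sigs}) != len(sigs):
        raise ValueError("duplicate signature class names")
    return sigs
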