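"""Pentamer decomposition of DYZ1-type satellite arrays.

A DYZ1 HaeIII unit (~3.56 kb) is built almost entirely of in-frame copies
of the pentanucleotide "TTCCA" and mutated derivatives of it.  This module
tiles an array into consecutive pentamers, classifies each tile by its
Hamming distance to the reference motif (0 = exact TTCCA, 1 = single-base
derivative such as GTCCA, ... up to 5), and summarises the tiling as a
spectrum: per-motif counts, aggregate counts per distance class, and the
residue (bases not assigned to any pentamer).

Two segmentation rules are provided:

``fixed-frame``
    Tile from position 1 in steps of 5; the trailing ``L mod 5`` bases are
    residue.  Transparent, but a single indel shifts the frame of every
    downstream tile.

``dynamic`` (default)
    Minimise  sum(Hamming distances of accepted tiles)
            + skip_penalty * (number of unassigned bases)
    by dynamic programming.  With the default ``skip_penalty = 3`` the
    tiling prefers accepting a distance <= 2 pentamer over skipping its
    five bases, but will skip a few bases to re-anchor the frame across an
    indel.  Ties resolve to the segmentation whose first differing
    decision assigns a pentamer rather than a skip (leftmost assignment).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Mapping

from .core_io import Region, SequenceRecord

REFERENCE_MOTIF = "TTCCA"
UNAMBIGUOUS = frozenset("ACGT")

__all__ = [
    "REFERENCE_MOTIF",
    "PentamerClass",
    "SegmentationParams",
    "PentamerSpectrum",
    "classify_pentamer",
    "hamming",
    "segment_array",
    "segmentation_cost",
    "spectrum",
    "compare_spectra",
]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return sum(x != y for x, y in zip(a, b))


@dataclasses.dataclass(frozen=True)
class PentamerClass:
    """A 5-base motif and its Hamming distance to the reference motif."""

    motif: str
    distance: int


def classify_pentamer(motif: str, reference: str = REFERENCE_MOTIF) -> PentamerClass:
    """Classify a pentamer by Hamming distance to the reference motif.

    Ambiguity codes are rejected: satellite units are unambiguous, and a
    distance to an ambiguous base is ill-defined.
    """
    motif = motif.upper()
    if len(motif) != len(reference):
        raise ValueError(f"motif must be {len(reference)} bases, got {motif!r}")
    if set(motif) - UNAMBIGUOUS:
        raise ValueError(f"ambiguous or non-DNA base in motif {motif!r}")
    return PentamerClass(motif=motif, distance=hamming(motif, reference))


@dataclasses.dataclass(frozen=True)
class SegmentationParams:
    """Controls how an array is tiled into pentamers.

    skip_penalty is the cost per unassigned base (dynamic mode);
    max_unit_cost is the largest pentamer distance accepted before the
    tiling prefers skipping those bases instead.
    """

    mode: str = "dynamic"
    skip_penalty: int = 3
    max_unit_cost: int = 5
    reference: str = REFERENCE_MOTIF

    def __post_init__(self) -> None:
        if self.mode not in ("dynamic", "fixed-frame"):
            raise ValueError(f"mode must be dynamic|fixed-frame, got {self.mode!r}")
        if self.skip_penalty <= 0:
            raise ValueError("skip_penalty must be positive")
        if not (0 <= self.max_unit_cost <= len(self.reference)):
            raise ValueError("max_unit_cost out of range")


@dataclasses.dataclass(frozen=True)
class Segmentation:
    """An assignment of a sequence into pentamer tiles and residue bases."""

    units: tuple[tuple[Region, PentamerClass], ...]
    residues: tuple[Region, ...]
    cost: int


def _check_sequence(seq: SequenceRecord, k: int) -> str:
    s = seq.residues
    if len(s) < k:
        raise ValueError(f"sequence shorter than {k} bases")
    if set(s) - UNAMBIGUOUS:
        raise ValueError(f"ambiguity codes not allowed in arrays (record {seq.id!r})")
    return s


def _runs(positions: list[int]) -> list[Region]:
    """Collapse sorted 1-based positions into maximal runs."""
    out: list[Region] = []
    for p in positions:
        if out and out[-1].end == p - 1:
            out[-1] = Region(out[-1].start, p)
        else:
            out.append(Region(p, p))
    return out


def segment_array(seq: SequenceRecord, params: SegmentationParams | None = None) -> Segmentation:
    """Tile an array into pentamers plus residue regions.

    Returns the ordered unit list (1-based regions with their motif
    classes), the residue regions, and the total cost under ``params``.
    """
    params = params or SegmentationParams()
    ref = params.reference
    k = len(ref)
    s = _check_sequence(seq, k)
    n = len(s)

    if params.mode == "fixed-frame":
        units = []
        for i in range(0, n - n % k, k):
            motif = s[i : i + k]
            units.append((Region(i + 1, i + k), PentamerClass(motif, hamming(motif, ref))))
        residues = [Region(n - n % k + 1, n)] if n % k else []
        cost = sum(pc.distance for _, pc in units) + params.skip_penalty * (n % k)
        return Segmentation(tuple(units), tuple(residues), cost)

    # dynamic mode: suffix-cost DP, then a left-to-right walk that takes a
    # pentamer whenever doing so still achieves the optimal suffix cost
    # (leftmost-assignment tie-break).
    dist = [0] * (n - k + 1)
    for i in range(n - k + 1):
        dist[i] = hamming(s[i : i + k], ref)

    INF = float("inf")
    suffix = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        best = params.skip_penalty + suffix[i + 1]
        if i + k <= n and dist[i] <= params.max_unit_cost:
            cand = dist[i] + suffix[i + k]
            if cand < best:
                best = cand
        suffix[i] = best if best < INF else INF

    units = []
    skipped: list[int] = []
    i = 0
    while i < n:
        take = (
            i + k <= n
            and dist[i] <= params.max_unit_cost
            and dist[i] + suffix[i + k] == suffix[i]
        )
        if take:
            motif = s[i : i + k]
            units.append((Region(i + 1, i + k), PentamerClass(motif, dist[i])))
            i += k
        else:
            skipped.append(i + 1)
            i += 1
    return Segmentation(tuple(units), tuple(_runs(skipped)), int(suffix[0]))


def segmentation_cost(seq: SequenceRecord, params: SegmentationParams | None = None) -> int:
    """Total cost of the optimal (or fixed-frame) segmentation."""
    return segment_array(seq, params).cost


@dataclasses.dataclass(frozen=True)
class PentamerSpectrum:
    """Per-motif pentamer counts for one array.

    Invariant: 5 * sum(counts.values()) + residue_bases == total_length.
    ``by_distance[d]`` aggregates counts over all motifs at distance d.
    """

    counts: Mapping[str, int]
    residue_bases: int
    total_length: int
    params: SegmentationParams | None = None

    def __post_init__(self) -> None:
        k = len(self.params.reference) if self.params else 5
        assigned = k * sum(self.counts.values())
        if assigned + self.residue_bases != self.total_length:
            raise ValueError(
                f"length bookkeeping broken: {assigned} assigned + "
                f"{self.residue_bases} residue != {self.total_length}"
            )

    @property
    def by_distance(self) -> dict[int, int]:
        ref = self.params.reference if self.params else REFERENCE_MOTIF
        agg: dict[int, int] = {d: 0 for d in range(len(ref) + 1)}
        for motif, c in self.counts.items():
            agg[hamming(motif, ref)] += c
        return agg


def spectrum(seq: SequenceRecord, params: SegmentationParams | None = None) -> PentamerSpectrum:
    """Segment an array and summarise it as a pentamer spectrum."""
    params = params or SegmentationParams()
    seg = segment_array(seq, params)
    counts = Counter(pc.motif for _, pc in seg.units)
    residue = sum(len(r) for r in seg.residues)
    return PentamerSpectrum(
        counts=dict(counts),
        residue_bases=residue,
        total_length=len(seq),
        params=params,
    )


def compare_spectra(a: PentamerSpectrum, b: PentamerSpectrum) -> dict[str, int]:
    """Per-motif count difference b - a over the union of motifs.

    Antisymmetric: compare_spectra(a, b) == -compare_spectra(b, a).
    Raises if the spectra were built with different parameters.
    """
    if a.params != b.params:
        raise ValueError("spectra built with different segmentation params")
    motifs = set(a.counts) | set(b.counts)
    return {m: b.counts.get(m, 0) - a.counts.get(m, 0) for m in sorted(motifs)}
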