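"""Seeded synthetic-data generators for every input class of the toolkit.

These generators stand in for cell-line DNA: they produce DYZ1-like
satellite arrays with known pentamer composition, sequences with planted
substitutions and indels, qPCR dilution series under an explicit
amplification-efficiency model, and STS panels with planted deletion
classes.  Every generator records its ground truth so that recovery
tests elsewhere need no external data, and every generator is a pure
function of (spec, seed).

Default study conditions: arrays of 712 pentamer units (3560 bases,
the scale of a 3564-base HaeIII unit) with derivative rates mirroring
the published reference-unit spectrum (about 41% single-base
derivatives, 20% two-base, 5% three-base, 1.3% four-base, 0.15%
five-base); qPCR series of six ten-fold dilutions from 2e8 copies in
triplicate at 100% efficiency.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .core_io import SequenceRecord, reverse_complement
from .pentamer import REFERENCE_MOTIF, PentamerSpectrum
from .qpcr import DilutionPoint
from .sts import DeletionSignature, PrimerPair, StsMarker, StsProfile
from .sts import load_signatures, load_sts_panel, profile_sts
from .variants import IndelEvent, VariantTally

BASES = "ACGT"

#: Per-unit probabilities of drawing a derivative at each Hamming
#: distance; the remainder stays an exact reference motif.  Mirrors the
#: published composition of a normal reference unit (292/142/37/9/1
#: derivatives among 710 pentamers).
DEFAULT_DERIVATIVE_RATES: dict[int, float] = {
    1: 292 / 710,
    2: 142 / 710,
    3: 37 / 710,
    4: 9 / 710,
    5: 1 / 710,
}

__all__ = [
    "BASES",
    "DEFAULT_DERIVATIVE_RATES",
    "ArraySpec",
    "VariantPlan",
    "SeriesSpec",
    "StsDataset",
    "generate_array",
    "inject_variants",
    "simulate_dilution_series",
    "generate_sts_dataset",
]


@dataclasses.dataclass(frozen=True)
class ArraySpec:
    """A tandem pentamer array with derivatives drawn at fixed rates."""

    n_units: int = 712
    derivative_rates: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DERIVATIVE_RATES)
    )
    seed: int = 0
    reference: str = REFERENCE_MOTIF

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        rates = dict(self.derivative_rates)
        if any(not (1 <= d <= len(self.reference)) for d in rates):
            raise ValueError("derivative distances must be in 1..motif length")
        if any(r < 0 for r in rates.values()) or sum(rates.values()) > 1 + 1e-12:
            raise ValueError("derivative rates must be >= 0 and sum to <= 1")


def _mutate_motif(motif: str, distance: int, rng: np.random.Generator) -> str:
    """Substitute ``distance`` uniformly chosen positions to uniformly
    chosen *different* bases, so the result is at exactly that Hamming
    distance from ``motif``."""
    positions = rng.choice(len(motif), size=distance, replace=False)
    out = list(motif)
    for p in positions:
        alternatives = [b for b in BASES if b != out[p]]
        out[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def generate_array(spec: ArraySpec) -> tuple[SequenceRecord, PentamerSpectrum]:
    """Generate a tandem pentamer array and its exact truth spectrum.

    The array is a gapless in-frame concatenation of units, so the truth
    spectrum has zero residue bases.
    """
    rng = np.random.default_rng(spec.seed)
    distances = sorted(spec.derivative_rates)
    probs = [spec.derivative_rates[d] for d in distances]
    p0 = 1.0 - sum(probs)
    draw = rng.choice(
        [0] + distances, size=spec.n_units, p=[max(p0, 0.0)] + probs
    )
    units = []
    counts: dict[str, int] = {}
    for d in draw:
        motif = spec.reference if d == 0 else _mutate_motif(spec.reference, int(d), rng)
        units.append(motif)
        counts[motif] = counts.get(motif, 0) + 1
    record = SequenceRecord(
        id=f"synthetic_array_seed{spec.seed}",
        residues="".join(units),
        description=f"synthetic tandem {spec.reference} array, {spec.n_units} units",
    )
    truth = PentamerSpectrum(
        counts=counts,
        residue_bases=0,
        total_length=5 * spec.n_units,
        params=None,
    )
    return record, truth


@dataclasses.dataclass(frozen=True)
class VariantPlan:
    """Planted substitutions plus explicit indel events.

    ``indels`` entries are (kind, position, length) on reference
    coordinates: a deletion removes ``length`` bases starting at
    ``position``; an insertion adds ``length`` random bases immediately
    after ``position``.  All events (including the sampled substitution
    sites) keep at least ``min_event_spacing`` bases apart so that an
    optimal realignment can recover them unambiguously.
    """

    n_substitutions: int = 0
    indels: Sequence[tuple[str, int, int]] = ()
    min_event_spacing: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for kind, pos, length in self.indels:
            if kind not in ("insertion", "deletion"):
                raise ValueError(f"indel kind must be insertion|deletion, got {kind!r}")
            if pos < 1 or length < 1:
                raise ValueError(f"bad indel ({kind}, {pos}, {length})")
        spans = sorted(
            (pos, pos + (length - 1 if kind == "deletion" else 0))
            for kind, pos, length in self.indels
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 - e1 < self.min_event_spacing:
                raise ValueError(
                    f"indel events closer than min_event_spacing: {e1} vs {s2}"
                )


def inject_variants(
    seq: SequenceRecord, plan: VariantPlan
) -> tuple[SequenceRecord, VariantTally]:
    """Apply a variant plan and return the mutated record plus the exact
    truth tally (reference coordinates, events in reference order)."""
    rng = np.random.default_rng(plan.seed)
    n = len(seq)
    for kind, pos, length in plan.indels:
        end = pos + length - 1 if kind == "deletion" else pos
        if end > n:
            raise ValueError(f"indel ({kind}, {pos}, {length}) exceeds length {n}")

    # sample substitution sites away from indels and from each other
    blocked = np.zeros(n + 1, dtype=bool)
    for kind, pos, length in plan.indels:
        end = pos + length - 1 if kind == "deletion" else pos + 1
        lo = max(1, pos - plan.min_event_spacing)
        hi = min(n, end + plan.min_event_spacing)
        blocked[lo : hi + 1] = True
    sub_sites: list[int] = []
    candidates = np.flatnonzero(~blocked[1:]) + 1
    rng.shuffle(candidates)
    for pos in candidates:
        if len(sub_sites) == plan.n_substitutions:
            break
        if all(abs(pos - s) >= plan.min_event_spacing for s in sub_sites):
            sub_sites.append(int(pos))
    if len(sub_sites) < plan.n_substitutions:
        raise ValueError(
            f"cannot place {plan.n_substitutions} substitutions with spacing "
            f"{plan.min_event_spacing} in {n} bases"
        )
    sub_sites.sort()

    residues = list(seq.residues)
    subs: list[tuple[int, str, str]] = []
    for pos in sub_sites:
        ref = residues[pos - 1]
        alt = [b for b in BASES if b != ref][rng.integers(3)]
        residues[pos - 1] = alt
        subs.append((pos, ref, alt))

    # apply indels right-to-left so reference coordinates stay valid
    events = []
    for kind, pos, length in sorted(plan.indels, key=lambda e: -e[1]):
        if kind == "deletion":
            del residues[pos - 1 : pos - 1 + length]
        else:
            insert = "".join(BASES[i] for i in rng.integers(4, size=length))
            residues[pos:pos] = list(insert)
        events.append(IndelEvent(kind, pos, length))
    events.sort(key=lambda e: e.ref_position)

    mutated = SequenceRecord(
        id=f"{seq.id}_variant_seed{plan.seed}",
        residues="".join(residues),
        description=f"synthetic variant of {seq.id}",
    )
    truth = VariantTally(
        substitutions=len(subs),
        substitution_sites=tuple(subs),
        indels=tuple(events),
    )
    return mutated, truth


@dataclasses.dataclass(frozen=True)
class SeriesSpec:
    """A qPCR dilution series under the constant-efficiency model

    ct = ct_at_1_copy - log(copies)/log(1 + efficiency) + N(0, noise_sd).
    """

    start_copies: float = 2e8
    dilution_factor: float = 10.0
    n_levels: int = 6
    replicates: int = 3
    efficiency: float = 1.0
    ct_at_1_copy: float = 40.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.efficiency <= 0:
            raise ValueError("efficiency must be > 0")
        if self.n_levels < 1 or self.replicates < 1:
            raise ValueError("n_levels and replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def true_ct(copies: float, spec: SeriesSpec) -> float:
    """Noise-free Ct implied by the series' efficiency model."""
    return spec.ct_at_1_copy - np.log(copies) / np.log(1.0 + spec.efficiency)


def simulate_dilution_series(spec: SeriesSpec) -> list[DilutionPoint]:
    """Simulate Ct values for a dilution series (seeded, reproducible)."""
    rng = np.random.default_rng(spec.seed)
    points = []
    for level in range(spec.n_levels):
        copies = spec.start_copies / spec.dilution_factor**level
        for rep in range(spec.replicates):
            noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            points.append(
                DilutionPoint(
                    known_copies=copies,
                    ct=float(true_ct(copies, spec) + noise),
                    replicate=f"L{level + 1}R{rep + 1}",
                )
            )
    return points


@dataclasses.dataclass(frozen=True)
class StsDataset:
    """A planted STS dataset: the profile, per-marker synthetic primer
    pairs, and (optionally) a mock template carrying the present loci."""

    profile: StsProfile
    primer_pairs: tuple[PrimerPair, ...]
    template: SequenceRecord | None = None


def _random_primer(rng: np.random.Generator, length: int = 20) -> str:
    return "".join(BASES[i] for i in rng.integers(4, size=length))


def generate_sts_dataset(
    class_name: str,
    signatures: Sequence[DeletionSignature] | None = None,
    panel: Sequence[StsMarker] | None = None,
    seed: int = 0,
    with_template: bool = False,
    locus_spacing: int = 60,
    amplicon_insert: int = 100,
) -> StsDataset:
    """Plant one deletion class into a synthetic STS dataset.

    The profile is absent exactly at the class's ``absent`` markers (the
    reserved class name ``"none"`` yields the all-present profile of an
    intact MSY).  With ``with_template`` a mock linear template is built
    by concatenating, for each *present* marker, a synthetic locus
    ``forward-primer + insert + reverse-complement(reverse-primer)``
    separated by random linker sequence; absent markers' loci are left
    out, so in-silico PCR on the template reproduces the profile.
    """
    signatures = list(signatures) if signatures is not None else load_signatures()
    panel = list(panel) if panel is not None else load_sts_panel()
    if class_name == "none":
        absent: frozenset[str] = frozenset()
    else:
        by_name = {s.name: s for s in signatures}
        if class_name not in by_name:
            raise ValueError(
                f"unknown deletion class {class_name!r}; have {sorted(by_name)} or 'none'"
            )
        absent = by_name[class_name].absent
    profile = profile_sts({m.id: m.id not in absent for m in panel}, panel)

    rng = np.random.default_rng(seed)
    pairs = []
    chunks = []
    for marker in panel:
        fwd = _random_primer(rng)
        rev = _random_primer(rng)
        pairs.append(PrimerPair(id=marker.id, forward=fwd, reverse=rev))
        if with_template and marker.id not in absent:
            insert = _random_primer(rng, amplicon_insert)
            linker = _random_primer(rng, locus_spacing)
            chunks.append(linker + fwd + insert + reverse_complement(rev))
    template = None
    if with_template:
        chunks.append(_random_primer(rng, locus_spacing))
        template = SequenceRecord(
            id=f"synthetic_msy_mock_{class_name}_seed{seed}",
            residues="".join(chunks),
            description=f"synthetic MSY mock with planted class {class_name!r}",
        )
    return StsDataset(profile=profile, primer_pairs=tuple(pairs), template=template)
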