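"""IUPAC-aware restriction-site scanning, virtual digestion and PCR-RFLP.

Site counting convention (documented because published "virtual digest"
frequencies rarely state one): a hit is an occurrence of the recognition
sequence; overlapping occurrences all count; palindromic recognition
sites (IUPAC-aware reverse complement equals the pattern) are counted
once per double-stranded site; non-palindromic patterns are additionally
sought on the reverse strand and reported at their forward-strand start
coordinate with ``strand='reverse'``.

Cut geometry: ``cut_top`` is the number of bases from the 5' end of the
recognition sequence (on the strand that carries it) to the top-strand
cut; ``cut_bottom`` analogously for the bottom strand.  Type IIS enzymes
cutting outside the recognition site have offsets beyond the pattern
length (or are left without offsets in the shipped panel, which disables
fragmentation but not site counting).
"""

from __future__ import annotations

import dataclasses
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .core_io import SequenceRecord, read_table, reverse_complement

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

__all__ = [
    "EnzymeSpec",
    "SiteHit",
    "DigestSummary",
    "FragmentSet",
    "compile_iupac",
    "find_sites",
    "site_frequency_table",
    "compare_frequencies",
    "digest_fragments",
    "predict_rflp",
    "load_enzyme_panel",
    "default_panel_path",
]


def compile_iupac(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC recognition pattern to a regex matching all
    (and only) its concrete expansions, with overlapping matches found
    via a lookahead group."""
    if not pattern:
        raise ValueError("empty recognition pattern")
    parts = []
    for letter in pattern.upper():
        try:
            bases = IUPAC_CODES[letter]
        except KeyError:
            raise ValueError(f"illegal IUPAC letter {letter!r} in pattern {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?=({''.join(parts)}))")


@dataclasses.dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition pattern plus cut geometry.

    ``site_length`` (informative, non-N bases) is derived from the
    pattern; ``overhang`` is blunt | 5' | 3'.  Cut offsets are optional:
    without them an enzyme can be counted but not used to fragment.
    """

    name: str
    recognition: str
    overhang: str = "blunt"
    cut_top: int | None = None
    cut_bottom: int | None = None

    def __post_init__(self) -> None:
        compile_iupac(self.recognition)  # validates letters
        object.__setattr__(self, "recognition", self.recognition.upper())
        if self.overhang not in ("blunt", "5'", "3'"):
            raise ValueError(f"overhang must be blunt|5'|3', got {self.overhang!r}")

    @property
    def site_length(self) -> int:
        return sum(1 for c in self.recognition if c != "N")

    @property
    def palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition

    @property
    def can_fragment(self) -> bool:
        return self.cut_top is not None


@dataclasses.dataclass(frozen=True)
class SiteHit:
    enzyme: str
    position: int  # 1-based start of the occurrence on the forward strand
    strand: str = "forward"


def find_sites(
    seq: SequenceRecord, enzyme: EnzymeSpec, both_strands: bool = True
) -> list[SiteHit]:
    """All recognition-site occurrences, sorted by forward-strand position.

    Palindromic sites are counted once per double-stranded site even when
    ``both_strands`` is set.
    """
    s = seq.residues
    hits = [
        SiteHit(enzyme.name, m.start() + 1, "forward")
        for m in compile_iupac(enzyme.recognition).finditer(s)
    ]
    if both_strands and not enzyme.palindromic:
        rc = compile_iupac(reverse_complement(enzyme.recognition))
        hits += [SiteHit(enzyme.name, m.start() + 1, "reverse") for m in rc.finditer(s)]
    return sorted(hits, key=lambda h: (h.position, h.strand))


def site_frequency_table(
    seq: SequenceRecord, panel: Iterable[EnzymeSpec], both_strands: bool = True
) -> dict[str, int]:
    """Per-enzyme site counts over a panel (zero counts included)."""
    panel = list(panel)
    if not panel:
        raise ValueError("empty enzyme panel")
    names = [e.name for e in panel]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate enzyme names in panel: {dupes}")
    return {e.name: len(find_sites(seq, e, both_strands)) for e in panel}


@dataclasses.dataclass(frozen=True)
class DigestSummary:
    """Lost / gained / changed enzymes between two frequency tables.

    lost: >=1 site in reference, 0 in sample; gained: the converse;
    changed: nonzero in both but with different counts.
    """

    reference: Mapping[str, int]
    sample: Mapping[str, int]
    lost: frozenset[str]
    gained: frozenset[str]
    changed: frozenset[str]


def compare_frequencies(ref: Mapping[str, int], sample: Mapping[str, int]) -> DigestSummary:
    if set(ref) != set(sample):
        raise ValueError(
            f"enzyme panels differ: {sorted(set(ref) ^ set(sample))}"
        )
    lost = frozenset(e for e in ref if ref[e] >= 1 and sample[e] == 0)
    gained = frozenset(e for e in ref if ref[e] == 0 and sample[e] >= 1)
    changed = frozenset(
        e for e in ref if ref[e] > 0 and sample[e] > 0 and ref[e] != sample[e]
    )
    return DigestSummary(dict(ref), dict(sample), lost, gained, changed)


@dataclasses.dataclass(frozen=True)
class FragmentSet:
    """Ordered fragment lengths of a linear digestion product."""

    fragments: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.fragments)


def _top_strand_cuts(seq_len: int, enzyme: EnzymeSpec, hits: Iterable[SiteHit]) -> list[int]:
    """Top-strand cut positions (0-based, 'cut after this many bases').

    For a reverse-strand hit the recognition reads 3'->5' on the top
    strand, so the enzyme's bottom-strand offset, mirrored about the site
    end, gives the top-strand cut.  Cuts falling outside the molecule are
    dropped (the recognition hit still counts towards frequencies).
    """
    L = len(enzyme.recognition)
    cut_bottom = enzyme.cut_bottom if enzyme.cut_bottom is not None else enzyme.cut_top
    cuts = set()
    for h in hits:
        if h.strand == "forward":
            pos = (h.position - 1) + enzyme.cut_top
        else:
            pos = (h.position - 1 + L) - cut_bottom
        if 0 < pos < seq_len:
            cuts.add(pos)
    return sorted(cuts)


def digest_fragments(seq: SequenceRecord, enzyme: EnzymeSpec) -> FragmentSet:
    """Fragment lengths of the linear molecule, in molecule order.

    Always conserves length: sum(fragments) == len(seq).
    """
    if not enzyme.can_fragment:
        raise NotImplementedError(
            f"enzyme {enzyme.name} has no cut offsets; counting only"
        )
    cuts = _top_strand_cuts(len(seq), enzyme, find_sites(seq, enzyme))
    bounds = [0] + cuts + [len(seq)]
    return FragmentSet(tuple(b - a for a, b in zip(bounds, bounds[1:])))


def predict_rflp(amplicon: SequenceRecord, enzyme: EnzymeSpec) -> tuple[str, FragmentSet]:
    """PCR-RFLP allele call: 'cut' with the fragment pattern, or 'uncut'
    with the full-length fragment when the amplicon has no site."""
    frags = digest_fragments(amplicon, enzyme)
    call = "cut" if len(frags.fragments) > 1 else "uncut"
    return call, frags


def default_panel_path() -> Path:
    """Path of the bundled virtual-digest enzyme panel (editable TSV)."""
    return Path(str(resources.files("dyz1kit").joinpath("data/enzyme_panel.tsv")))


def load_enzyme_panel(path: str | Path | None = None) -> list[EnzymeSpec]:
    """Load an enzyme panel TSV: name, recognition, overhang, cut_top,
    cut_bottom (offsets optional)."""
    df = read_table(path if path is not None else default_panel_path())
    required = {"name", "recognition", "overhang"}
    if not required <= set(df.columns):
        raise ValueError(f"panel is missing columns {sorted(required - set(df.columns))}")
    panel = []
    for row in df.itertuples(index=False):
        cut_top = getattr(row, "cut_top", "")
        cut_bottom = getattr(row, "cut_bottom", "")
        panel.append(
            EnzymeSpec(
                name=row.name,
                recognition=row.recognition,
                overhang=row.overhang,
                cut_top=int(cut_top) if str(cut_top).strip() else None,
                cut_bottom=int(cut_bottom) if str(cut_bottom).strip() else None,
            )
        )
    return panel
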