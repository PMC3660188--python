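"""Pairwise global alignment and substitution / indel tallying.

The alignment is Needleman–Wunsch with affine gap costs, maximised over
three layers (match/mismatch, gap-in-second-sequence, gap-in-first).  A
gap of length k costs ``gap_open + (k - 1) * gap_extend``.  Default
scores (match +1, mismatch -1, open -5, extend -1) make multi-base
indels align as single runs rather than scattered gaps, which is what
the event tally needs.  Traceback is deterministic: at equal score the
diagonal move is preferred, then a gap in the second sequence, then a
gap in the first.

Tallying treats the first sequence of a pair as the reference:
substitutions are aligned columns with two differing bases (a gapped
column is never a substitution); one maximal run of gap columns is one
indel event, located on reference coordinates; the net length change is
the signed sum of event lengths (+insertions, -deletions) and always
equals ``len(b) - len(a)``.

Alignments may also be ingested from CLUSTAL / aligned-FASTA files
(e.g. a published multiple alignment); ingested alignments are
authoritative for reproducing published counts, since a re-computed
optimal alignment can legitimately differ in repetitive satellite DNA.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import GappedRecord, SequenceRecord

NEG = np.float32(-1e9)

__all__ = [
    "AlignmentScores",
    "AlignedPair",
    "VariantTally",
    "IndelEvent",
    "align_global",
    "pair_from_rows",
    "tally_from_alignment",
    "net_length",
]


@dataclasses.dataclass(frozen=True)
class AlignmentScores:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclasses.dataclass(frozen=True)
class AlignedPair:
    """Two gapped rows of equal aligned length over {A,C,G,T,-}."""

    a: str
    b: str
    source: str = "computed"
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("aligned rows have unequal length")
        if not self.a:
            raise ValueError("empty alignment")
        for x, y in zip(self.a, self.b):
            if x == "-" and y == "-":
                raise ValueError("column with gaps in both rows")


def pair_from_rows(rows: list[GappedRecord], a_id: str | None = None, b_id: str | None = None) -> AlignedPair:
    """Build an AlignedPair from two rows of an ingested alignment.

    With ids given, picks those rows; otherwise takes the first two.
    Columns gapped in both selected rows (possible when extracting a
    pair from a larger multiple alignment) are dropped.
    """
    by_id = {r.id: r for r in rows}
    if a_id is not None or b_id is not None:
        try:
            ra, rb = by_id[a_id], by_id[b_id]
        except KeyError as exc:
            raise ValueError(f"row {exc} not in alignment (have {sorted(by_id)})")
    else:
        if len(rows) < 2:
            raise ValueError("alignment has fewer than two rows")
        ra, rb = rows[0], rows[1]
    cols = [(x, y) for x, y in zip(ra.residues, rb.residues) if not (x == "-" and y == "-")]
    return AlignedPair("".join(x for x, _ in cols), "".join(y for _, y in cols), source="ingested")


def align_global(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scores: AlignmentScores | None = None,
) -> AlignedPair:
    """Optimal global alignment of two unambiguous DNA sequences."""
    scores = scores or AlignmentScores()
    sa = a.residues if isinstance(a, SequenceRecord) else a.upper()
    sb = b.residues if isinstance(b, SequenceRecord) else b.upper()
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")
    n, m = len(sa), len(sb)
    open_, ext = np.float32(scores.gap_open), np.float32(scores.gap_extend)

    av = np.frombuffer(sa.encode(), dtype=np.uint8)
    bv = np.frombuffer(sb.encode(), dtype=np.uint8)

    M = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in b (consumes a)
    M[0, 0] = 0.0
    j = np.arange(1, m + 1, dtype=np.float32)
    E[0, 1:] = open_ + (j - 1) * ext
    i_idx = np.arange(1, n + 1, dtype=np.float32)
    F[1:, 0] = open_ + (i_idx - 1) * ext

    ext_ramp = np.arange(m, dtype=np.float32) * ext  # k * ext for k = 0..m-1
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], np.float32(scores.match), np.float32(scores.mismatch))
        prev_best = np.maximum(np.maximum(M[i - 1], E[i - 1]), F[i - 1])
        M[i, 1:] = sub + prev_best[:-1]
        F[i] = np.maximum(
            np.maximum(M[i - 1] + open_, E[i - 1] + open_), F[i - 1] + ext
        )
        if i == 1:
            F[1, 0] = open_  # boundary column is a pure gap run
        # E scan: E[j] = max_{k<j} (H[k] + open + (j-1-k)*ext), H = max(M, F)
        H = np.maximum(M[i], F[i])
        A = H[:-1] - ext_ramp  # H[k] - k*ext
        P = np.maximum.accumulate(A)
        E[i, 1:] = P + open_ + ext_ramp
        E[i, 0] = NEG
    # F boundary re-fix (row loop overwrote column 0)
    F[1:, 0] = open_ + (i_idx - 1) * ext
    M[1:, 0] = NEG
    E[1:, 0] = NEG

    # traceback; preference at ties: diagonal (M), gap in b (F), gap in a (E)
    TOL = np.float32(1e-3)

    def pick(i: int, j: int) -> str:
        vals = {"M": M[i, j], "F": F[i, j], "E": E[i, j]}
        best = max(vals.values())
        for layer in ("M", "F", "E"):
            if vals[layer] >= best - TOL:
                return layer
        raise AssertionError

    out_a: list[str] = []
    out_b: list[str] = []
    i_, j_ = n, m
    layer = pick(n, m)
    final = float(max(M[n, m], E[n, m], F[n, m]))
    while i_ > 0 or j_ > 0:
        if layer == "M":
            out_a.append(sa[i_ - 1])
            out_b.append(sb[j_ - 1])
            i_, j_ = i_ - 1, j_ - 1
            layer = "M" if (i_ == 0 and j_ == 0) else pick(i_, j_)
        elif layer == "F":
            out_a.append(sa[i_ - 1])
            out_b.append("-")
            target = F[i_, j_]
            prev = (
                "M" if M[i_ - 1, j_] + open_ >= target - TOL
                else "F" if F[i_ - 1, j_] + ext >= target - TOL
                else "E"
            )
            i_ -= 1
            layer = prev
        else:  # E
            out_a.append("-")
            out_b.append(sb[j_ - 1])
            target = E[i_, j_]
            prev = (
                "M" if M[i_, j_ - 1] + open_ >= target - TOL
                else "F" if F[i_, j_ - 1] + open_ >= target - TOL
                else "E"
            )
            j_ -= 1
            layer = prev
    return AlignedPair("".join(reversed(out_a)), "".join(reversed(out_b)), score=final)


@dataclasses.dataclass(frozen=True)
class IndelEvent:
    """One merged gap run, located on the first (reference) sequence.

    For a deletion, ``ref_position`` is the first deleted reference
    base; for an insertion, the reference base immediately left of the
    insertion point (0 when inserted before the first base).
    """

    kind: str  # "insertion" | "deletion" relative to the first sequence
    ref_position: int
    length: int


@dataclasses.dataclass(frozen=True)
class VariantTally:
    substitutions: int
    substitution_sites: tuple[tuple[int, str, str], ...]  # (ref pos, ref, alt)
    indels: tuple[IndelEvent, ...]

    @property
    def net_length_change(self) -> int:
        return sum(e.length if e.kind == "insertion" else -e.length for e in self.indels)


def tally_from_alignment(aln: AlignedPair) -> VariantTally:
    """Count substitutions and merged indel events of b relative to a."""
    subs: list[tuple[int, str, str]] = []
    events: list[IndelEvent] = []
    ref_pos = 0
    run_kind: str | None = None
    run_len = 0
    run_ref = 0

    def flush() -> None:
        nonlocal run_kind, run_len
        if run_kind is not None:
            events.append(IndelEvent(run_kind, run_ref, run_len))
        run_kind, run_len = None, 0

    for x, y in zip(aln.a, aln.b):
        if x != "-" and y != "-":
            flush()
            ref_pos += 1
            if x != y:
                subs.append((ref_pos, x, y))
        elif y == "-":  # deletion from reference
            if run_kind != "deletion":
                flush()
                run_kind, run_ref = "deletion", ref_pos + 1
            run_len += 1
            ref_pos += 1
        else:  # insertion relative to reference
            if run_kind != "insertion":
                flush()
                run_kind, run_ref = "insertion", ref_pos
            run_len += 1
    flush()
    return VariantTally(
        substitutions=len(subs),
        substitution_sites=tuple(subs),
        indels=tuple(events),
    )


def net_length(tally: VariantTally) -> int:
    """Signed net length change (+insertions, -deletions)."""
    return tally.net_length_change
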