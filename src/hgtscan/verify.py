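"""Genomic-integration verification by exact 25 bp fragment matching.

Zero-mismatch alignment of k-mers is exactly substring search, so the
verification step is specified as such: each read is divided into
consecutive non-overlapping k bp fragments and every exact occurrence of a
fragment (forward or reverse complement) in the transcript set is reported.
A transcript is "verified" as genomically integrated when at least one
gDNA-read fragment hits it (``min_hits`` configurable).

Intron detection follows split-read logic: a gDNA read whose early
fragments map at one transcript offset and later fragments at a smaller
offset spans an insertion in the genomic copy.  The two k-mer-anchored
flanks are extended base-by-base (still zero mismatches) to the junction;
within the residual ambiguity window the junction satisfying the canonical
GT donor / AG acceptor motifs is preferred.  Reads entering an intron from
one side only yield partial calls whose unobserved end is undecidable.

Parasite-host sequence divergence uses global alignment (match +1,
mismatch -1, gap -2) with divergence = mismatched columns over aligned
non-gap columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .errors import ValidationError
from .io import SequenceRecord

__all__ = [
    "FragmentHit",
    "IntronCall",
    "FragmentIndex",
    "fragment_read",
    "reverse_complement",
    "map_fragments",
    "map_read",
    "verify_transcripts",
    "detect_introns",
    "pairwise_divergence",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fragment_read(read: SequenceRecord | str, k: int) -> list[str]:
    """Consecutive non-overlapping k-mers from position 0; a trailing
    remainder shorter than k is discarded (a 150 bp read at k=25 gives 6)."""
    if k < 1:
        raise ValidationError("fragment size k must be >= 1")
    seq = read if isinstance(read, str) else read.seq
    return [seq[i : i + k] for i in range(0, len(seq) - k + 1, k)]


@dataclass(frozen=True)
class FragmentHit:
    read_id: str
    fragment_index: int
    transcript_id: str
    offset: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class IntronCall:
    transcript_id: str
    read_id: str
    junction: int  # cDNA position of the first base after the junction
    gap: str  # observed intron sequence (possibly partial)
    donor_motif_ok: bool | None  # None when the donor end is unobserved
    acceptor_motif_ok: bool | None
    complete: bool


class FragmentIndex:
    """Exact k-mer index over a transcript set."""

    def __init__(self, transcripts: Iterable[SequenceRecord], k: int):
        if k < 1:
            raise ValidationError("fragment size k must be >= 1")
        self.k = k
        self.transcripts: dict[str, str] = {}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for rec in transcripts:
            if rec.id in self.transcripts:
                raise ValidationError(f"duplicate transcript id {rec.id!r}")
            self.transcripts[rec.id] = rec.seq
            for off in range(len(rec.seq) - k + 1):
                kmer = rec.seq[off : off + k]
                self._index.setdefault(kmer, []).append((rec.id, off))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def map_fragments(
    read: SequenceRecord, index: FragmentIndex
) -> list[FragmentHit]:
    """Every exact occurrence (both strands) of each fragment of ``read``.

    Equivalent by contract to a brute-force substring scan of each fragment
    and its reverse complement against every transcript.
    """
    hits: list[FragmentHit] = []
    for i, frag in enumerate(fragment_read(read, index.k)):
        for tid, off in index.lookup(frag):
            hits.append(FragmentHit(read.id, i, tid, off, "+"))
        for tid, off in index.lookup(reverse_complement(frag)):
            hits.append(FragmentHit(read.id, i, tid, off, "-"))
    return hits


def map_read(read: SequenceRecord, index: FragmentIndex) -> list[FragmentHit]:
    return map_fragments(read, index)


def verify_transcripts(
    transcript_ids: Sequence[str],
    gdna_reads: Iterable[SequenceRecord],
    index: FragmentIndex,
    min_hits: int = 1,
) -> dict[str, int]:
    """gDNA fragment-hit counts per transcript; a transcript is verified
    when its count reaches ``min_hits`` (default: one exact hit)."""
    counts = {tid: 0 for tid in transcript_ids}
    for tid in transcript_ids:
        if tid not in index.transcripts:
            raise ValidationError(f"unknown transcript id {tid!r}")
    for read in gdna_reads:
        for hit in map_fragments(read, index):
            if hit.transcript_id in counts:
                counts[hit.transcript_id] += 1
    return counts


def is_verified(counts: Mapping[str, int], tid: str, min_hits: int = 1) -> bool:
    return counts[tid] >= min_hits


# ---------------------------------------------------------------------------
# Intron detection


#: how far a partial call's junction may be shifted to honour the GT/AG
#: motif when chance matches blur the exact-extension boundary
_MOTIF_BACKTRACK = 8


def _extend_right(read: str, tx: str, start: int, c: int) -> int:
    """First read position >= start where read and transcript (at offset c)
    disagree or run out."""
    r = start
    while r < len(read) and 0 <= r + c < len(tx) and read[r] == tx[r + c]:
        r += 1
    return r


def _extend_left(read: str, tx: str, end: int, c: int) -> int:
    """Smallest read position p <= end such that read[p:end] matches the
    transcript at offset c."""
    p = end
    while p > 0 and 0 <= p - 1 + c < len(tx) and read[p - 1] == tx[p - 1 + c]:
        p -= 1
    return p


def _refine_junction(read: str, p1: int, p2: int, intron_len: int) -> int:
    """Choose the intron start within the exact-match ambiguity window
    [p2 - intron_len, p1], preferring a GT..AG-consistent placement."""
    lo = max(0, p2 - intron_len)
    hi = min(p1, len(read) - intron_len)
    for a in range(lo, hi + 1):
        gap = read[a : a + intron_len]
        if gap.startswith("GT") and gap.endswith("AG"):
            return a
    return hi


def _detect_one_strand(
    read_id: str, read: str, tid: str, tx: str, k: int
) -> list[IntronCall]:
    # group mapped fragments of this read on this transcript by their
    # implied read-to-transcript offset c = transcript_pos - read_pos
    by_offset: dict[int, list[int]] = {}
    for i in range(0, len(read) - k + 1, k):
        frag = read[i : i + k]
        pos = tx.find(frag)
        while pos != -1:
            by_offset.setdefault(pos - i, []).append(i)
            pos = tx.find(frag, pos + 1)
    if not by_offset:
        return []
    calls: list[IntronCall] = []
    offsets = sorted(by_offset, reverse=True)  # prefix offset > suffix offset
    # complete calls: a prefix run at c1 and a suffix run at smaller c2
    for c1 in offsets:
        for c2 in offsets:
            intron_len = c1 - c2
            if intron_len <= 0:
                continue
            if max(by_offset[c1]) >= min(by_offset[c2]):
                continue
            p1 = _extend_right(read, tx, max(by_offset[c1]) + k, c1)
            p2 = _extend_left(read, tx, min(by_offset[c2]), c2)
            if p1 < p2 - intron_len:  # flanks do not meet: not a clean splice
                continue
            a = _refine_junction(read, p1, p2, intron_len)
            gap = read[a : a + intron_len]
            calls.append(
                IntronCall(
                    transcript_id=tid,
                    read_id=read_id,
                    junction=a + c1,
                    gap=gap,
                    donor_motif_ok=gap.startswith("GT"),
                    acceptor_motif_ok=gap.endswith("AG"),
                    complete=True,
                )
            )
    if calls:
        return calls
    # partial calls: a single anchored flank with unmapped read sequence
    # running off into the (uncovered) intron
    if len(offsets) == 1:
        c = offsets[0]
        p1 = _extend_right(read, tx, max(by_offset[c]) + k, c)
        p2 = _extend_left(read, tx, min(by_offset[c]), c)
        if p1 < len(read) and 0 < p1 + c < len(tx):
            # chance matches can carry the extension a few bases into the
            # intron; prefer the nearest consistent GT donor placement
            for back in range(_MOTIF_BACKTRACK):
                a = p1 - back
                if a >= 2 and read[a : a + 2] == "GT":
                    p1 = a
                    break
            gap = read[p1:]
            calls.append(
                IntronCall(
                    transcript_id=tid,
                    read_id=read_id,
                    junction=p1 + c,
                    gap=gap,
                    donor_motif_ok=gap.startswith("GT"),
                    acceptor_motif_ok=None,
                    complete=False,
                )
            )
        if p2 > 0 and 0 < p2 + c < len(tx):
            for fwd in range(_MOTIF_BACKTRACK):
                a = p2 + fwd
                if a <= len(read) - 2 and read[a - 2 : a] == "AG":
                    p2 = a
                    break
            gap = read[:p2]
            calls.append(
                IntronCall(
                    transcript_id=tid,
                    read_id=read_id,
                    junction=p2 + c,
                    gap=gap,
                    donor_motif_ok=None,
                    acceptor_motif_ok=gap.endswith("AG"),
                    complete=False,
                )
            )
    return calls


def detect_introns(
    read: SequenceRecord, index: FragmentIndex
) -> list[IntronCall]:
    """Split-read intron calls for one gDNA read against the transcript set.

    A read lying entirely within one exon produces no call; a read spanning
    an insertion with a mapped flank on each side produces a complete call
    with the full intron sequence; a read covering only one end of an
    insertion produces a partial call whose far motif flag is ``None``.
    """
    k = index.k
    calls: list[IntronCall] = []
    for seq in (read.seq, reverse_complement(read.seq)):
        tids = set()
        for frag in fragment_read(seq, k):
            for tid, _ in index.lookup(frag):
                tids.add(tid)
        for tid in sorted(tids):
            calls.extend(
                _detect_one_strand(read.id, seq, tid, index.transcripts[tid], k)
            )
    return calls


# ---------------------------------------------------------------------------
# Divergence

_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def pairwise_divergence(
    seq_a: SequenceRecord | str, seq_b: SequenceRecord | str
) -> float:
    """Percent divergence from a global alignment: mismatched columns over
    aligned non-gap columns, times 100."""
    a = seq_a if isinstance(seq_a, str) else seq_a.seq
    b = seq_b if isinstance(seq_b, str) else seq_b.seq
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    alignment = _ALIGNER.align(a, b)[0]
    mism = 0
    cols = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        cols += a1 - a0
        mism += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x != y)
    if cols == 0:
        return 100.0
    return 100.0 * mism / cols


def alignment_score(seq_a: str, seq_b: str) -> float:
    """Optimal global alignment score under the divergence scoring scheme
    (exposed for cross-checking)."""
    return float(_ALIGNER.score(seq_a, seq_b))
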