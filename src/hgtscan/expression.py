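"""Per-transcript expression from cDNA reads.

A read counts toward a transcript when at least one of its k bp fragments
matches the transcript exactly (the same zero-mismatch machinery as the
genomic verification stage); a multi-mapping read counts once per matched
transcript.  Counts are normalized two ways:

* the study's window normalization R = N / (L - k + 1 + l - k), where N is
  the mapped-read count, L the transcript length, k the minimum overlap
  (default 25) and l the read length used in the mapping (default 25);
* standard RPKM = 1e9 * N / (L * total mapped reads).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .classify import TranscriptClassification
from .errors import ValidationError
from .io import SequenceRecord
from .verify import FragmentIndex, map_fragments

__all__ = [
    "ExpressionRecord",
    "count_mapped_reads",
    "eq1_normalize",
    "rpkm",
    "build_expression_records",
    "compare_expression",
]


@dataclass
class ExpressionRecord:
    transcript_id: str
    N: int
    L: int
    k: int = 25
    l: int = 25
    R: float = 0.0
    RPKM: float = 0.0


def count_mapped_reads(
    cdna_reads: Iterable[SequenceRecord],
    index: FragmentIndex,
) -> dict[str, int]:
    """Mapped-read count N per transcript (>=1 exact fragment hit; a read
    hitting several transcripts increments each once)."""
    counts = {tid: 0 for tid in index.transcripts}
    for read in cdna_reads:
        hit_tids = {h.transcript_id for h in map_fragments(read, index)}
        for tid in hit_tids:
            counts[tid] += 1
    return counts


def eq1_normalize(N: int, L: int, k: int = 25, l: int = 25) -> float:
    """The window normalization R = N / (L - k + 1 + l - k)."""
    if N < 0:
        raise ValidationError("read count N must be non-negative")
    denom = L - k + 1 + l - k
    if denom < 1:
        raise ValidationError(
            f"non-positive denominator for L={L}, k={k}, l={l}"
        )
    return N / denom


def rpkm(records: Sequence[ExpressionRecord]) -> list[ExpressionRecord]:
    """Fill RPKM = 1e9 * N / (L * total N) in place; returns the records."""
    total = sum(r.N for r in records)
    if total <= 0:
        raise ValidationError("RPKM undefined: no mapped reads in the library")
    for r in records:
        r.RPKM = 1e9 * r.N / (r.L * total)
    return list(records)


def build_expression_records(
    transcripts: Sequence[SequenceRecord],
    cdna_reads: Iterable[SequenceRecord],
    k: int = 25,
    l: int = 25,
) -> list[ExpressionRecord]:
    """Count, window-normalize and RPKM-normalize in one pass."""
    index = FragmentIndex(transcripts, k)
    counts = count_mapped_reads(cdna_reads, index)
    records = [
        ExpressionRecord(
            transcript_id=t.id,
            N=counts[t.id],
            L=len(t.seq),
            k=k,
            l=l,
            R=eq1_normalize(counts[t.id], len(t.seq), k, l),
        )
        for t in transcripts
    ]
    if sum(r.N for r in records) > 0:
        rpkm(records)
    return records


def compare_expression(
    records: Sequence[ExpressionRecord],
    classifications: Sequence[TranscriptClassification],
) -> dict:
    """Boxplot-style summaries of RPKM per category plus Welch's test on
    log-scale RPKM (HGT vs VGT).  Categories with <2 members are skipped."""
    from .rates import welch_t_test  # local import avoids a cycle

    cat = {c.transcript_id: c.category for c in classifications}
    groups: dict[str, list[float]] = {"VGT": [], "HGT": []}
    for r in records:
        c = cat.get(r.transcript_id)
        if c in groups:
            groups[c].append(r.RPKM)
    report: dict = {"groups": {}, "skipped": []}
    for name, vals in groups.items():
        if not vals:
            continue
        arr = np.asarray(vals)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        report["groups"][name] = {
            "n": int(arr.size),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
        }
    expressed = {
        name: [np.log10(v) for v in vals if v > 0] for name, vals in groups.items()
    }
    if len(expressed["HGT"]) >= 2 and len(expressed["VGT"]) >= 2:
        t, df, p = welch_t_test(expressed["HGT"], expressed["VGT"])
        report["test"] = {"t": t, "df": df, "p": p, "scale": "log10 RPKM"}
    else:
        report["skipped"].append("hgt_vs_vgt expression: a category has <2 members")
    return report
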