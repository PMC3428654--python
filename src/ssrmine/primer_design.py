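"""Primer-pair enumeration and constraint filtering around SSR loci.

Candidates are exhaustively enumerated in the flanks of a locus and kept
only if they satisfy the marker-development constraints: primer length
18-24 nt, G/C content 40-70 %, annealing temperature 54-63 °C, product
length >= 100 bp (and a configurable maximum). The melting temperature is
the simple GC-count formula Tm = 64.9 + 41 (nGC - 16.4) / L, which depends
only on primer length and G+C count; it is deliberately swappable and is
not a nearest-neighbour thermodynamic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.SeqUtils import gc_fraction

from .sequence_io import TranscriptRecord
from .ssr_mining import SsrLocus, revcomp

__all__ = [
    "PrimerConstraints",
    "PrimerPair",
    "gc_content",
    "melting_temp",
    "design_primers",
    "audit_primer_pair",
    "write_primer_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrimerConstraints:
    """Acceptance windows for primer candidates."""

    min_primer_len: int = 18
    max_primer_len: int = 24
    min_gc_pct: float = 40.0
    max_gc_pct: float = 70.0
    min_tm_c: float = 54.0
    max_tm_c: float = 63.0
    min_product_bp: int = 100
    max_product_bp: int = 400

    def __post_init__(self):
        if self.min_primer_len > self.max_primer_len:
            raise ValueError("empty primer-length range")
        if self.min_gc_pct > self.max_gc_pct or self.min_tm_c > self.max_tm_c:
            raise ValueError("empty GC or Tm range")
        if self.min_product_bp > self.max_product_bp:
            raise ValueError("empty product-length range")
        if self.min_product_bp <= 2 * self.min_primer_len:
            raise ValueError("min product must exceed two primer lengths")


@dataclass(frozen=True)
class PrimerPair:
    """A left/right candidate pair whose product spans the SSR tract.

    ``right_seq`` is given 5'→3' on the reverse strand (synthesis order);
    coordinates are 0-based on the transcript and
    ``product_length_bp == right_end - left_start``.
    """

    locus: SsrLocus
    left_seq: str
    right_seq: str
    left_start: int
    right_end: int
    product_length_bp: int
    left_gc_pct: float
    right_gc_pct: float
    left_tm_c: float
    right_tm_c: float


def gc_content(seq: str) -> float:
    """G+C percentage of a sequence over {A,C,G,T}."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def melting_temp(seq: str) -> float:
    """Tm (°C) by the GC-count formula 64.9 + 41 (nGC - 16.4) / L."""
    if not 10 <= len(seq) <= 40:
        raise ValueError(f"primer length {len(seq)} outside 10-40 nt")
    ngc = sum(1 for b in seq if b in "GC")
    return 64.9 + 41.0 * (ngc - 16.4) / len(seq)


def _passes(seq: str, c: PrimerConstraints) -> bool:
    if set(seq) - set("ACGT"):
        return False  # N or other ambiguity disqualifies, not an error
    gc = gc_content(seq)
    if not c.min_gc_pct <= gc <= c.max_gc_pct:
        return False
    tm = melting_temp(seq)
    return c.min_tm_c <= tm <= c.max_tm_c


def design_primers(
    record: TranscriptRecord,
    locus: SsrLocus,
    constraints: PrimerConstraints = PrimerConstraints(),
    top_k: int = 3,
) -> list[PrimerPair]:
    """All-window scan of both flanks; returns up to *top_k* passing pairs.

    Pairs are ranked by |Tm_left − Tm_right| ascending, then product length
    ascending (tight products amplify more reliably on PAGE). An empty list
    means no window combination satisfied every constraint.
    """
    seq = record.seq
    if not (0 <= locus.start < locus.end <= len(seq)):
        raise ValueError("locus outside transcript")
    c = constraints
    # restrict the scan to windows that could still yield a legal product
    lo = max(0, locus.end - c.max_product_bp)
    hi = min(len(seq), locus.start + c.max_product_bp)
    if locus.start - lo < c.min_primer_len or hi - locus.end < c.min_primer_len:
        log.info("locus %s:%d-%d: flank too short for any primer",
                 locus.transcript_id, locus.start, locus.end)
        return []

    lefts = []  # (start, end, seq) on forward strand, entirely left of tract
    for ln in range(c.min_primer_len, c.max_primer_len + 1):
        for start in range(lo, locus.start - ln + 1):
            cand = seq[start : start + ln]
            if _passes(cand, c):
                lefts.append((start, start + ln, cand))
    rights = []  # windows entirely right of tract; primer is the revcomp
    for ln in range(c.min_primer_len, c.max_primer_len + 1):
        for start in range(locus.end, hi - ln + 1):
            cand = seq[start : start + ln]
            if _passes(cand, c):
                rights.append((start, start + ln, cand))

    if not lefts or not rights:
        return []
    l_start = np.array([l[0] for l in lefts])
    l_tm = np.array([melting_temp(l[2]) for l in lefts])
    r_end = np.array([r[1] for r in rights])
    r_tm = np.array([melting_temp(r[2]) for r in rights])
    product = r_end[None, :] - l_start[:, None]
    valid = (product >= c.min_product_bp) & (product <= c.max_product_bp)
    li, ri = np.nonzero(valid)
    if li.size == 0:
        return []
    tm_diff = np.abs(l_tm[li] - r_tm[ri])
    order = np.lexsort((l_start[li], product[li, ri], tm_diff))[:top_k]

    pairs = []
    for idx in order:
        ls, le, lseq = lefts[li[idx]]
        rs, re_, rseq = rights[ri[idx]]
        pairs.append(
            PrimerPair(
                locus=locus,
                left_seq=lseq,
                right_seq=revcomp(rseq),
                left_start=ls,
                right_end=re_,
                product_length_bp=re_ - ls,
                left_gc_pct=gc_content(lseq),
                right_gc_pct=gc_content(rseq),
                left_tm_c=melting_temp(lseq),
                right_tm_c=melting_temp(rseq),
            )
        )
    return pairs


def audit_primer_pair(
    record: TranscriptRecord, pair: PrimerPair,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> list[str]:
    """Independent re-validation of one pair; returns violation messages.

    Recomputes every constraint from the transcript sequence with its own
    arithmetic (Biopython's ``gc_fraction`` and a re-derived Tm expression)
    rather than the enumerator's helpers, so the two routes cannot share a
    defect. An empty list means the pair is valid.
    """
    c = constraints
    problems = []
    locus = pair.locus
    left_tpl = record.seq[pair.left_start : pair.left_start + len(pair.left_seq)]
    right_tpl = record.seq[pair.right_end - len(pair.right_seq) : pair.right_end]
    if left_tpl != pair.left_seq:
        problems.append("left primer does not match template")
    if revcomp(right_tpl) != pair.right_seq:
        problems.append("right primer is not the reverse complement of template")
    if not (pair.left_start + len(pair.left_seq) <= locus.start
            and pair.right_end - len(pair.right_seq) >= locus.end):
        problems.append("product does not span the SSR tract")
    if pair.product_length_bp != pair.right_end - pair.left_start:
        problems.append("product length inconsistent with coordinates")
    if not c.min_product_bp <= pair.product_length_bp <= c.max_product_bp:
        problems.append("product length outside range")
    for name, p in (("left", pair.left_seq), ("right", pair.right_seq)):
        n = len(p)
        if not c.min_primer_len <= n <= c.max_primer_len:
            problems.append(f"{name} primer length {n} outside range")
        gc = 100.0 * gc_fraction(p)
        if not c.min_gc_pct <= gc <= c.max_gc_pct:
            problems.append(f"{name} primer GC {gc:.2f} outside range")
        # same model as the enumerator, independently re-expressed:
        # Tm = 64.9 + 41*GCfrac - 672.4/L
        tm = 64.9 + 41.0 * gc_fraction(p) - 672.4 / n
        if not c.min_tm_c - 1e-9 <= tm <= c.max_tm_c + 1e-9:
            problems.append(f"{name} primer Tm {tm:.2f} outside range")
    return problems


def write_primer_table(pairs: Sequence[PrimerPair], path) -> None:
    """TSV of designed pairs (one row per pair, mirroring marker-sheet
    fields: name, sequences, Tm, repeat motif, product length)."""
    import pandas as pd

    rows = [
        {
            "primer_name": f"{p.locus.transcript_id}_{p.locus.start}_{i}",
            "transcript_id": p.locus.transcript_id,
            "left_seq": p.left_seq,
            "right_seq": p.right_seq,
            "left_tm_c": round(p.left_tm_c, 2),
            "right_tm_c": round(p.right_tm_c, 2),
            "left_gc_pct": round(p.left_gc_pct, 2),
            "right_gc_pct": round(p.right_gc_pct, 2),
            "repeat_motif": f"({p.locus.motif}){p.locus.copies}",
            "product_length_bp": p.product_length_bp,
        }
        for i, p in enumerate(pairs, 1)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
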