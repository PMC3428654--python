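"""Summary statistics over an SSR catalogue.

Counts and frequencies by classification, unit size, motif family and copy
number; genome-wide density (kb of sequence per SSR) and incidence
(SSRs per 100 transcripts); copy-number threshold filtering. Internal values
are exact; percentages are rounded half-up to 2 decimals only for
presentation, matching how such survey tables are printed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequence_io import TranscriptSet
from .ssr_mining import (
    COMPOUND_IMPERFECT,
    COMPOUND_PERFECT,
    IMPERFECT,
    PERFECT,
    SsrLocus,
)

__all__ = [
    "CatalogueSummary",
    "summarize",
    "density_kb_per_ssr",
    "incidence_pct",
    "apply_length_threshold",
    "copy_number_modes",
    "round2",
]

CLASSIFICATIONS = (PERFECT, IMPERFECT, COMPOUND_PERFECT, COMPOUND_IMPERFECT)


def round2(x: float) -> float:
    """Round half-up to 2 decimals (presentation rule for printed tables)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class CatalogueSummary:
    """Disjoint counts over a catalogue plus density/incidence inputs.

    ``by_unit_size`` is keyed per classification by the subtype label
    (``mono``..``hexa`` for simple loci, ``di-di`` etc. for compound loci);
    ``by_motif_class`` and ``copy_number_histogram`` cover perfect loci, the
    scope of published motif-family and copy-number tables.
    """

    n_ssrs: int
    n_transcripts: int
    total_length_bp: int
    threshold_bp: int
    by_classification: dict[str, int]
    by_unit_size: dict[str, Counter]
    by_motif_class: Counter
    copy_number_histogram: dict[int, Counter]
    motif_types_per_unit: Counter

    @property
    def density_kb_per_ssr(self) -> float:
        return density_kb_per_ssr(self.total_length_bp, self.n_ssrs)

    @property
    def incidence_pct(self) -> float:
        return incidence_pct(self.n_ssrs, self.n_transcripts)

    def classification_pct(self) -> dict[str, float]:
        tot = self.n_ssrs
        return {
            k: round2(100 * v / tot) if tot else 0.0
            for k, v in self.by_classification.items()
        }

    def unit_size_pct(self, classification: str) -> dict[str, float]:
        counts = self.by_unit_size[classification]
        tot = sum(counts.values())
        return {k: round2(100 * v / tot) if tot else 0.0 for k, v in counts.items()}

    def motif_class_table(self) -> pd.DataFrame:
        """Motif-family counts over perfect loci, sorted by count descending."""
        df = pd.DataFrame(
            sorted(self.by_motif_class.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["motif_class", "count"],
        )
        tot = df["count"].sum()
        df["pct"] = [round2(100 * c / tot) if tot else 0.0 for c in df["count"]]
        return df


def summarize(
    loci: Sequence[SsrLocus],
    transcript_set: TranscriptSet | None = None,
    threshold_bp: int = 18,
    n_transcripts: int | None = None,
    total_length_bp: int | None = None,
) -> CatalogueSummary:
    """Complete, marginal-consistent summary of an SSR catalogue.

    Transcript totals come from *transcript_set* or may be given directly
    (for catalogues loaded from disk). Loci referencing transcripts absent
    from the set are an error.
    """
    if transcript_set is not None:
        for l in loci:
            if l.transcript_id not in transcript_set:
                raise KeyError(f"locus references unknown transcript {l.transcript_id!r}")
        n_transcripts = len(transcript_set)
        total_length_bp = transcript_set.total_length_bp
    by_class = {c: 0 for c in CLASSIFICATIONS}
    by_unit: dict[str, Counter] = {c: Counter() for c in CLASSIFICATIONS}
    by_motif: Counter = Counter()
    cn_hist: dict[int, Counter] = {k: Counter() for k in range(1, 7)}
    types: dict[int, set] = {k: set() for k in range(1, 7)}
    for l in loci:
        by_class[l.classification] += 1
        by_unit[l.classification][l.subtype] += 1
        if l.classification == PERFECT:
            by_motif[l.canonical.display_pair] += 1
            cn_hist[l.unit_size][l.copies] += 1
            types[l.unit_size].add(l.canonical.display_pair)
    return CatalogueSummary(
        n_ssrs=len(loci),
        n_transcripts=n_transcripts or 0,
        total_length_bp=total_length_bp or 0,
        threshold_bp=threshold_bp,
        by_classification=by_class,
        by_unit_size=by_unit,
        by_motif_class=by_motif,
        copy_number_histogram={k: v for k, v in cn_hist.items() if v},
        motif_types_per_unit=Counter({k: len(v) for k, v in types.items() if v}),
    )


def density_kb_per_ssr(total_length_bp: int, n_ssrs: int) -> float:
    """kb of transcript sequence per SSR, 2 decimals.

    47,986,977 bp with 7,324 loci gives one SSR per 6.55 kb.
    """
    if n_ssrs <= 0:
        raise ZeroDivisionError("density undefined for an empty catalogue")
    return round2((total_length_bp / 1000) / n_ssrs)


def incidence_pct(n_ssrs: int, n_transcripts: int) -> float:
    """100 * n_ssrs / n_transcripts, 2 decimals.

    This is a count ratio (SSRs per 100 transcripts), not the fraction of
    transcripts containing at least one SSR — the two differ when a
    transcript carries several loci.
    """
    if n_transcripts <= 0:
        raise ZeroDivisionError("incidence undefined without transcripts")
    return round2(100 * n_ssrs / n_transcripts)


def apply_length_threshold(
    histogram: Mapping[int, int], unit_size: int, min_tract_bp: int
) -> int:
    """Total loci whose tract (copies * unit_size) meets *min_tract_bp*."""
    if any(c < 1 for c in histogram):
        raise ValueError("copy numbers must be >= 1")
    return sum(n for c, n in histogram.items() if c * unit_size >= min_tract_bp)


def copy_number_modes(
    histogram_by_unit: Mapping[int, Mapping[int, int]],
) -> list[tuple[int, float]]:
    """Copy numbers ranked by total count across unit sizes.

    Returns (copy_number, share_pct) pairs, share rounded to 2 decimals;
    ties rank by copy number ascending.
    """
    totals: Counter = Counter()
    for hist in histogram_by_unit.values():
        for c, n in hist.items():
            totals[c] += n
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("empty histogram")
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(c, round2(100 * n / grand)) for c, n in ranked if n > 0]
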