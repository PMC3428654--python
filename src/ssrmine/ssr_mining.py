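"""Detection and classification of simple sequence repeats (SSRs).

An SSR (microsatellite) is a tandem repetition of a 1-6 bp motif. This
module finds maximal *perfect* tandem runs, joins interrupted runs of the
same motif family into *imperfect* loci, joins adjacent runs into
*compound* loci, and produces a disjoint catalogue in which every base
belongs to at most one reported locus.

Motifs are grouped into canonical classes: all cyclic rotations of a motif
and of its reverse complement are the same family (AG, GA, CT and TC are
all ``AG/CT``), because repeat tracts have no intrinsic phase or strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import TranscriptRecord

__all__ = [
    "MotifClass",
    "SsrLocus",
    "Component",
    "MiningConfig",
    "canonical_motif_class",
    "canonical_label",
    "revcomp",
    "is_primitive",
    "find_perfect_ssrs",
    "detect_imperfect_ssrs",
    "assemble_compound_ssrs",
    "classify_catalogue",
    "UNIT_NAMES",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

UNIT_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}

PERFECT = "perfect"
IMPERFECT = "imperfect"
COMPOUND_PERFECT = "compound_perfect"
COMPOUND_IMPERFECT = "compound_imperfect"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if *motif* is not itself a tandem repetition of a shorter unit.

    Uses the classic rotation trick: a string is non-primitive iff it occurs
    in its own doubling with both flanking characters removed.
    """
    return motif not in (motif + motif)[1:-1]


@dataclass(frozen=True)
class MotifClass:
    """Equivalence class of a repeat motif under rotation and reverse complement.

    ``representative`` is the lexicographically smallest member of the closure
    {rotations(m)} ∪ {rotations(revcomp(m))}; ``display_pair`` is the
    conventional ``MOTIF/REVCOMP`` label, e.g. ``AG/CT``.
    """

    representative: str
    display_pair: str
    unit_size: int


@lru_cache(maxsize=None)
def canonical_motif_class(motif: str) -> MotifClass:
    """Canonical motif class of a 1-6 bp primitive motif.

    Raises ``ValueError`` for motifs with characters outside {A,C,G,T},
    lengths outside 1-6, or non-primitive motifs (``ATAT`` is an (AT)n
    repeat, not a tetranucleotide unit).
    """
    motif = motif.upper()
    if not motif or len(motif) > 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif contains illegal characters: {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif is not primitive: {motif!r}")
    members = _closure(motif)
    rep = min(members)
    return MotifClass(rep, f"{rep}/{revcomp(rep)}", len(rep))


def _closure(motif: str) -> frozenset[str]:
    rc = revcomp(motif)
    rots = {motif[i:] + motif[:i] for i in range(len(motif))}
    rots |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return frozenset(rots)


def canonical_label(label: str) -> str:
    """Canonicalize a motif or ``X/Y`` family label to its display pair.

    Published tables sometimes label a family by a non-minimal member
    (``CA/TG`` for the class whose representative is ``AC``); this maps any
    member or member-pair label onto the canonical ``display_pair``.
    """
    motif = label.split("/")[0].strip()
    return canonical_motif_class(motif).display_pair


@dataclass(frozen=True)
class Component:
    """One perfect run inside an imperfect or compound locus."""

    motif: str
    unit_size: int
    copies: int
    start: int
    end: int


@dataclass(frozen=True)
class SsrLocus:
    """A detected repeat tract on one transcript.

    Coordinates are 0-based half-open. For perfect loci
    ``tract_length == unit_size * copies`` and ``seq[start:end]`` is exactly
    ``copies`` repetitions of ``motif``; for imperfect/compound loci
    ``tract_length`` is the full span and ``copies`` sums the component runs.
    """

    transcript_id: str
    start: int
    end: int
    motif: str
    canonical: MotifClass
    unit_size: int
    copies: int
    classification: str
    components: tuple[Component, ...] = ()

    @property
    def tract_length(self) -> int:
        return self.end - self.start

    @property
    def subtype(self) -> str:
        """Unit-size subtype label: ``di`` for simple loci, ``di-di`` etc.

        Compound loci are labelled by the sorted (min, max) component unit
        sizes, the convention of published compound-SSR taxonomies.
        """
        if self.classification in (COMPOUND_PERFECT, COMPOUND_IMPERFECT):
            sizes = sorted({c.unit_size for c in self.components})
            lo, hi = sizes[0], sizes[-1]
            return f"{UNIT_NAMES[lo]}-{UNIT_NAMES[hi]}"
        return UNIT_NAMES[self.unit_size]


@dataclass(frozen=True)
class MiningConfig:
    """Detection thresholds and joining rules.

    min_tract_bp
        Minimum total span (bp) for a reported locus; 18 by default, 15
        supported. Applies to the full span of imperfect/compound loci.
    unit_sizes
        Repeat unit sizes to scan (subset of 1-6).
    imperfect_max_gap_bp
        Largest interruption (bp) joining two same-family runs into an
        imperfect locus.
    imperfect_min_run_copies
        Minimum full copies for each run joined into an imperfect locus.
    imperfect_min_run_bp
        Minimum span (bp) for each run joined into an imperfect locus. With
        copies alone, any two chance ``AA`` pairs within the gap limit would
        form an "imperfect SSR" — random sequence would then contain one
        every few hundred bases. An 8 bp floor (8 mono copies, 4 di, 3 tri)
        keeps joined runs substantial while admitting classic interrupted
        tracts.
    compound_max_spacer_bp
        Largest spacer (bp) joining adjacent runs into a compound locus.
    compound_min_component_bp
        Minimum span for each member of a different-family compound locus.
        Without a floor, any chance 2-3 bp repeat next to a genuine tract
        would convert it into a compound; 12 bp (two thirds of the default
        reporting threshold) keeps sub-threshold but substantial members
        joinable while excluding background noise.
    composite_unit_sizes
        Unit sizes eligible to form imperfect/compound loci (mono/di/tri by
        default, the only subtypes observed in genic-SSR surveys).
    """

    min_tract_bp: int = 18
    unit_sizes: frozenset[int] = frozenset(range(1, 7))
    imperfect_max_gap_bp: int = 4
    imperfect_min_run_copies: int = 2
    imperfect_min_run_bp: int = 8
    compound_max_spacer_bp: int = 10
    compound_min_component_bp: int = 12
    composite_unit_sizes: frozenset[int] = frozenset({1, 2, 3})

    def __post_init__(self):
        if self.min_tract_bp < 1:
            raise ValueError("min_tract_bp must be positive")
        if not set(self.unit_sizes) <= set(range(1, 7)):
            raise ValueError("unit_sizes must be a subset of {1..6}")
        if min(self.imperfect_max_gap_bp, self.compound_max_spacer_bp) < 0:
            raise ValueError("gap/spacer parameters must be >= 0")


# ---------------------------------------------------------------------------
# perfect-run scan
# ---------------------------------------------------------------------------

def _perfect_runs(seq: str, unit_sizes: Iterable[int], min_tract_bp: int = 0):
    """All maximal perfect tandem runs with >= 2 full copies.

    A run of period k is anchored at the first position of a maximal stretch
    where ``seq[t] == seq[t+k]``; its copy count is the number of full units
    in the stretch. Runs whose leading unit is non-primitive are skipped
    (they are reported under the primitive period instead). N never matches
    anything, so runs cannot cross N.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    ok = arr != b"N"
    out = []
    for k in sorted(unit_sizes):
        if len(seq) < 2 * k:
            continue
        eq = (arr[:-k] == arr[k:]) & ok[:-k] & ok[k:]
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(np.diff(padded.view(np.int8)))
        for s, e in zip(edges[0::2], edges[1::2]):
            copies = int(e - s + k) // k
            if copies < 2:
                continue
            motif = seq[s : s + k]
            if not is_primitive(motif):
                continue
            tract = copies * k
            if tract < min_tract_bp:
                continue
            out.append((int(s), int(s) + tract, motif, k, copies))
    out.sort(key=lambda r: (r[0], r[3]))
    return out


def _run_locus(tid: str, run) -> SsrLocus:
    s, e, motif, k, copies = run
    return SsrLocus(
        transcript_id=tid,
        start=s,
        end=e,
        motif=motif,
        canonical=canonical_motif_class(motif),
        unit_size=k,
        copies=copies,
        classification=PERFECT,
        components=(Component(motif, k, copies, s, e),),
    )


def find_perfect_ssrs(
    record: TranscriptRecord, config: MiningConfig = MiningConfig()
) -> list[SsrLocus]:
    """Maximal perfect SSR loci with tract length >= ``config.min_tract_bp``.

    Loci of different unit sizes may overlap here; ``classify_catalogue``
    resolves overlaps into a disjoint catalogue.
    """
    runs = _perfect_runs(record.seq, config.unit_sizes, config.min_tract_bp)
    return [_run_locus(record.id, r) for r in runs]


def _resolve_overlaps(runs):
    """Disjoint subset of runs: longer tract wins, ties to smaller unit size."""
    order = sorted(runs, key=lambda r: (-(r[1] - r[0]), r[3], r[0]))
    taken: list[tuple[int, int]] = []
    kept = []
    for r in order:
        if all(r[1] <= s or r[0] >= e for s, e in taken):
            kept.append(r)
            taken.append((r[0], r[1]))
    kept.sort(key=lambda r: r[0])
    return kept


def _chain_imperfect(runs, config: MiningConfig):
    """Group same-family runs separated by short interruptions into
    imperfect chains.

    Chaining is done per motif family, so a chance micro-repeat of another
    family sitting inside an interruption (necessarily <= the gap limit, so
    tiny) does not split the chain; runs interleaved within an accepted
    chain's span are consumed by it. Returns a list of "units": either a
    single run tuple or a list of >= 2 run tuples (an interrupted tract).
    """
    eligible: dict[MotifClass, list[int]] = {}
    for idx, r in enumerate(runs):
        if (
            r[3] in config.composite_unit_sizes
            and r[4] >= config.imperfect_min_run_copies
            and (r[1] - r[0]) >= config.imperfect_min_run_bp
        ):
            eligible.setdefault(canonical_motif_class(r[2]), []).append(idx)

    candidates: list[list[int]] = []
    for idxs in eligible.values():
        cur = [idxs[0]]
        for a, b in zip(idxs, idxs[1:]):
            gap = runs[b][0] - runs[a][1]
            if 1 <= gap <= config.imperfect_max_gap_bp:
                cur.append(b)
            else:
                if len(cur) > 1:
                    candidates.append(cur)
                cur = [b]
        if len(cur) > 1:
            candidates.append(cur)

    # longest chain wins where chains of different families would interleave
    candidates.sort(key=lambda c: -(runs[c[-1]][1] - runs[c[0]][0]))
    consumed = [False] * len(runs)
    spans: list[tuple[int, int]] = []
    units: list = []
    for chain in candidates:
        s, e = runs[chain[0]][0], runs[chain[-1]][1]
        if any(consumed[i] for i in chain):
            continue
        if any(s < se and e > ss for ss, se in spans):
            continue
        for i, r in enumerate(runs):
            if r[0] >= s and r[1] <= e:
                consumed[i] = True
        spans.append((s, e))
        units.append([runs[i] for i in chain])
    for i, r in enumerate(runs):
        if not consumed[i]:
            units.append(r)
    units.sort(key=lambda u: _unit_span(u)[0])
    return units


def _unit_span(unit):
    if isinstance(unit, list):
        return unit[0][0], unit[-1][1]
    return unit[0], unit[1]


def _unit_class(unit):
    motif = unit[0][2] if isinstance(unit, list) else unit[2]
    return canonical_motif_class(motif)


def _unit_size(unit):
    return (unit[0][3] if isinstance(unit, list) else unit[3])


def _compound_joinable(a, b, config: MiningConfig) -> bool:
    sa, ea = _unit_span(a)
    sb, eb = _unit_span(b)
    gap = sb - ea
    if not (0 <= gap <= config.compound_max_spacer_bp):
        return False
    if not (
        _unit_size(a) in config.composite_unit_sizes
        and _unit_size(b) in config.composite_unit_sizes
    ):
        return False
    if _unit_class(a) != _unit_class(b):
        return (
            (ea - sa) >= config.compound_min_component_bp
            and (eb - sb) >= config.compound_min_component_bp
        )
    # same family: only if each side independently passes the span threshold
    return (ea - sa) >= config.min_tract_bp and (eb - sb) >= config.min_tract_bp


def _imperfect_locus(tid: str, chain, config: MiningConfig) -> SsrLocus:
    start, end = chain[0][0], chain[-1][1]
    return SsrLocus(
        transcript_id=tid,
        start=start,
        end=end,
        motif=chain[0][2],
        canonical=canonical_motif_class(chain[0][2]),
        unit_size=chain[0][3],
        copies=sum(r[4] for r in chain),
        classification=IMPERFECT,
        components=tuple(Component(r[2], r[3], r[4], r[0], r[1]) for r in chain),
    )


def _compound_locus(tid: str, group, config: MiningConfig) -> SsrLocus:
    comps = []
    any_imperfect = False
    for unit in group:
        if isinstance(unit, list):
            any_imperfect = True
            comps.extend(Component(r[2], r[3], r[4], r[0], r[1]) for r in unit)
        else:
            comps.append(Component(unit[2], unit[3], unit[4], unit[0], unit[1]))
    start, end = comps[0].start, comps[-1].end
    first = comps[0]
    return SsrLocus(
        transcript_id=tid,
        start=start,
        end=end,
        motif=first.motif,
        canonical=canonical_motif_class(first.motif),
        unit_size=first.unit_size,
        copies=sum(c.copies for c in comps),
        classification=COMPOUND_IMPERFECT if any_imperfect else COMPOUND_PERFECT,
        components=tuple(comps),
    )


def detect_imperfect_ssrs(
    record: TranscriptRecord, config: MiningConfig = MiningConfig()
) -> list[SsrLocus]:
    """Imperfect loci only: same-family runs joined across short interruptions."""
    runs = _resolve_overlaps(_perfect_runs(record.seq, config.unit_sizes))
    units = _chain_imperfect(runs, config)
    return [
        _imperfect_locus(record.id, u, config)
        for u in units
        if isinstance(u, list) and (u[-1][1] - u[0][0]) >= config.min_tract_bp
    ]


def assemble_compound_ssrs(
    record: TranscriptRecord, config: MiningConfig = MiningConfig()
) -> list[SsrLocus]:
    """Compound loci only: adjacent runs of different families (or long
    same-family runs) joined across a short spacer."""
    return [
        l
        for l in classify_catalogue(record, config)
        if l.classification in (COMPOUND_PERFECT, COMPOUND_IMPERFECT)
    ]


def classify_catalogue(
    record: TranscriptRecord, config: MiningConfig = MiningConfig()
) -> list[SsrLocus]:
    """Full disjoint SSR catalogue for one transcript.

    Precedence is compound > imperfect > perfect: runs consumed by a joined
    locus are not re-reported, so the four classification counts partition
    the catalogue and each base belongs to at most one locus. The span
    threshold applies to the total extent of joined loci.
    """
    runs = _resolve_overlaps(_perfect_runs(record.seq, config.unit_sizes))
    units = _chain_imperfect(runs, config)
    # chance micro-repeats below the component floor are transparent for
    # compound assembly: they neither join a chain nor break one (they can
    # sit inside a spacer), and being sub-threshold they are never reported
    floor = min(config.compound_min_component_bp, config.min_tract_bp)
    units = [
        u for u in units if _unit_span(u)[1] - _unit_span(u)[0] >= floor
    ]

    loci: list[SsrLocus] = []
    i = 0
    while i < len(units):
        group = [units[i]]
        j = i
        while j + 1 < len(units) and _compound_joinable(units[j], units[j + 1], config):
            group.append(units[j + 1])
            j += 1
        if len(group) > 1:
            span = _unit_span(group[-1])[1] - _unit_span(group[0])[0]
            if span >= config.min_tract_bp:
                loci.append(_compound_locus(record.id, group, config))
        else:
            unit = group[0]
            s, e = _unit_span(unit)
            if e - s >= config.min_tract_bp:
                if isinstance(unit, list):
                    loci.append(_imperfect_locus(record.id, unit, config))
                else:
                    loci.append(_run_locus(record.id, unit))
        i = j + 1
    loci.sort(key=lambda l: l.start)
    return loci
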