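"""Ground-truthed synthetic inputs for every pipeline stage.

Two generators:

* ``generate_transcripts`` builds transcript sets with planted SSR loci
  (perfect, imperfect, compound) embedded in repeat-free background, with
  exact positions recorded. Backgrounds are rejection-sampled and each
  transcript is verified against the detector before acceptance, so
  detection recall and precision against the ground truth are exact by
  construction, not approximate.
* ``generate_genotypes`` draws band profiles for accessions × markers from
  known allele frequencies, so downstream PIC and similarity estimates have
  a known target.

Default distributional parameters mirror a published sesame transcriptome
SSR survey: mean transcript length ≈ 1,127 bp, ~0.104 loci per transcript
at the 18 bp threshold, a di-dominant / AG/CT-dominant motif spectrum, and
copy numbers shaped like the published per-unit histograms (loaded from the
packaged fixture). Exact reproduction of the real survey's counts is not
claimed — the generator targets the published *distributions*.

``load_fixture`` exposes the packaged published count tables for
consistency tests and arithmetic checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .marker_diversity import GenotypeMatrix, pic
from .sequence_io import TranscriptRecord, TranscriptSet
from .ssr_mining import (
    COMPOUND_IMPERFECT,
    COMPOUND_PERFECT,
    IMPERFECT,
    PERFECT,
    MiningConfig,
    canonical_motif_class,
    classify_catalogue,
    revcomp,
)

__all__ = [
    "SimulationSpec",
    "PlantedLocus",
    "GroundTruth",
    "generate_transcripts",
    "generate_genotypes",
    "evaluate_detection",
    "load_fixture",
    "DEFAULT_MOTIF_WEIGHTS",
]

_BASES = np.array(["A", "C", "G", "T"])

#: Motif-family weights shaped like the published >=18 bp perfect-SSR
#: spectrum: mono 0.57 %, di 48.01 % (AG/CT 34.51, CA/TG 7.65, AT/AT 5.85),
#: tri 20.96 % (GAA/TTC 3.57, remainder spread over common tri families),
#: tetra 2.12 %, penta 2.97 %, hexa 25.37 % (spread over A-rich hexamers).
DEFAULT_MOTIF_WEIGHTS: dict[str, float] = {
    "A": 0.0057,
    "AG": 0.3451,
    "CA": 0.0765,
    "AT": 0.0585,
    "GAA": 0.0357,
    "AAC": 0.0290,
    "AAT": 0.0290,
    "ACC": 0.0290,
    "AGG": 0.0290,
    "ATC": 0.0290,
    "ACT": 0.0289,
    "ATAC": 0.0212,
    "AAAAG": 0.0297,
    "GAAAAA": 0.0900,
    "AAACAG": 0.0600,
    "AACAGC": 0.0537,
    "AATGCC": 0.0500,
}

#: Compound subtype mix shaped like the published >=18 bp compound table
#: (di-di dominant).
_COMPOUND_SUBTYPE_WEIGHTS = {
    (1, 1): 0.10,
    (2, 2): 0.86,
    (3, 3): 0.018,
    (1, 2): 0.013,
    (1, 3): 0.009,
}


@dataclass
class SimulationSpec:
    """Parameters of a transcript-set simulation; the seed fully determines
    the output."""

    n_transcripts: int = 1000
    #: lognormal length model tuned so the mean is ~1,127 bp
    length_log_mean: float = math.log(1127.0) - 0.5
    length_log_sigma: float = 1.0
    min_length_bp: int = 150
    gc_background: float = 0.40
    #: expected planted loci per transcript (published: 4,440 / 42,566)
    ssr_plant_rate: float = 0.104
    motif_class_weights: Mapping[str, float] | None = None
    copy_number_distribution: Mapping[int, Mapping[int, float]] | None = None
    #: perfect / imperfect / compound mix (published >=18 bp shares)
    classification_mix: tuple[float, float, float] = (0.8275, 0.0453, 0.1272)
    #: fraction of compound loci with an interrupted member (340 / 565)
    compound_imperfect_frac: float = 0.602
    min_tract_bp: int = 18
    seed: int = 0

    def mining_config(self) -> MiningConfig:
        return MiningConfig(min_tract_bp=self.min_tract_bp)

    def normalized_motif_weights(self) -> dict[str, float]:
        raw = dict(self.motif_class_weights or DEFAULT_MOTIF_WEIGHTS)
        # canonicalize keys and merge duplicates
        canon: dict[str, float] = {}
        for motif, w in raw.items():
            if w < 0:
                raise ValueError("motif weights must be non-negative")
            rep = canonical_motif_class(motif).representative
            canon[rep] = canon.get(rep, 0.0) + w
        total = sum(canon.values())
        if total <= 0:
            raise ValueError("motif weights sum to zero")
        return {m: w / total for m, w in canon.items()}

    def copy_weights(self) -> dict[int, dict[int, float]]:
        if self.copy_number_distribution is not None:
            return {
                k: dict(v) for k, v in self.copy_number_distribution.items()
            }
        t4 = load_fixture("table4")
        cols = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
        return {
            k: {
                int(c): float(n)
                for c, n in zip(t4["copies"], t4[col])
                if n > 0
            }
            for k, col in cols.items()
        }


@dataclass(frozen=True)
class PlantedLocus:
    transcript_id: str
    start: int
    end: int
    classification: str
    canonical_class: str
    subtype: str
    copies: int


@dataclass
class GroundTruth:
    """Exact positions and classes of planted loci."""

    loci: list[PlantedLocus] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": l.transcript_id,
                    "start": l.start,
                    "end": l.end,
                    "classification": l.classification,
                    "canonical_class": l.canonical_class,
                    "subtype": l.subtype,
                    "copies": l.copies,
                }
                for l in self.loci
            ],
            columns=[
                "transcript_id", "start", "end", "classification",
                "canonical_class", "subtype", "copies",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transcript simulation
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_bases(rng, n: int, gc: float) -> list[str]:
    return list(rng.choice(_BASES, size=n, p=_base_probs(gc)))


def _clean_background(rng, n: int, gc: float, config: MiningConfig) -> str:
    """Background with no SSR catalogue entry at the active threshold and no
    perfect run of 8 bp or longer (so chance runs cannot chain with planted
    loci into longer spans)."""
    if n == 0:
        return ""
    # long stretches are built from independently validated chunks: the
    # per-chunk rejection probability is small and does not compound with
    # total length (a chance run crossing a chunk seam is caught by the
    # transcript-level verification)
    chunk = 400
    if n > chunk:
        parts = [
            _clean_background(rng, m, gc, config)
            for m in [chunk] * (n // chunk) + ([n % chunk] if n % chunk else [])
        ]
        return "".join(parts)

    from .ssr_mining import _perfect_runs  # internal scan, fastest check

    for _ in range(200):
        block = "".join(_random_bases(rng, n, gc))
        # mono/di/tri runs that could chain with a planted locus, or any run
        # reaching the compound component floor, disqualify a block; shorter
        # runs of large units are transparent noise and are allowed
        runs = _perfect_runs(block, range(1, 7), min_tract_bp=8)
        if any(
            (r[3] <= 3 and (r[1] - r[0]) >= config.imperfect_min_run_bp)
            or (r[1] - r[0]) >= config.compound_min_component_bp
            for r in runs
        ):
            continue
        if classify_catalogue(TranscriptRecord("bg", block), config):
            continue
        return block
    raise RuntimeError("could not generate repeat-free background")


def _pick(rng, weights: Mapping) -> object:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _member_motif(rng, rep: str) -> str:
    """Random member of the motif class (rotation, either strand)."""
    strand = rep if rng.random() < 0.5 else revcomp(rep)
    shift = int(rng.integers(len(strand)))
    return strand[shift:] + strand[:shift]


def _sample_copies(rng, copy_weights, unit: int, min_bp: int, min_copies: int = 2) -> int:
    hist = copy_weights.get(unit, {})
    lo = max(min_copies, -(-min_bp // unit))  # ceil division
    eligible = {c: w for c, w in hist.items() if c >= lo}
    if not eligible:
        return lo
    return int(_pick(rng, eligible))


def _insert(rng, length: int, left_motif: str, left_unit: int,
            right_motif: str, right_unit: int) -> str:
    """Spacer/interruption of *length* bases that cannot seed a repeat run
    or extend its neighbours.

    Characters avoid equality at lags 1-3 (no mono/di/tri run fits inside),
    the first character breaks the left run's period and the last breaks the
    right run's.
    """
    for _ in range(50):
        chars: list[str] = []
        ok = True
        for i in range(length):
            banned = {chars[i - lag] for lag in (1, 2, 3) if i - lag >= 0}
            if i == 0:
                # would continue the left run's period
                banned.add(left_motif[0])
            if i == length - 1:
                # would let the right run extend one base leftwards
                banned.add(right_motif[right_unit - 1])
            avail = [b for b in "ACGT" if b not in banned]
            if not avail:
                ok = False
                break
            chars.append(avail[int(rng.integers(len(avail)))])
        if ok:
            return "".join(chars)
    raise RuntimeError("could not build a period-breaking insert")


def _tract_perfect(rng, spec, weights, copy_weights):
    rep = _pick(rng, weights)
    unit = len(rep)
    motif = _member_motif(rng, rep)
    copies = _sample_copies(rng, copy_weights, unit, spec.min_tract_bp)
    cls = canonical_motif_class(motif)
    return motif * copies, PERFECT, cls.display_pair, cls, copies, None


def _tract_imperfect(rng, spec, weights, copy_weights):
    small = {m: w for m, w in weights.items() if len(m) <= 3}
    rep = _pick(rng, small)
    unit = len(rep)
    motif = _member_motif(rng, rep)
    min_run = -(-8 // unit)  # each joined run must span >= 8 bp
    total = _sample_copies(
        rng, copy_weights, unit, spec.min_tract_bp, min_copies=2 * min_run
    )
    c1 = int(rng.integers(min_run, total - min_run + 1))
    c2 = total - c1
    gap = int(rng.integers(1, 5))
    mid = _insert(rng, gap, motif, unit, motif, unit)
    cls = canonical_motif_class(motif)
    return motif * c1 + mid + motif * c2, IMPERFECT, cls.display_pair, cls, total, None


def _tract_compound(rng, spec, weights, copy_weights, imperfect_member: bool):
    for _ in range(50):
        u1, u2 = _pick(rng, _COMPOUND_SUBTYPE_WEIGHTS)
        if int(rng.random() < 0.5):
            u1, u2 = u2, u1
        pool1 = {m: w for m, w in weights.items() if len(m) == u1}
        pool2 = {m: w for m, w in weights.items() if len(m) == u2}
        if u1 == 1:
            pool1 = {"A": 1.0, "C": 1.0}
        if u2 == 1:
            pool2 = {"A": 1.0, "C": 1.0}
        if not pool1 or not pool2:
            continue
        rep1, rep2 = _pick(rng, pool1), _pick(rng, pool2)
        if canonical_motif_class(rep1) == canonical_motif_class(rep2):
            continue
        m1, m2 = _member_motif(rng, rep1), _member_motif(rng, rep2)
        comp_min = max(12, spec.min_tract_bp // 2 + 3)
        c1 = _sample_copies(rng, copy_weights, u1, comp_min)
        c2 = _sample_copies(rng, copy_weights, u2, comp_min)
        left = m1 * c1
        copies = c1 + c2
        if imperfect_member:
            # interrupt the first member so the locus is compound_imperfect
            min_run = -(-8 // u1)
            extra = _sample_copies(
                rng, copy_weights, u1, comp_min, min_copies=2 * min_run
            )
            ca = int(rng.integers(min_run, extra - min_run + 1))
            cb = extra - ca
            gap = int(rng.integers(1, 5))
            left = m1 * ca + _insert(rng, gap, m1, u1, m1, u1) + m1 * cb
            copies = extra + c2
        spacer_len = int(rng.integers(0, 5))
        right = m2 * c2
        if spacer_len == 0 and (right[0] == left[-u1] or left[-1] == right[u2 - 1]):
            continue  # abutting runs would extend each other; redraw
        spacer = (
            _insert(rng, spacer_len, m1, u1, m2, u2) if spacer_len else ""
        )
        seq = left + spacer + right
        lo, hi = sorted((u1, u2))
        names = {1: "mono", 2: "di", 3: "tri"}
        subtype = f"{names[lo]}-{names[hi]}"
        kind = COMPOUND_IMPERFECT if imperfect_member else COMPOUND_PERFECT
        cls = canonical_motif_class(left[:u1])
        return seq, kind, cls.display_pair, cls, copies, subtype
    raise RuntimeError("could not construct a compound tract")


def _plant_one(rng, spec, weights, copy_weights):
    r = rng.random()
    p_perf, p_imp, p_comp = np.array(spec.classification_mix) / sum(
        spec.classification_mix
    )
    if r < p_perf:
        return _tract_perfect(rng, spec, weights, copy_weights)
    if r < p_perf + p_imp:
        return _tract_imperfect(rng, spec, weights, copy_weights)
    return _tract_compound(
        rng, spec, weights, copy_weights,
        imperfect_member=bool(rng.random() < spec.compound_imperfect_frac),
    )


def _subtype_of(unit: int) -> str:
    from .ssr_mining import UNIT_NAMES

    return UNIT_NAMES[unit]


def _build_transcript(rng, spec, tid, weights, copy_weights, config):
    base_len = max(
        spec.min_length_bp,
        int(round(rng.lognormal(spec.length_log_mean, spec.length_log_sigma))),
    )
    n_plant = int(rng.poisson(spec.ssr_plant_rate))
    for _ in range(100):
        tracts = [_plant_one(rng, spec, weights, copy_weights) for _ in range(n_plant)]
        tract_bp = sum(len(t[0]) for t in tracts)
        need = tract_bp + 30 * (n_plant + 1)
        length = max(base_len, need)
        spare = length - need
        extra = rng.multinomial(spare, [1 / (n_plant + 1)] * (n_plant + 1))
        flank_lens = [30 + int(e) for e in extra]
        if n_plant == 0:
            flank_lens = [length]

        parts: list[str] = []
        truth_rows = []
        pos = 0
        ok = True
        for i, t in enumerate(tracts):
            seq_t, kind, display, cls, copies, subtype = t
            unit = cls.unit_size
            flank = _clean_background(rng, flank_lens[i], spec.gc_background, config)
            # junction repair: the flank must not extend the tract's period
            if flank and flank[-1] == seq_t[unit - 1]:
                choices = [b for b in "ACGT" if b != seq_t[unit - 1]
                           and (len(flank) < 2 or b != flank[-2])]
                flank = flank[:-1] + choices[int(rng.integers(len(choices)))]
            parts.append(flank)
            pos += len(flank)
            truth_rows.append(
                PlantedLocus(
                    tid, pos, pos + len(seq_t), kind, display,
                    subtype or _subtype_of(unit), copies,
                )
            )
            parts.append(seq_t)
            pos += len(seq_t)
            # right junction handled when the next flank is prepended below
        tail = _clean_background(rng, flank_lens[-1] if n_plant else flank_lens[0],
                                 spec.gc_background, config)
        parts.append(tail)
        seq = "".join(parts)

        # repair right junctions: the first flank base after a tract must not
        # match the tract at lags 1-3, else it could extend the final run
        chars = list(seq)
        for row in truth_rows:
            e = row.end
            if e < len(chars):
                banned = {chars[e - lag] for lag in (1, 2, 3) if e - lag >= 0}
                if chars[e] in banned:
                    avail = [b for b in "ACGT" if b not in banned]
                    chars[e] = avail[int(rng.integers(len(avail)))]
        seq = "".join(chars)

        record = TranscriptRecord(tid, seq)
        detected = classify_catalogue(record, config)
        want = {(r.start, r.end, r.classification, r.copies) for r in truth_rows}
        got = {(l.start, l.end, l.classification, l.copies) for l in detected}
        if want == got:
            return record, truth_rows
    raise RuntimeError(f"could not realize transcript {tid} after 100 attempts")


def generate_transcripts(spec: SimulationSpec) -> tuple[TranscriptSet, GroundTruth]:
    """Simulate a transcript set with exactly recoverable planted SSRs.

    Every accepted transcript is re-classified with the detector and only
    kept when the detected catalogue equals the planted one, so
    ``evaluate_detection`` returns 100 % recall and precision by
    construction. Deterministic for a fixed spec (including seed).
    """
    mean_len = math.exp(spec.length_log_mean + spec.length_log_sigma**2 / 2)
    if spec.ssr_plant_rate * 75 + 60 > mean_len:
        raise ValueError(
            "infeasible spec: planted loci and mandatory flanks exceed the "
            "expected transcript length"
        )
    rng = np.random.default_rng(spec.seed)
    weights = spec.normalized_motif_weights()
    copy_weights = spec.copy_weights()
    config = spec.mining_config()
    records, truth = [], GroundTruth()
    for i in range(spec.n_transcripts):
        tid = f"TR{i + 1:05d}"
        rec, rows = _build_transcript(rng, spec, tid, weights, copy_weights, config)
        records.append(rec)
        truth.loci.extend(rows)
    return TranscriptSet(records), truth


def evaluate_detection(truth: GroundTruth, detected: Sequence) -> dict:
    """Recall/precision of a detected catalogue against planted ground truth.

    A detected locus matches a planted one when transcript, coordinates,
    classification and total copy count all agree.
    """
    want = {
        (l.transcript_id, l.start, l.end, l.classification, l.copies)
        for l in truth.loci
    }
    got = {
        (l.transcript_id, l.start, l.end, l.classification, l.copies)
        for l in detected
    }
    tp = len(want & got)
    return {
        "n_truth": len(want),
        "n_detected": len(got),
        "recall_pct": 100.0 * tp / len(want) if want else 100.0,
        "precision_pct": 100.0 * tp / len(got) if got else 100.0,
    }


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def generate_genotypes(
    n_accessions: int,
    markers: Sequence[Sequence[float]],
    seed: int = 0,
    band_base_bp: int = 150,
    band_step_bp: int = 10,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Band matrix drawn from known allele frequencies.

    Each accession carries one allele per marker, drawn independently from
    that marker's frequency vector; allele *j* of marker *i* runs at band
    size ``band_base_bp + band_step_bp * j`` (distinct within a marker).
    Returns the matrix and a truth table with each marker's frequencies and
    exact PIC. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    accession_ids = [f"M{i + 1:02d}" for i in range(n_accessions)]
    marker_ids = [f"HS{i + 1:03d}" for i in range(len(markers))]
    bands: dict[tuple[str, str], frozenset] = {}
    truth_rows = []
    for mi, freqs in enumerate(markers):
        freqs = np.asarray(freqs, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-6 or np.any(freqs <= 0):
            raise ValueError(f"invalid allele frequencies for marker {mi}")
        sizes = [band_base_bp + band_step_bp * j for j in range(len(freqs))]
        draws = rng.choice(len(freqs), size=n_accessions, p=freqs)
        for ai, allele in enumerate(draws):
            bands[(marker_ids[mi], accession_ids[ai])] = frozenset(
                {sizes[int(allele)]}
            )
        truth_rows.append(
            {
                "marker": marker_ids[mi],
                "n_alleles": len(freqs),
                "allele_freqs": tuple(float(f) for f in freqs),
                "true_pic": pic(freqs),
            }
        )
    matrix = GenotypeMatrix(accession_ids, marker_ids, bands)
    return matrix, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

_FIXTURES = {"table2", "table4", "totals", "motifs"}


def load_fixture(name: str):
    """Packaged published count tables.

    ``table2``: loci by classification/subtype at both thresholds;
    ``table4``: perfect-SSR copy-number histogram by unit size (>=15 bp);
    ``totals``: headline totals as a dict; ``motifs``: top motif families.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    path = resources.files("ssrmine.data") / f"{name}.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    if name == "totals":
        return dict(zip(df["key"], df["value"].astype(int)))
    return df
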