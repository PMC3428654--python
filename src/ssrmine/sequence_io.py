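"""FASTA transcript I/O and SSR-catalogue serialization (TSV / GFF3).

Internal coordinates are 0-based half-open; GFF3 export converts to the
format's 1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptRecord",
    "TranscriptSet",
    "SequenceFormatError",
    "read_fasta",
    "write_fasta",
    "write_catalogue",
    "read_catalogue",
    "CATALOGUE_COLUMNS",
]

_ALPHABET = set("ACGTN")


class SequenceFormatError(ValueError):
    """Malformed FASTA input: bad header, illegal character, empty or
    duplicate record."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One uni-transcript: a unique id plus an uppercase A/C/G/T/N sequence."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceFormatError(f"malformed header / id: {self.id!r}")
        if not self.seq:
            raise SequenceFormatError(f"empty sequence for record {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise SequenceFormatError(
                f"illegal character(s) {sorted(bad)} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TranscriptSet:
    """Ordered collection of transcripts with unique ids."""

    records: list[TranscriptRecord] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for r in self.records:
            if r.id in seen:
                raise SequenceFormatError(f"duplicate id: {r.id!r}")
            seen.add(r.id)
        self._index = {r.id: r for r in self.records}

    @property
    def total_length_bp(self) -> int:
        return sum(len(r) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, transcript_id: str) -> TranscriptRecord:
        return self._index[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._index


def read_fasta(path) -> TranscriptSet:
    """Read a (multi-line) FASTA file into a TranscriptSet.

    Ids are headers truncated at the first whitespace; the remainder is kept
    as ``description``. Lowercase bases are folded to uppercase; characters
    outside A/C/G/T/N are rejected.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(TranscriptRecord(rec.id, str(rec.seq), desc))
    return TranscriptSet(records)


def write_fasta(transcripts: TranscriptSet, path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(t.seq), id=t.id, description=t.description)
        for t in transcripts
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# catalogue tables
# ---------------------------------------------------------------------------

CATALOGUE_COLUMNS = [
    "transcript_id",
    "start",
    "end",
    "motif",
    "canonical_class",
    "unit_size",
    "copies",
    "tract_length",
    "classification",
    "component_motifs",
]


def _components_field(locus) -> str:
    return ";".join(f"{c.motif}:{c.copies}" for c in locus.components)


def catalogue_frame(loci: Iterable) -> pd.DataFrame:
    """SSR loci as a DataFrame with the standard catalogue columns."""
    rows = [
        {
            "transcript_id": l.transcript_id,
            "start": l.start,
            "end": l.end,
            "motif": l.motif,
            "canonical_class": l.canonical.display_pair,
            "unit_size": l.unit_size,
            "copies": l.copies,
            "tract_length": l.tract_length,
            "classification": l.classification,
            "component_motifs": _components_field(l),
        }
        for l in loci
    ]
    return pd.DataFrame(rows, columns=CATALOGUE_COLUMNS)


def write_catalogue(loci: Sequence, path, format: str = "tsv") -> None:
    """Write an SSR catalogue as TSV or GFF3.

    GFF3 rows use 1-based inclusive coordinates and feature type
    ``microsatellite``; all catalogue fields travel in the attribute column.
    """
    if format == "tsv":
        catalogue_frame(loci).to_csv(path, sep="\t", index=False)
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, l in enumerate(loci, 1):
                attrs = (
                    f"ID=ssr{i};motif={l.motif};"
                    f"canonical_class={l.canonical.display_pair};"
                    f"unit_size={l.unit_size};copies={l.copies};"
                    f"tract_length={l.tract_length};"
                    f"classification={l.classification};"
                    f"component_motifs={_components_field(l)}"
                )
                fh.write(
                    f"{l.transcript_id}\tssrmine\tmicrosatellite\t"
                    f"{l.start + 1}\t{l.end}\t.\t+\t.\t{attrs}\n"
                )
    else:
        raise ValueError(f"unknown catalogue format: {format!r}")


def read_catalogue(path) -> pd.DataFrame:
    """Read a TSV catalogue back into a DataFrame (round-trip of
    ``write_catalogue(..., format='tsv')``)."""
    df = pd.read_csv(path, sep="\t", dtype={"component_motifs": str})
    df["component_motifs"] = df["component_motifs"].fillna("").astype(object)
    return df[CATALOGUE_COLUMNS]
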