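"""Sequence records, coordinate conventions, and FASTA/BED/TSV I/O.

Coordinates are 1-based and fully closed throughout the package, matching
the convention used for NCBI accession coordinates; only BED export uses
the standard 0-based half-open convention.  TSS-relative coordinates count
upstream positions -1, -2, ... with no position 0: -1 is the base
immediately 5' of the transcription start site.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
# IUPAC ambiguity codes (other than N) that are coerced to N on input.
_AMBIGUOUS = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty file, duplicate ids, bad characters)."""


@dataclass
class SequenceRecord:
    """An upstream genomic region with species label and optional TSS anchor.

    ``tss_abs`` is the 1-based position of the annotated transcription start
    site on the source accession; when present, ``gene_strand`` must also be
    set so that TSS-relative coordinates can be resolved.
    """

    id: str
    sequence: str
    species: str = ""
    accession: str | None = None
    tss_abs: int | None = None
    gene_strand: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad & _AMBIGUOUS:
            logger.warning(
                "record %s: IUPAC ambiguity codes %s coerced to N",
                self.id, sorted(bad & _AMBIGUOUS),
            )
            seq = re.sub(f"[{''.join(_AMBIGUOUS)}]", "N", seq)
            bad = set(seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise FastaFormatError(
                f"record {self.id}: invalid character {seq[pos]!r} at position {pos + 1}"
            )
        if len(seq) < 1:
            raise ValueError(f"record {self.id}: empty sequence")
        self.sequence = seq
        if not self.species:
            self.species = self.id
        if self.tss_abs is not None:
            if self.tss_abs < 1:
                raise ValueError(f"record {self.id}: tss_abs must be positive")
            if self.gene_strand not in ("+", "-"):
                raise ValueError(
                    f"record {self.id}: gene_strand required when tss_abs is set"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based fully-closed interval, absolute or TSS-relative.

    Absolute frame: 1 <= start <= end.  TSS-relative frame: start <= end <= -1
    (there is no position 0).  In both frames the length is end - start + 1.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    frame: str = "absolute"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.frame == "absolute":
            if not (1 <= self.start <= self.end):
                raise ValueError(
                    f"absolute interval requires 1 <= start <= end, got "
                    f"({self.start}, {self.end})"
                )
        elif self.frame == "tss_relative":
            if not (self.start <= self.end <= -1):
                raise ValueError(
                    f"tss-relative interval requires start <= end <= -1, got "
                    f"({self.start}, {self.end})"
                )
        else:
            raise ValueError(f"invalid frame {self.frame!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def interval_length(iv: GenomicInterval) -> int:
    """Length of a fully-closed interval: end - start + 1."""
    return iv.length


def normalize_complement_listing(a: int, b: int, seq_id: str = "") -> GenomicInterval:
    """Normalize a complement-strand coordinate pair (possibly descending).

    Accession tables list reverse-strand features with descending coordinates
    flagged "complement"; this returns the ascending absolute interval on the
    minus strand.
    """
    if a < 1 or b < 1:
        raise ValueError(f"coordinates must be positive, got ({a}, {b})")
    return GenomicInterval(seq_id, min(a, b), max(a, b), strand="-")


def tss_relative_to_absolute(iv: GenomicInterval, rec: SequenceRecord) -> GenomicInterval:
    """Convert a TSS-relative interval to absolute accession coordinates.

    For a gene on '+', relative position -n maps to tss_abs - n (so -1 abuts
    the TSS); on '-' it maps to tss_abs + n.  Length is preserved.
    """
    if iv.frame != "tss_relative":
        raise ValueError("interval must be in tss_relative frame")
    if rec.tss_abs is None or rec.gene_strand is None:
        raise ValueError(f"record {rec.id} has no TSS anchor")
    if rec.gene_strand == "+":
        a, b = rec.tss_abs + iv.start, rec.tss_abs + iv.end
    else:
        a, b = rec.tss_abs - iv.end, rec.tss_abs - iv.start
    start, end = min(a, b), max(a, b)
    if start < 1:
        raise ValueError(
            f"interval ({iv.start}, {iv.end}) extends beyond the start of "
            f"{rec.accession or rec.id}"
        )
    return GenomicInterval(rec.accession or rec.id, start, end,
                           strand=rec.gene_strand, frame="absolute")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """G+C fraction over unambiguous bases; N is excluded from the denominator."""
    s = seq.upper()
    denom = sum(s.count(c) for c in "ACGT")
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (s.count("G") + s.count("C")) / denom


# ---------------------------------------------------------------------------
# FASTA I/O
#
# Header convention: the first whitespace-separated token is the record id;
# optional key=value tokens "species=", "accession=", "tss=" (integer) and
# "strand=" (+/-) are recognized.

def _parse_header(description: str) -> dict:
    tokens = description.split()
    info: dict = {"id": tokens[0]}
    for tok in tokens[1:]:
        if "=" not in tok:
            continue
        key, _, val = tok.partition("=")
        if key == "species":
            info["species"] = val.replace("_", " ")
        elif key == "accession":
            info["accession"] = val
        elif key == "tss":
            info["tss_abs"] = int(val)
        elif key == "strand":
            info["gene_strand"] = val
    return info


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, unwrapped)."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        info = _parse_header(rec.description)
        if info["id"] in seen:
            raise FastaFormatError(f"duplicate record id {info['id']!r} in {path}")
        seen.add(info["id"])
        records.append(SequenceRecord(
            id=info["id"],
            sequence=str(rec.seq),
            species=info.get("species", ""),
            accession=info.get("accession"),
            tss_abs=info.get("tss_abs"),
            gene_strand=info.get("gene_strand"),
        ))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path,
                wrap: int = 60) -> None:
    """Write records as FASTA, 60-column wrapped, preserving header metadata."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            parts = [rec.id]
            if rec.species and rec.species != rec.id:
                parts.append(f"species={rec.species.replace(' ', '_')}")
            if rec.accession:
                parts.append(f"accession={rec.accession}")
            if rec.tss_abs is not None:
                parts.append(f"tss={rec.tss_abs}")
                parts.append(f"strand={rec.gene_strand}")
            fh.write(">" + " ".join(parts) + "\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i:i + wrap] + "\n")


# ---------------------------------------------------------------------------
# BED / TSV export

def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None,
              scores: Sequence[float] | None = None) -> None:
    """Write absolute intervals as 6-column BED (0-based half-open).

    ``scores``, if given, are fractions in [0, 1] scaled to the 0-1000 BED
    score range.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for i, iv in enumerate(intervals):
            if iv.frame != "absolute":
                raise ValueError("only absolute intervals can be exported to BED")
            name = names[i] if names else f"region_{i + 1}"
            score = int(round(1000 * scores[i])) if scores else 0
            fh.write(f"{iv.seq_id}\t{iv.start - 1}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 6-column BED file back into 1-based closed intervals."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            strand = fields[5] if len(fields) > 5 else "+"
            intervals.append(GenomicInterval(
                fields[0], int(fields[1]) + 1, int(fields[2]), strand=strand))
    return intervals


def write_tsv(table, path: str | Path, comment: str | None = None) -> None:
    """Write a pandas DataFrame as TSV; coordinates stay 1-based closed.

    A header comment labels the coordinate convention so exported reports are
    self-describing.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {comment or 'coordinates: 1-based, fully closed'}\n")
        table.to_csv(fh, sep="\t", index=False)
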