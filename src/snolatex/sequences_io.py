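"""Domain types, sequence I/O and alphabet conventions shared by all stages.

Conventions used throughout the package:

* RNA alphabet ``{A, C, G, U, N}``; DNA input is silently normalized
  (``T`` -> ``U``, case-folded to upper) because assembled transcriptomes
  and genome-derived sequences mix alphabets.
* All coordinates at module interfaces are 1-based and inclusive, matching
  the standard rRNA site notation (e.g. "U791") and GFF3.
* Transcripts are scanned on the given strand only by default; assembled
  contigs already carry the transcribed orientation.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("snolatex")

RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

#: IUPAC degenerate nucleotide codes over the RNA alphabet.
IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}


def configure_logging(verbose: bool = False) -> None:
    """Send package log records to stderr; ``verbose`` enables DEBUG."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


class SequenceError(ValueError):
    """Raised on malformed sequence input (alphabet, ids, coordinates)."""


def normalize_residues(raw: str, *, name: str = "<sequence>") -> str:
    """Upper-case, convert T to U and validate the RNA alphabet."""
    residues = raw.upper().replace("T", "U")
    bad = set(residues) - RNA_ALPHABET
    if bad:
        raise SequenceError(
            f"sequence {name!r} contains non-IUPAC RNA characters: {sorted(bad)}"
        )
    if not residues:
        raise SequenceError(f"sequence {name!r} is empty")
    return residues


@dataclass(frozen=True)
class RnaSequence:
    """A named RNA string with a role in the analysis."""

    id: str
    residues: str
    role: str = "transcript"  # transcript | rRNA | pre-rRNA

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if self.role not in ("transcript", "rRNA", "pre-rRNA"):
            raise SequenceError(f"unknown sequence role {self.role!r}")
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, name=self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)

    def slice1(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= len(self)):
            raise SequenceError(
                f"interval {start}..{end} outside 1..{len(self)} of {self.id!r}"
            )
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class GenomicContext:
    """Location of a feature on its parent transcript (1-based, inclusive)."""

    transcript_id: str
    start: int
    end: int
    strand: str = "+"
    exon_overlap: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SequenceError(f"bad interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise SequenceError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "GenomicContext") -> int:
        if self.transcript_id != other.transcript_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


def read_fasta(path: str | Path, role: str = "transcript") -> list[RnaSequence]:
    """Read a FASTA file into validated, T->U-normalized records.

    Ids are the first whitespace token of each header and must be unique.
    """
    path = Path(path)
    records: list[RnaSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(RnaSequence(rec.id, str(rec.seq), role=role))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[RnaSequence], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def reverse_complement_rna(s: str) -> str:
    """Antiparallel RNA complement (A<->U, C<->G, N<->N)."""
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise SequenceError(f"cannot complement non-RNA characters {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def complement_base(b: str) -> str:
    return b.translate(_COMPLEMENT)


def match_degenerate(pattern: str, window: str) -> int:
    """Mismatch count of ``window`` against a degenerate IUPAC ``pattern``.

    A position mismatches when the window residue is outside the pattern
    code's allowed set (R = {A,G}, N = {A,C,G,U}, ...).
    """
    if len(pattern) != len(window):
        raise SequenceError(
            f"pattern length {len(pattern)} != window length {len(window)}"
        )
    mismatches = 0
    for p, w in zip(pattern, window):
        try:
            allowed = IUPAC_SETS[p]
        except KeyError:
            raise SequenceError(f"unknown IUPAC code {p!r} in pattern") from None
        if w not in allowed:
            mismatches += 1
    return mismatches


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

PRE_RRNA_ID = "pre_rRNA"


@dataclass
class CountTable:
    """Read counts: rows are feature ids (plus one pre-rRNA reference row),
    columns are sample ids, cells are non-negative integers."""

    counts: pd.DataFrame
    prerrna_id: str = PRE_RRNA_ID

    def __post_init__(self) -> None:
        if self.prerrna_id not in self.counts.index:
            raise SequenceError(
                f"pre-rRNA reference row {self.prerrna_id!r} missing from count table"
            )
        if (self.counts.to_numpy() < 0).any():
            raise SequenceError("count table contains negative cells")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return [i for i in self.counts.index if i != self.prerrna_id]


def read_counts_tsv(path: str | Path, prerrna_id: str = PRE_RRNA_ID) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountTable(df, prerrna_id=prerrna_id)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# GFF3 output for snoRNA candidates
# ---------------------------------------------------------------------------

def candidates_to_gff3(candidates: Sequence, path: str | Path) -> None:
    """Write snoRNA candidates as GFF3 ``snoRNA`` features.

    Rows are ordered by (transcript id, start) so output is deterministic.
    Attributes carry id, subfamily, class and score.
    """
    lines = ["##gff-version 3"]
    ordered = sorted(candidates, key=lambda c: (c.context.transcript_id, c.context.start, c.id))
    for c in ordered:
        score = "." if c.score is None else f"{c.score:g}"
        attrs = f"ID={c.id};subfamily={c.subfamily};class={c.cls}"
        lines.append(
            "\t".join(
                [
                    c.context.transcript_id,
                    "snolatex",
                    "snoRNA",
                    str(c.context.start),
                    str(c.context.end),
                    score,
                    c.context.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class Gff3Feature:
    """A parsed GFF3 snoRNA feature (round-trip companion of the writer)."""

    id: str
    context: GenomicContext
    subfamily: str
    cls: str
    score: float | None


def read_candidates_gff3(path: str | Path) -> list[Gff3Feature]:
    feats: list[Gff3Feature] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, _src, ftype, start, end, score, strand, _phase, attrs = line.split("\t")
        if ftype != "snoRNA":
            continue
        meta = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
        feats.append(
            Gff3Feature(
                id=meta["ID"],
                context=GenomicContext(seqid, int(start), int(end), strand),
                subfamily=meta.get("subfamily", ""),
                cls=meta.get("class", "unclassified"),
                score=None if score == "." else float(score),
            )
        )
    return feats
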