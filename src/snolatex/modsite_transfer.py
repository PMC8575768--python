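"""Homology transfer of known rRNA modification sites onto a target rRNA.

Known 2'-O-methylation (Nm) and pseudouridylation (psi) positions from
model-organism rRNAs are lifted onto the target species' rRNA through a
global pairwise alignment.  A transferred site must map to an ungapped
column, reproduce the expected nucleotide (psi sites must land on a U) and
sit in a locally conserved context; sites failing any check are dropped
with a reason code so the input partitions exactly into outputs + drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align

from .sequences_io import RnaSequence, SequenceError, logger


@dataclass(frozen=True)
class ModificationSite:
    """An rRNA position carrying a chemical modification (1-based)."""

    rrna_id: str
    position: int
    nucleotide: str
    mtype: str  # "Nm" | "psi"
    provenance: str = "reference"  # reference | transferred | predicted

    def __post_init__(self) -> None:
        if self.mtype not in ("Nm", "psi"):
            raise SequenceError(f"unknown modification type {self.mtype!r}")
        if self.nucleotide not in "ACGU":
            raise SequenceError(f"bad site nucleotide {self.nucleotide!r}")
        if self.mtype == "psi" and self.nucleotide != "U":
            raise SequenceError("pseudouridylation sites must sit on U")
        if self.position < 1:
            raise SequenceError("site positions are 1-based")

    @property
    def label(self) -> str:
        """Field-style label, e.g. ``U791``."""
        return f"{self.nucleotide}{self.position}"


@dataclass(frozen=True)
class PairwiseAlignment:
    reference_id: str
    target_id: str
    aligned_reference: str
    aligned_target: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_reference) != len(self.aligned_target):
            raise SequenceError("aligned strings differ in length")


@dataclass(frozen=True)
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0


def global_align(
    reference: RnaSequence, target: RnaSequence, params: AlignParams = AlignParams()
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (Needleman-Wunsch).

    Opening a gap of length k costs ``gap_open + k * gap_extend``.  Among
    co-optimal alignments the aligner's first traceback is taken, which
    prefers diagonal (match/mismatch) moves; the choice is deterministic.
    """
    if not reference.residues or not target.residues:
        raise SequenceError("cannot align empty sequences")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=params.match,
        mismatch_score=params.mismatch,
        open_gap_score=params.gap_open + params.gap_extend,
        extend_gap_score=params.gap_extend,
    )
    aln = aligner.align(reference.residues, target.residues)[0]
    return PairwiseAlignment(
        reference_id=reference.id,
        target_id=target.id,
        aligned_reference=str(aln[0]),
        aligned_target=str(aln[1]),
        score=float(aln.score),
    )


def _column_maps(alignment: PairwiseAlignment) -> tuple[list[int], list[int]]:
    """Per-column 1-based reference and target coordinates (0 at gaps)."""
    ref_pos, tgt_pos = [], []
    r = t = 0
    for a, b in zip(alignment.aligned_reference, alignment.aligned_target):
        if a != "-":
            r += 1
        if b != "-":
            t += 1
        ref_pos.append(r if a != "-" else 0)
        tgt_pos.append(t if b != "-" else 0)
    return ref_pos, tgt_pos


def map_position(alignment: PairwiseAlignment, reference_position: int) -> int | None:
    """Target coordinate of the column holding ``reference_position``.

    Returns ``None`` when the column pairs the reference residue with a
    target gap (the site is deleted in the target).
    """
    ref_len = sum(1 for a in alignment.aligned_reference if a != "-")
    if not (1 <= reference_position <= ref_len):
        raise SequenceError(
            f"reference position {reference_position} outside 1..{ref_len}"
        )
    ref_pos, tgt_pos = _column_maps(alignment)
    col = ref_pos.index(reference_position)
    return tgt_pos[col] or None


def transfer_sites(
    alignment: PairwiseAlignment,
    reference_sites: list[ModificationSite],
    target: RnaSequence,
    context_window: int = 5,
    min_context_identity: float = 0.8,
) -> tuple[list[ModificationSite], list[tuple[ModificationSite, str]]]:
    """Lift reference sites through the alignment onto the target rRNA.

    Returns ``(transferred, dropped)`` where each drop carries a reason code:
    ``deleted`` (target gap at the site column), ``nucleotide mismatch``
    (target residue differs from the reference site's, or psi not on U) or
    ``low context identity`` (< ``min_context_identity`` matching columns
    within +/- ``context_window`` of the site).
    """
    ref_pos, tgt_pos = _column_maps(alignment)
    col_of_ref = {p: i for i, p in enumerate(ref_pos) if p}
    transferred: list[ModificationSite] = []
    dropped: list[tuple[ModificationSite, str]] = []
    for site in reference_sites:
        if site.rrna_id != alignment.reference_id:
            raise SequenceError(
                f"site {site.label} references {site.rrna_id!r}, alignment "
                f"reference is {alignment.reference_id!r}"
            )
        col = col_of_ref[site.position]
        tpos = tgt_pos[col]
        if not tpos:
            dropped.append((site, "deleted"))
            continue
        tnuc = target.residues[tpos - 1]
        if tnuc != site.nucleotide or (site.mtype == "psi" and tnuc != "U"):
            dropped.append((site, "nucleotide mismatch"))
            continue
        lo = max(0, col - context_window)
        hi = min(len(ref_pos) - 1, col + context_window)
        cols = range(lo, hi + 1)
        matches = sum(
            1
            for i in cols
            if alignment.aligned_reference[i] == alignment.aligned_target[i] != "-"
        )
        if matches / len(cols) < min_context_identity:
            dropped.append((site, "low context identity"))
            continue
        transferred.append(
            ModificationSite(
                rrna_id=target.id,
                position=tpos,
                nucleotide=tnuc,
                mtype=site.mtype,
                provenance="transferred",
            )
        )
    for site, reason in dropped:
        logger.debug("site %s/%s dropped: %s", site.rrna_id, site.label, reason)
    return transferred, dropped


# ---------------------------------------------------------------------------
# Site table I/O (TSV: rrna_id, position, nucleotide, mtype, provenance)
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["rrna_id", "position", "nucleotide", "mtype", "provenance"]


def read_sites_tsv(path: str | Path) -> list[ModificationSite]:
    df = pd.read_csv(path, sep="\t")
    return [
        ModificationSite(
            rrna_id=row.rrna_id,
            position=int(row.position),
            nucleotide=row.nucleotide,
            mtype=row.mtype,
            provenance=getattr(row, "provenance", "reference"),
        )
        for row in df.itertuples(index=False)
    ]


def sites_to_frame(sites: list[ModificationSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rrna_id": s.rrna_id,
                "position": s.position,
                "nucleotide": s.nucleotide,
                "mtype": s.mtype,
                "provenance": s.provenance,
            }
            for s in sites
        ],
        columns=SITE_COLUMNS,
    )


def write_sites_tsv(sites: list[ModificationSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def validate_site(site: ModificationSite, rrna: RnaSequence) -> bool:
    """Re-check the nucleotide invariant against the parent rRNA."""
    return (
        site.rrna_id == rrna.id
        and 1 <= site.position <= len(rrna)
        and rrna.residues[site.position - 1] == site.nucleotide
    )
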