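"""C/D and H/ACA box snoRNA candidate detection on transcripts.

C/D box snoRNAs carry a 5' C box (RUGAUGA) and a 3' D box (CUGA), often
with less conserved internal C'/D' copies; H/ACA box snoRNAs fold into a
hairpin-hinge-hairpin-tail architecture with an H box (ANANNA) in the
hinge and an ACA motif near the 3' end.  Candidates are 50-300 nt.

Secondary structure is assessed by complementary-segment search (Watson-
Crick plus GU wobble): a hairpin is an outer stem of at least
``min_stem_pairs`` contiguous pairs, optionally split by an internal loop
(the pseudouridylation pocket) from an upper stem.  A Nussinov-style
dynamic program supplies the maximal nested pairing count of each hairpin
region, used downstream for structure bonuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .sequences_io import (
    GenomicContext,
    RnaSequence,
    SequenceError,
    match_degenerate,
)

#: Box consensus motifs (degenerate IUPAC).
BOX_CONSENSUS = {
    "C": "RUGAUGA",
    "Cprime": "RUGAUGA",
    "D": "CUGA",
    "Dprime": "CUGA",
    "H": "ANANNA",
    "ACA": "ACA",
}

#: Admissible base pairs: Watson-Crick plus GU wobble.
WC_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
GU_PAIRS = {("G", "U"), ("U", "G")}


def can_pair(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS or (a, b) in GU_PAIRS


@dataclass(frozen=True)
class BoxMotif:
    """A box occurrence on the candidate's transcript (1-based inclusive)."""

    kind: str
    start: int
    end: int
    seq: str
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.kind not in BOX_CONSENSUS:
            raise SequenceError(f"unknown box kind {self.kind!r}")
        if self.end - self.start + 1 != len(BOX_CONSENSUS[self.kind]):
            raise SequenceError(
                f"{self.kind} box must span {len(BOX_CONSENSUS[self.kind])} nt"
            )


@dataclass(frozen=True)
class Hairpin:
    """One hairpin: outer stem, optional internal loop (pocket) + upper stem.

    All coordinates are 1-based inclusive on the parent transcript.
    ``pairs`` is the maximal nested pairing count of the hairpin region.
    """

    start: int
    end: int
    stem5: tuple[int, int]
    stem3: tuple[int, int]
    loop: tuple[int, int]
    pairs: int
    upper5: tuple[int, int] | None = None
    upper3: tuple[int, int] | None = None
    pocket5: tuple[int, int] | None = None
    pocket3: tuple[int, int] | None = None

    @property
    def has_pocket(self) -> bool:
        return self.pocket5 is not None and self.pocket3 is not None


@dataclass(frozen=True)
class StemAnnotation:
    """Hairpin-hinge-hairpin-tail annotation of an H/ACA candidate region."""

    hairpins: tuple[Hairpin, ...]
    hinge: tuple[int, int] | None = None
    tail: tuple[int, int] | None = None
    #: alternative decompositions per hairpin slot, for robust pocket search
    alternatives: tuple[tuple[Hairpin, ...], ...] = ()


@dataclass
class SnoRnaCandidate:
    """A located snoRNA candidate (C/D or H/ACA)."""

    id: str
    context: GenomicContext
    subfamily: str  # "CD" | "HACA"
    boxes: list[BoxMotif]
    sequence: str
    structure: StemAnnotation | None = None
    score: float | None = None
    cls: str = "unclassified"  # guide | orphan | unclassified
    group: str | None = None  # redundancy group (assembly subcomponent)

    @property
    def length(self) -> int:
        return self.context.length

    @property
    def total_box_mismatches(self) -> int:
        return sum(b.mismatches for b in self.boxes)

    def box(self, kind: str) -> BoxMotif | None:
        for b in self.boxes:
            if b.kind == kind:
                return b
        return None

    def to_local(self, transcript_pos: int) -> int:
        """Convert a transcript coordinate to a candidate-local one."""
        return transcript_pos - self.context.start + 1


@dataclass(frozen=True)
class ScanConfig:
    len_min: int = 50
    len_max: int = 300
    flank: int = 4  # candidate span extension beyond the terminal boxes
    c_mismatch: int = 1
    d_mismatch: int = 0
    internal_mismatch: int = 1  # C'/D' allowance
    h_mismatch: int = 1
    aca_mismatch: int = 0
    cd_gap_min: int = 8
    cd_gap_max: int = 292
    min_stem_pairs: int = 4
    min_loop: int = 3
    tail_offset: int = 3  # ACA ends this many nt before the candidate 3' end
    hairpin_max_span: int = 60  # search window for the 5' hairpin
    top_k_stems: int = 3
    pocket_min: int = 5
    pocket_max: int = 13


def find_boxes(seq: RnaSequence | str, kind: str, max_mismatch: int) -> list[BoxMotif]:
    """All windows matching the box consensus with <= max_mismatch, sorted."""
    if kind not in BOX_CONSENSUS:
        raise SequenceError(f"unknown box kind {kind!r}")
    residues = seq.residues if isinstance(seq, RnaSequence) else seq
    pattern = BOX_CONSENSUS[kind]
    w = len(pattern)
    hits: list[BoxMotif] = []
    for i in range(len(residues) - w + 1):
        window = residues[i : i + w]
        mm = match_degenerate(pattern, window)
        if mm <= max_mismatch:
            hits.append(BoxMotif(kind, i + 1, i + w, window, mm))
    return hits


# ---------------------------------------------------------------------------
# Structure: complementary-segment search + nested-pairing maximization
# ---------------------------------------------------------------------------

def max_nested_pairs(s: str, min_loop: int = 3) -> int:
    """Maximal number of nested base pairs (WC + GU) with a minimum hairpin
    loop of ``min_loop`` unpaired nucleotides (Nussinov-style DP)."""
    n = len(s)
    if n == 0:
        return 0
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            if can_pair(s[i], s[j]):
                best = max(best, 1 + dp[i + 1][j - 1])
            for k in range(i, j):
                cand = dp[i][k] + dp[k + 1][j]
                if cand > best:
                    best = cand
            dp[i][j] = best
    return dp[0][n - 1]


def _maximal_stems(
    residues: str, lo: int, hi: int, min_pairs: int, min_loop: int
) -> list[tuple[int, int, int]]:
    """Maximal contiguous complementary segment pairs within [lo, hi].

    Returns (i, j, k) with 1-based outer pair (i, j) and stem length k:
    positions (i+t, j-t) pair for t in 0..k-1, and the enclosed gap between
    the stem's inner ends is >= min_loop.  Only runs that cannot be extended
    outward are reported, sorted by (pairs desc, start asc, end desc).
    """
    s = residues
    stems: list[tuple[int, int, int]] = []
    for i in range(lo, hi + 1):
        for j in range(hi, i + min_loop, -1):
            a, b = s[i - 1], s[j - 1]
            if not can_pair(a, b):
                continue
            # skip non-maximal starts (extendable outward within the region)
            if i > lo and j < hi and can_pair(s[i - 2], s[j]):
                continue
            k = 0
            while (
                i + k <= j - k - min_loop - 1
                and can_pair(s[i + k - 1], s[j - k - 1])
            ):
                k += 1
            if k >= min_pairs:
                stems.append((i, j, k))
    stems.sort(key=lambda t: (-t[2], t[0], -t[1]))
    return stems


def _annotate_hairpin(
    residues: str, outer: tuple[int, int, int], cfg: ScanConfig
) -> list[Hairpin]:
    """Hairpin variants for one outer stem: one per admissible upper-stem
    choice (alternative internal-loop decompositions), plus the pocketless
    arrangement."""
    i, j, k = outer
    inner_lo, inner_hi = i + k, j - k  # region enclosed by the outer stem
    pairs = max_nested_pairs(residues[i - 1 : j], cfg.min_loop)
    base = dict(
        start=i,
        end=j,
        stem5=(i, i + k - 1),
        stem3=(j - k + 1, j),
        loop=(i + k, j - k),
        pairs=pairs,
    )
    variants: list[Hairpin] = []
    if inner_hi - inner_lo + 1 >= 2 * cfg.min_stem_pairs + cfg.min_loop:
        uppers = _maximal_stems(
            residues, inner_lo, inner_hi, cfg.min_stem_pairs, cfg.min_loop
        )
        for ui, uj, uk in uppers[: cfg.top_k_stems]:
            gap5 = ui - inner_lo  # unpaired run between outer and upper, 5' side
            gap3 = inner_hi - uj
            if gap5 >= 1 and gap3 >= 1:
                variants.append(
                    Hairpin(
                        **base,
                        upper5=(ui, ui + uk - 1),
                        upper3=(uj - uk + 1, uj),
                        pocket5=(inner_lo, ui - 1),
                        pocket3=(uj + 1, inner_hi),
                    )
                )
    variants.append(Hairpin(**base))
    return variants


def find_hairpins(
    residues: str, lo: int, hi: int, cfg: ScanConfig = ScanConfig()
) -> list[Hairpin]:
    """Alternative hairpin annotations within [lo, hi] (1-based): the top-k
    outer stems, each with its alternative internal-loop decompositions."""
    if hi - lo + 1 < 2 * cfg.min_stem_pairs + cfg.min_loop:
        return []
    stems = _maximal_stems(residues, lo, hi, cfg.min_stem_pairs, cfg.min_loop)
    out: list[Hairpin] = []
    for st in stems[: cfg.top_k_stems]:
        out.extend(_annotate_hairpin(residues, st, cfg))
    return out


def fold_stems(
    region: str | RnaSequence, cfg: ScanConfig = ScanConfig()
) -> StemAnnotation | None:
    """Best one- or two-hairpin arrangement of a region, or ``None``.

    The first hairpin is the best complementary-segment stem anywhere in the
    region; a second hairpin is searched to its right.  ``None`` when no
    stem reaches ``min_stem_pairs``.
    """
    residues = region.residues if isinstance(region, RnaSequence) else region
    first = find_hairpins(residues, 1, len(residues), cfg)
    if not first:
        return None
    hp1 = first[0]
    second = find_hairpins(residues, hp1.end + 1, len(residues), cfg)
    if second:
        hp2 = second[0]
        return StemAnnotation(
            hairpins=(hp1, hp2),
            hinge=(hp1.end + 1, hp2.start - 1),
            tail=(hp2.end + 1, len(residues)) if hp2.end < len(residues) else None,
            alternatives=(tuple(first), tuple(second)),
        )
    return StemAnnotation(hairpins=(hp1,), alternatives=(tuple(first),))


# ---------------------------------------------------------------------------
# Candidate scanning
# ---------------------------------------------------------------------------

def _resolve_overlaps(candidates: list[SnoRnaCandidate]) -> list[SnoRnaCandidate]:
    """Keep one candidate per locus: among candidates sharing > 50% of the
    shorter span, prefer fewer total box mismatches, then longer span, then
    leftmost start."""
    ranked = sorted(
        candidates,
        key=lambda c: (c.total_box_mismatches, -c.length, c.context.start, c.id),
    )
    kept: list[SnoRnaCandidate] = []
    for cand in ranked:
        clash = False
        for other in kept:
            ov = cand.context.overlap(other.context)
            if ov > 0.5 * min(cand.length, other.length):
                clash = True
                break
        if not clash:
            kept.append(cand)
    kept.sort(key=lambda c: (c.context.transcript_id, c.context.start))
    return kept


def _candidate_id(seq_id: str, start: int, end: int, subfamily: str) -> str:
    return f"{seq_id}:{start}-{end}:{subfamily}"


def scan_cd(seq: RnaSequence, cfg: ScanConfig = ScanConfig()) -> list[SnoRnaCandidate]:
    """C/D box candidates: a C box and a downstream D box whose +/-flank
    span satisfies the length bounds, with internal D'/C' copies attached
    when present.  Overlapping calls are resolved to one per locus."""
    n = len(seq)
    if n < cfg.len_min:
        return []
    c_hits = find_boxes(seq, "C", cfg.c_mismatch)
    d_hits = find_boxes(seq, "D", cfg.d_mismatch)
    raw: list[SnoRnaCandidate] = []
    for c in c_hits:
        for d in d_hits:
            gap = d.start - c.end - 1
            if gap < cfg.cd_gap_min or gap > cfg.cd_gap_max:
                continue
            start = max(1, c.start - cfg.flank)
            end = min(n, d.end + cfg.flank)
            length = end - start + 1
            if not (cfg.len_min <= length <= cfg.len_max):
                continue
            boxes = [c, d]
            # internal copies: canonical order is C ... D' ... C' ... D
            if gap >= 2 * len(BOX_CONSENSUS["Dprime"]):
                interior = seq.residues[c.end : d.start - 1]
                dp_hits = find_boxes(interior, "Dprime", cfg.internal_mismatch)
                dp = min(dp_hits, key=lambda b: (b.mismatches, b.start), default=None)
                if dp is not None:
                    dp = replace(dp, start=dp.start + c.end, end=dp.end + c.end)
                    boxes.append(dp)
                    cp_zone = seq.residues[dp.end : d.start - 1]
                    cp_hits = find_boxes(cp_zone, "Cprime", cfg.internal_mismatch)
                    cp = min(
                        cp_hits, key=lambda b: (b.mismatches, b.start), default=None
                    )
                    if cp is not None:
                        boxes.append(
                            replace(cp, start=cp.start + dp.end, end=cp.end + dp.end)
                        )
            raw.append(
                SnoRnaCandidate(
                    id=_candidate_id(seq.id, start, end, "CD"),
                    context=GenomicContext(seq.id, start, end),
                    subfamily="CD",
                    boxes=boxes,
                    sequence=seq.residues[start - 1 : end],
                )
            )
    return _resolve_overlaps(raw)


def scan_haca(seq: RnaSequence, cfg: ScanConfig = ScanConfig()) -> list[SnoRnaCandidate]:
    """H/ACA candidates: an ACA motif ending ``tail_offset`` nt before the
    candidate 3' end, an H box in the hinge, and a validated hairpin on
    each side of the H box."""
    n = len(seq)
    if n < cfg.len_min:
        return []
    aca_hits = find_boxes(seq, "ACA", cfg.aca_mismatch)
    h_hits = find_boxes(seq, "H", cfg.h_mismatch)
    raw: list[SnoRnaCandidate] = []
    for aca in aca_hits:
        cand_end = aca.end + cfg.tail_offset
        if cand_end > n:
            continue
        for h in h_hits:
            if h.end >= aca.start:
                continue
            hp2_region = (h.end + 1, aca.start - 1)
            if hp2_region[1] - hp2_region[0] + 1 < 2 * cfg.min_stem_pairs + cfg.min_loop:
                continue
            hp2_alts = find_hairpins(seq.residues, *hp2_region, cfg)
            if not hp2_alts:
                continue
            lo = max(1, h.start - cfg.hairpin_max_span)
            hp1_alts = find_hairpins(seq.residues, lo, h.start - 1, cfg)
            if not hp1_alts:
                continue
            hp1, hp2 = hp1_alts[0], hp2_alts[0]
            start = hp1.start
            length = cand_end - start + 1
            if not (cfg.len_min <= length <= cfg.len_max):
                continue
            structure = StemAnnotation(
                hairpins=(hp1, hp2),
                hinge=(hp1.end + 1, hp2.start - 1),
                tail=(aca.end + 1, cand_end),
                alternatives=(tuple(hp1_alts), tuple(hp2_alts)),
            )
            raw.append(
                SnoRnaCandidate(
                    id=_candidate_id(seq.id, start, cand_end, "HACA"),
                    context=GenomicContext(seq.id, start, cand_end),
                    subfamily="HACA",
                    boxes=[h, aca],
                    sequence=seq.residues[start - 1 : cand_end],
                    structure=structure,
                )
            )
    return _resolve_overlaps(raw)


def scan_transcripts(
    transcripts: list[RnaSequence],
    subfamily: str = "both",
    cfg: ScanConfig = ScanConfig(),
) -> list[SnoRnaCandidate]:
    """Scan a transcript repertoire; deterministic and order-invariant
    (results are sorted by transcript id, then start)."""
    out: list[SnoRnaCandidate] = []
    for seq in sorted(transcripts, key=lambda s: s.id):
        if subfamily in ("cd", "both"):
            out.extend(scan_cd(seq, cfg))
        if subfamily in ("haca", "both"):
            out.extend(scan_haca(seq, cfg))
    out.sort(key=lambda c: (c.context.transcript_id, c.context.start, c.subfamily))
    return out
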