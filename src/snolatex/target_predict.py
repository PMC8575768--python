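"""Guide-rRNA duplex prediction, modified-site calling and classification.

C/D box snoRNAs pair an antisense element -- the stretch immediately
upstream of, and including the first nucleotide of, the D or D' box --
with the rRNA; the rRNA nucleotide paired to the guide position five
nucleotides upstream of the D/D' box receives the 2'-O-methylation
(the D+5 rule).  H/ACA snoRNAs present two pocket strands (the internal
loop of a hairpin) that clamp the rRNA around an unpaired UN dinucleotide;
the bracketed U is isomerized to pseudouridine.

Admissible duplexes are contiguous and antiparallel with at most one
mismatch and at most two GU wobble pairs; bulges are not allowed.  Scores
are a documented repo default (Watson-Crick +2, GU +1, mismatch -2, plus a
capped stem bonus for H/ACA) calibrated so that a canonical 9-12 nt
perfect C/D duplex clears the C/D guide threshold (14) and a two-pocket
H/ACA guide with designed stems clears the H/ACA threshold (40).  Guide
thresholds are strict (>); candidates overlapping an exon use the higher
thresholds compared inclusively (>=).
"""

from __future__ import annotations

from dataclasses import dataclass

from .modsite_transfer import ModificationSite
from .sequences_io import RnaSequence, SequenceError, logger
from .sno_scan import GU_PAIRS, WC_PAIRS, ScanConfig, SnoRnaCandidate


@dataclass(frozen=True)
class GuideElement:
    """An antisense element, 1-based inclusive on the candidate."""

    candidate_id: str
    box_kind: str  # D | Dprime | pocket5 | pocket3
    start: int
    end: int
    residues: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.residues):
            raise SequenceError("guide coordinates do not match residues")


@dataclass
class DuplexAssignment:
    """A contiguous antiparallel guide<->rRNA duplex with pair accounting."""

    candidate_id: str
    guide: GuideElement
    rrna_id: str
    target_start: int
    target_end: int
    pairing: dict[int, int]  # guide-local position -> rRNA position
    wc_pairs: int
    gu_pairs: int
    mismatches: int
    site: ModificationSite | None = None
    score: float | None = None


@dataclass(frozen=True)
class PsiCall:
    """A pseudouridylation call: the bracketed U plus both pocket duplexes."""

    site: ModificationSite
    duplexes: tuple[DuplexAssignment, DuplexAssignment]
    score: float


@dataclass(frozen=True)
class DuplexConfig:
    min_guide: int = 9
    max_guide: int = 21
    max_mismatch: int = 1
    max_gu: int = 2
    #: D+5 rule: methylated rRNA base pairs the guide nucleotide this many
    #: positions upstream of the D/D' box first nucleotide.
    methyl_offset: int = 5
    pocket_distance_min: int = 13
    pocket_distance_max: int = 17


@dataclass(frozen=True)
class DuplexWeights:
    wc: float = 2.0
    gu: float = 1.0
    mismatch: float = -2.0
    stem_bonus_cap: float = 10.0


@dataclass(frozen=True)
class ScoreThresholds:
    cd_guide: float = 14.0
    haca_guide: float = 40.0
    cd_guide_exon: float = 20.0
    haca_guide_exon: float = 45.0

    def __post_init__(self) -> None:
        if self.cd_guide_exon < self.cd_guide or self.haca_guide_exon < self.haca_guide:
            raise SequenceError("exon thresholds must be >= plain thresholds")


def extract_guides(
    candidate: SnoRnaCandidate, cfg: DuplexConfig = DuplexConfig()
) -> list[GuideElement]:
    """Antisense elements of a candidate (candidate-local coordinates).

    C/D: one element per D/D' box, spanning up to ``max_guide`` nt and
    ending at the box's first nucleotide (included); bounded on the left by
    the previous box.  H/ACA: the two pocket strands of each hairpin
    carrying an internal loop.
    """
    guides: list[GuideElement] = []
    if candidate.subfamily == "CD":
        ordered = sorted(candidate.boxes, key=lambda b: b.start)
        for idx, box in enumerate(ordered):
            if box.kind not in ("D", "Dprime"):
                continue
            end = candidate.to_local(box.start)  # first D-box nt included
            prev_end = candidate.to_local(ordered[idx - 1].end) if idx else 0
            start = max(prev_end + 1, end - cfg.max_guide + 1, 1)
            if end - start + 1 < cfg.min_guide:
                logger.debug(
                    "candidate %s: %s guide too short, skipped", candidate.id, box.kind
                )
                continue
            guides.append(
                GuideElement(
                    candidate_id=candidate.id,
                    box_kind=box.kind,
                    start=start,
                    end=end,
                    residues=candidate.sequence[start - 1 : end],
                )
            )
    elif candidate.subfamily == "HACA":
        if candidate.structure is None:
            logger.debug("candidate %s has no structure annotation", candidate.id)
            return []
        for hp in candidate.structure.hairpins:
            if not hp.has_pocket:
                continue
            for kind, (s, e) in (("pocket5", hp.pocket5), ("pocket3", hp.pocket3)):
                ls, le = candidate.to_local(s), candidate.to_local(e)
                guides.append(
                    GuideElement(
                        candidate_id=candidate.id,
                        box_kind=kind,
                        start=ls,
                        end=le,
                        residues=candidate.sequence[ls - 1 : le],
                    )
                )
    if not guides:
        logger.debug("candidate %s yielded no guide elements", candidate.id)
    return guides


def _pair_kind(g: str, t: str) -> str:
    if (g, t) in WC_PAIRS:
        return "wc"
    if (g, t) in GU_PAIRS:
        return "gu"
    return "mm"


def enumerate_duplexes(
    guide: GuideElement, rrna: RnaSequence, cfg: DuplexConfig = DuplexConfig()
) -> list[DuplexAssignment]:
    """All admissible duplexes of the guide against one rRNA.

    Sub-guides are 3'-anchored suffixes of the element (the end of a C/D
    guide is pinned to the D-box first nucleotide) of every admissible
    length; each is slid over all rRNA windows of equal length and kept
    when the antiparallel pairing shows <= ``max_mismatch`` mismatches and
    <= ``max_gu`` GU pairs.  Duplexes are contiguous, so bulges cannot
    occur by construction.
    """
    if rrna.role not in ("rRNA", "pre-rRNA"):
        raise SequenceError(f"{rrna.id!r} is not an rRNA (role={rrna.role})")
    out: list[DuplexAssignment] = []
    g_full = guide.residues
    r = rrna.residues
    max_len = min(cfg.max_guide, len(g_full))
    for L in range(cfg.min_guide, max_len + 1):
        sub = g_full[len(g_full) - L :]
        for s in range(len(r) - L + 1):
            wc = gu = mm = 0
            for i in range(L):
                kind = _pair_kind(sub[i], r[s + L - 1 - i])
                if kind == "wc":
                    wc += 1
                elif kind == "gu":
                    gu += 1
                    if gu > cfg.max_gu:
                        break
                else:
                    mm += 1
                    if mm > cfg.max_mismatch:
                        break
            else:
                pairing = {
                    guide.end - (L - 1 - i): s + L - i for i in range(L)
                }
                out.append(
                    DuplexAssignment(
                        candidate_id=guide.candidate_id,
                        guide=guide,
                        rrna_id=rrna.id,
                        target_start=s + 1,
                        target_end=s + L,
                        pairing=pairing,
                        wc_pairs=wc,
                        gu_pairs=gu,
                        mismatches=mm,
                    )
                )
    return out


def score_duplex(d: DuplexAssignment, weights: DuplexWeights = DuplexWeights()) -> float:
    score = (
        weights.wc * d.wc_pairs
        + weights.gu * d.gu_pairs
        + weights.mismatch * d.mismatches
    )
    d.score = score
    return score


def call_methylation_site(
    d: DuplexAssignment, rrna: RnaSequence, cfg: DuplexConfig = DuplexConfig()
) -> ModificationSite | None:
    """Apply the D+5 rule through the explicit pairing map.

    The guide element's 3' end is the D/D' box first nucleotide; the rRNA
    base paired to the guide position ``methyl_offset`` upstream of it is
    called as 2'-O-methylated.  ``None`` when the duplex does not cover
    that guide position.
    """
    guide_pos = d.guide.end - cfg.methyl_offset
    rpos = d.pairing.get(guide_pos)
    if rpos is None:
        logger.debug(
            "duplex %s@%s:%d-%d does not cover the D+%d guide position",
            d.candidate_id,
            d.rrna_id,
            d.target_start,
            d.target_end,
            cfg.methyl_offset,
        )
        return None
    site = ModificationSite(
        rrna_id=rrna.id,
        position=rpos,
        nucleotide=rrna.residues[rpos - 1],
        mtype="Nm",
        provenance="predicted",
    )
    d.site = site
    return site


def _pocket_duplex(
    candidate_id: str,
    guide: GuideElement,
    rrna: RnaSequence,
    t_start: int,
    t_end: int,
) -> tuple[DuplexAssignment, int, int, int] | None:
    """Pair a pocket strand antiparallel against rRNA [t_start, t_end]."""
    L = t_end - t_start + 1
    if L != len(guide.residues):
        return None
    g = guide.residues
    r = rrna.residues
    wc = gu = mm = 0
    for i in range(L):
        kind = _pair_kind(g[i], r[t_end - 1 - i])  # antiparallel: g 5'..3' vs r 3'..5'
        if kind == "wc":
            wc += 1
        elif kind == "gu":
            gu += 1
        else:
            mm += 1
    pairing = {guide.start + i: t_end - i for i in range(L)}
    return (
        DuplexAssignment(
            candidate_id=candidate_id,
            guide=guide,
            rrna_id=rrna.id,
            target_start=t_start,
            target_end=t_end,
            pairing=pairing,
            wc_pairs=wc,
            gu_pairs=gu,
            mismatches=mm,
        ),
        wc,
        gu,
        mm,
    )


def call_pseudouridylation_site(
    candidate: SnoRnaCandidate,
    rrna: RnaSequence,
    cfg: DuplexConfig = DuplexConfig(),
    scan_cfg: ScanConfig = ScanConfig(),
    weights: DuplexWeights = DuplexWeights(),
) -> list[PsiCall]:
    """Pseudouridylation pocket search for an H/ACA candidate.

    For each annotated hairpin (alternative decompositions included) whose
    pocket sits 13-17 nt upstream of its H or ACA box, every rRNA U is
    tested: the 3' pocket strand must clamp the flank 5' of the U and the
    5' pocket strand the flank starting two nucleotides 3' of it, leaving
    the UN dinucleotide unpaired.  The composite duplex obeys the same
    <= 1 mismatch / <= 2 GU / no-bulge rule.
    """
    if candidate.subfamily != "HACA" or candidate.structure is None:
        return []
    boxes = {b.kind: b for b in candidate.boxes}
    calls: list[PsiCall] = []
    seen: set[tuple[int, int, int]] = set()
    alts = candidate.structure.alternatives or (candidate.structure.hairpins,)
    r = rrna.residues
    for slot, hairpin_alts in enumerate(alts):
        box = boxes.get("H") if slot == 0 else boxes.get("ACA")
        if box is None:
            continue
        for hp in hairpin_alts:
            if not hp.has_pocket:
                continue
            p5s, p5e = hp.pocket5
            p3s, p3e = hp.pocket3
            l5, l3 = p5e - p5s + 1, p3e - p3s + 1
            if not (scan_cfg.pocket_min <= l5 <= scan_cfg.pocket_max):
                continue
            if not (scan_cfg.pocket_min <= l3 <= scan_cfg.pocket_max):
                continue
            dist = box.start - p3s
            if not (cfg.pocket_distance_min <= dist <= cfg.pocket_distance_max):
                continue
            key = (hp.pocket5[0], hp.pocket3[0], slot)
            if key in seen:
                continue
            seen.add(key)
            g5 = GuideElement(
                candidate.id,
                "pocket5",
                candidate.to_local(p5s),
                candidate.to_local(p5e),
                candidate.sequence[
                    candidate.to_local(p5s) - 1 : candidate.to_local(p5e)
                ],
            )
            g3 = GuideElement(
                candidate.id,
                "pocket3",
                candidate.to_local(p3s),
                candidate.to_local(p3e),
                candidate.sequence[
                    candidate.to_local(p3s) - 1 : candidate.to_local(p3e)
                ],
            )
            for p in range(l3 + 1, len(r) - l5 - 1 + 1):
                if r[p - 1] != "U":
                    continue
                d3 = _pocket_duplex(candidate.id, g3, rrna, p - l3, p - 1)
                if d3 is None:
                    continue
                d5 = _pocket_duplex(candidate.id, g5, rrna, p + 2, p + 1 + l5)
                if d5 is None:
                    continue
                mm = d3[3] + d5[3]
                gu = d3[2] + d5[2]
                if mm > cfg.max_mismatch or gu > cfg.max_gu:
                    continue
                site = ModificationSite(
                    rrna_id=rrna.id,
                    position=p,
                    nucleotide="U",
                    mtype="psi",
                    provenance="predicted",
                )
                score = score_duplex(d3[0], weights) + score_duplex(d5[0], weights)
                d3[0].site = site
                d5[0].site = site
                calls.append(PsiCall(site=site, duplexes=(d3[0], d5[0]), score=score))
    return calls


def haca_stem_bonus(
    candidate: SnoRnaCandidate,
    scan_cfg: ScanConfig = ScanConfig(),
    weights: DuplexWeights = DuplexWeights(),
) -> float:
    """+1 per stem pair beyond ``min_stem_pairs`` per hairpin, capped."""
    if candidate.structure is None:
        return 0.0
    extra = sum(
        max(0, hp.pairs - scan_cfg.min_stem_pairs)
        for hp in candidate.structure.hairpins
    )
    return min(weights.stem_bonus_cap, float(extra))


def classify_guide(
    candidate: SnoRnaCandidate,
    best_score: float | None,
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> str:
    """Guide/orphan call at the subfamily threshold.

    Plain thresholds are strict (score > 14 for C/D, > 40 for H/ACA); the
    higher exon thresholds are inclusive (>= 20 / >= 45).
    """
    if best_score is None:
        return "orphan"
    if candidate.subfamily == "CD":
        plain, exon = thresholds.cd_guide, thresholds.cd_guide_exon
    else:
        plain, exon = thresholds.haca_guide, thresholds.haca_guide_exon
    if candidate.context.exon_overlap:
        return "guide" if best_score >= exon else "orphan"
    return "guide" if best_score > plain else "orphan"


@dataclass
class TargetResult:
    """Target-prediction outcome for one candidate."""

    candidate: SnoRnaCandidate
    assignments: list[DuplexAssignment]
    sites: list[ModificationSite]
    score: float | None
    cls: str


def predict_targets(
    candidate: SnoRnaCandidate,
    rrnas: list[RnaSequence],
    cfg: DuplexConfig = DuplexConfig(),
    scan_cfg: ScanConfig = ScanConfig(),
    weights: DuplexWeights = DuplexWeights(),
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> TargetResult:
    """Full target prediction and classification for one candidate.

    The candidate score is the best duplex score (C/D) or the best
    two-pocket score plus the stem bonus (H/ACA); sites are called from
    the top-scoring assignments, the lexicographically first
    (rrna_id, position) being primary.
    """
    assignments: list[DuplexAssignment] = []
    sites: list[ModificationSite] = []
    best: float | None = None
    if candidate.subfamily == "CD":
        for guide in extract_guides(candidate, cfg):
            for rrna in rrnas:
                for d in enumerate_duplexes(guide, rrna, cfg):
                    score_duplex(d, weights)
                    assignments.append(d)
        if assignments:
            best = max(d.score for d in assignments)
            seen = set()
            for d in assignments:
                if d.score == best:
                    site = call_methylation_site(
                        d, next(r for r in rrnas if r.id == d.rrna_id), cfg
                    )
                    if site and (site.rrna_id, site.position) not in seen:
                        seen.add((site.rrna_id, site.position))
                        sites.append(site)
    else:
        bonus = haca_stem_bonus(candidate, scan_cfg, weights)
        calls: list[PsiCall] = []
        for rrna in rrnas:
            calls.extend(
                call_pseudouridylation_site(candidate, rrna, cfg, scan_cfg, weights)
            )
        if calls:
            best_pocket = max(c.score for c in calls)
            best = best_pocket + bonus
            seen = set()
            for c in calls:
                if c.score == best_pocket:
                    assignments.extend(c.duplexes)
                    key = (c.site.rrna_id, c.site.position)
                    if key not in seen:
                        seen.add(key)
                        sites.append(c.site)
    sites.sort(key=lambda s: (s.rrna_id, s.position))
    cls = classify_guide(candidate, best, thresholds)
    candidate.score = best
    candidate.cls = cls
    return TargetResult(
        candidate=candidate, assignments=assignments, sites=sites, score=best, cls=cls
    )
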