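"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design at desk scale: synthetic 18S/28S/
5.8S rRNA analogues with a reference modification-site catalogue and a
pre-rRNA spanning ITS1; transcripts carrying planted C/D and H/ACA
snoRNAs whose antisense elements are built against chosen rRNA sites (so
the scanner, duplex predictor and site caller have exact expected
answers); negative-binomial leaf/latex count tables with planted fold
changes and a pre-rRNA reference row; an F1 population whose per-snoRNA
expression has chosen Spearman correlation with TSC/C (Gaussian copula);
and continuous-tapping TSC series that decline sharply and plateau by 3 h.

Every plant is self-validated at generation time: the planted snoRNA must
be recovered by the scanner and produce the intended classification and
site call, and planted orphans must score below the guide threshold;
failing arrangements are resampled.  All randomness derives from the
master seed, so identical seeds give identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .modsite_transfer import (
    ModificationSite,
    PairwiseAlignment,
    global_align,
    transfer_sites,
    write_sites_tsv,
)
from .sequences_io import (
    CountTable,
    PRE_RRNA_ID,
    RnaSequence,
    SequenceError,
    reverse_complement_rna,
    write_fasta,
)
from .sno_scan import (
    BOX_CONSENSUS,
    ScanConfig,
    SnoRnaCandidate,
    can_pair,
    match_degenerate,
    scan_cd,
    scan_haca,
)
from .target_predict import (
    DuplexConfig,
    DuplexWeights,
    ScoreThresholds,
    predict_targets,
)
from .yield_analysis import TappingSeries

_BASES = np.array(list("ACGU"))


def _rand_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


# ---------------------------------------------------------------------------
# rRNAs and the reference site catalogue
# ---------------------------------------------------------------------------

#: Synthetic rRNA lengths approximating plant rRNA scale (config, not claims).
DEFAULT_LENGTHS = {"18S": 1800, "28S": 3400, "5.8S": 160}


def gen_rrna_and_sites(
    seed: int,
    lengths: dict[str, int] | None = None,
    n_nm: int = 80,
    n_psi: int = 16,
    its1_length: int = 200,
) -> tuple[list[RnaSequence], RnaSequence, list[ModificationSite]]:
    """Random rRNA analogues, a pre-rRNA spanning ITS1, and reference sites.

    Nm sites land on any residue; psi sites only on U.  Sites are unique,
    nucleotide-consistent and tagged provenance=reference.
    """
    rng = np.random.default_rng(seed)
    lengths = dict(lengths or DEFAULT_LENGTHS)
    rrnas = [
        RnaSequence(name, _rand_rna(rng, n), role="rRNA")
        for name, n in lengths.items()
    ]
    pre = RnaSequence(
        PRE_RRNA_ID,
        rrnas[0].residues + _rand_rna(rng, its1_length) + rrnas[-1].residues,
        role="pre-rRNA",
    )
    # allocate site counts proportionally to length
    total = sum(lengths.values())
    sites: list[ModificationSite] = []
    for mtype, n_sites in (("Nm", n_nm), ("psi", n_psi)):
        alloc = {r.id: int(round(n_sites * len(r) / total)) for r in rrnas}
        # fix rounding drift on the largest rRNA
        big = max(rrnas, key=len).id
        alloc[big] += n_sites - sum(alloc.values())
        for r in rrnas:
            if mtype == "psi":
                pool = [i + 1 for i, b in enumerate(r.residues) if b == "U"]
            else:
                pool = list(range(1, len(r) + 1))
            taken = {s.position for s in sites if s.rrna_id == r.id}
            pool = [p for p in pool if p not in taken]
            if alloc[r.id] > len(pool):
                raise SequenceError(f"requested sites exceed positions on {r.id}")
            for p in sorted(rng.choice(pool, size=alloc[r.id], replace=False)):
                sites.append(
                    ModificationSite(
                        rrna_id=r.id,
                        position=int(p),
                        nucleotide=r.residues[p - 1],
                        mtype=mtype,
                        provenance="reference",
                    )
                )
    sites.sort(key=lambda s: (s.rrna_id, s.position))
    return rrnas, pre, sites


def mutate_rrna(
    seed: int,
    target: RnaSequence,
    sites: list[ModificationSite],
    sub_rate: float = 0.03,
    n_indels: int = 3,
    indel_max: int = 4,
    ref_id_suffix: str = "_model",
) -> tuple[RnaSequence, list[ModificationSite], dict[int, int]]:
    """A model-organism rRNA analogue derived from the target.

    Point substitutions (sparing site positions and their +/-5 context) and
    a few short indels are applied; the returned coordinate map (target
    position -> reference position) and the reference-coordinate site
    catalogue are the ground truth for the homology-transfer stage.
    """
    rng = np.random.default_rng(seed)
    protected = set()
    site_pos = {s.position for s in sites if s.rrna_id == target.id}
    for p in site_pos:
        protected.update(range(p - 5, p + 6))
    bases = list(target.residues)
    n = len(bases)
    for i in range(n):
        if (i + 1) not in protected and rng.random() < sub_rate:
            bases[i] = rng.choice([b for b in "ACGU" if b != bases[i]])
    # indels between sites: record a map target_pos -> ref_pos
    eligible = [
        i
        for i in range(50, n - 50)
        if all((i + d + 1) not in protected for d in range(indel_max))
    ]
    indel_spots = sorted(int(x) for x in rng.choice(eligible, n_indels, replace=False))
    ops = {
        spot: ("ins" if rng.random() < 0.5 else "del", int(rng.integers(1, indel_max + 1)))
        for spot in indel_spots
    }
    ref_chars: list[str] = []
    coord_map: dict[int, int] = {}
    i = 0
    while i < n:
        if i in ops:
            kind, k = ops[i]
            if kind == "ins":  # extra bases present only in the reference
                ref_chars.extend(_rand_rna(rng, k))
            else:  # bases deleted from the reference
                i += k
                continue
        ref_chars.append(bases[i])
        coord_map[i + 1] = len(ref_chars)
        i += 1
    reference = RnaSequence(target.id + ref_id_suffix, "".join(ref_chars), role="rRNA")
    ref_sites = [
        ModificationSite(
            rrna_id=reference.id,
            position=coord_map[s.position],
            nucleotide=s.nucleotide,
            mtype=s.mtype,
            provenance="reference",
        )
        for s in sites
        if s.rrna_id == target.id and s.position in coord_map
    ]
    return reference, ref_sites, coord_map


# ---------------------------------------------------------------------------
# Motif hygiene
# ---------------------------------------------------------------------------

def _forbidden_windows(s: str, protected_boxes: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """0-based [start, end) windows that would confuse the box scanner:
    exact D boxes, C boxes within 1 mismatch, exact H boxes -- excluding
    the planted boxes themselves."""
    exempt = set(protected_boxes)
    out = []
    for i in range(len(s) - 3):
        if s[i : i + 4] == "CUGA" and (i, i + 4) not in exempt:
            out.append((i, i + 4))
    for i in range(len(s) - 6):
        w7 = s[i : i + 7]
        if match_degenerate("RUGAUGA", w7) <= 1 and (i, i + 7) not in exempt:
            out.append((i, i + 7))
        w6 = s[i : i + 6]
        if match_degenerate("ANANNA", w6) == 0 and (i, i + 6) not in exempt:
            out.append((i, i + 6))
    return out


def _sanitize(
    rng: np.random.Generator,
    seq: list[str],
    protected_positions: set[int],
    protected_boxes: list[tuple[int, int]],
    max_rounds: int = 200,
) -> bool:
    """Mutate mutable positions until no forbidden window with a mutable
    position remains.  Windows lying entirely in protected positions are
    left alone (they are handled by plant-level validation)."""
    for _ in range(max_rounds):
        dirty = False
        for ws, we in _forbidden_windows("".join(seq), protected_boxes):
            mutable = [i for i in range(ws, we) if i not in protected_positions]
            if not mutable:
                continue
            i = int(rng.choice(mutable))
            seq[i] = str(rng.choice([b for b in "ACGU" if b != seq[i]]))
            dirty = True
        if not dirty:
            return True
    return False


# ---------------------------------------------------------------------------
# Planted snoRNAs
# ---------------------------------------------------------------------------

@dataclass
class PlantedSnoRna:
    """Ground truth for one planted snoRNA."""

    id: str
    transcript_id: str
    group: str
    subfamily: str  # CD | HACA
    expected_class: str  # guide | orphan
    start: int  # candidate span on the transcript, 1-based inclusive
    end: int
    boxes: dict[str, tuple[int, int]]
    guide_span: tuple[int, int] | None = None  # transcript coords
    target_rrna: str | None = None
    target_position: int | None = None
    target_mtype: str | None = None
    blacklisted: bool = False
    latex_abundant: bool = False
    fold_change: float = 1.0


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the ground truth."""

    seed: int
    rrnas: list[RnaSequence]
    pre_rrna: RnaSequence
    sites: list[ModificationSite]
    reference_rrna: RnaSequence
    reference_sites: list[ModificationSite]
    transcripts: list[RnaSequence]
    truth: list[PlantedSnoRna]
    blacklist: list[RnaSequence]
    counts: CountTable
    design_latex: tuple[str, ...]
    design_leaf: tuple[str, ...]
    population_expression: pd.DataFrame
    population_yield: pd.DataFrame
    rho_targets: dict[str, float]
    tapping: list[TappingSeries]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.rrnas + [self.pre_rrna, self.reference_rrna], out / "rrna.fa")
        write_fasta(self.transcripts, out / "transcripts.fa")
        write_fasta(self.blacklist, out / "blacklist.fa")
        write_sites_tsv(self.sites, out / "sites.tsv")
        write_sites_tsv(self.reference_sites, out / "reference_sites.tsv")
        self.counts.counts.to_csv(out / "counts.tsv", sep="\t")
        self.population_expression.to_csv(out / "population_expression.tsv", sep="\t")
        self.population_yield.to_csv(out / "population_yield.tsv", sep="\t", index=False)
        rows = []
        for s in self.tapping:
            rows += [
                {"tree_id": s.tree_id, "time_min": t, "tsc": v}
                for t, v in zip(s.times, s.tsc)
            ]
        pd.DataFrame(rows).to_csv(out / "tapping.tsv", sep="\t", index=False)
        truth = [asdict(t) for t in self.truth]
        (out / "truth.json").write_text(json.dumps(truth, indent=1, default=str))


def _make_cd_snorna(
    rng: np.random.Generator,
    rrna: RnaSequence,
    site: ModificationSite | None,
    guide_len: int = 12,
    mismatch_profile: str = "perfect",
) -> tuple[str, dict] | None:
    """One C/D snoRNA sequence; guide antisense to the window placing the
    D+5-paired base on ``site`` (or a scrambled guide for orphans)."""
    if site is not None:
        p = site.position
        w_start, w_end = p - 5, p - 5 + guide_len - 1
        if w_start < 1 or w_end > len(rrna):
            return None
        if rrna.residues[w_start - 1] != "G":  # D-box first nt must be C
            return None
        guide = reverse_complement_rna(rrna.slice1(w_start, w_end))
    else:
        guide = _rand_rna(rng, guide_len - 1) + "C"
    c_box = str(rng.choice(["AUGAUGA", "GUGAUGA"]))
    if mismatch_profile == "one_c_mismatch":
        i = int(rng.integers(1, 7))
        alt = [b for b in "ACGU" if match_degenerate("RUGAUGA"[i], b) > 0]
        c_box = c_box[:i] + str(rng.choice(alt)) + c_box[i + 1 :]
    spacer = _rand_rna(rng, int(rng.integers(25, 55)))
    flank5 = _rand_rna(rng, 4)
    flank3 = _rand_rna(rng, 4)
    seq = flank5 + c_box + spacer + guide + "UGA" + flank3
    c_start = 5  # 1-based within the snoRNA
    d_start = 4 + 7 + len(spacer) + guide_len  # guide's last nt = D first nt
    # spacer and terminal flanks may be mutated by motif sanitization
    mutable = set(range(0, 4)) | set(range(11, 11 + len(spacer)))
    mutable |= set(range(len(seq) - 4, len(seq)))
    info = {
        "boxes": {"C": (c_start, c_start + 6), "D": (d_start, d_start + 3)},
        "guide_span": (d_start - guide_len + 1, d_start),
        "length": len(seq),
        "mutable_local": mutable,
    }
    return seq, info


def _make_hairpin(rng: np.random.Generator, stem_len: int, loop_len: int) -> str:
    while True:
        stem5 = _rand_rna(rng, stem_len)
        loop = _rand_rna(rng, loop_len)
        stem3 = reverse_complement_rna(stem5)
        if not can_pair(loop[0], loop[-1]):  # keep the stem length exact
            return stem5 + loop + stem3


def _make_haca_snorna(
    rng: np.random.Generator,
    rrna: RnaSequence,
    site: ModificationSite | None,
    pocket_len: int = 8,
) -> tuple[str, dict] | None:
    """One H/ACA snoRNA: structural 5' hairpin, hinge H box, 3' hairpin
    whose internal-loop pockets clamp the target U (hairpin2 carries the
    guide), then ACA and a 3-nt tail."""
    pockets = None
    for plen in (pocket_len, pocket_len + 1):  # shorter pockets score < 40
        if site is not None:
            p = site.position
            if p - plen < 1 or p + 1 + plen > len(rrna):
                continue
            p3 = reverse_complement_rna(rrna.slice1(p - plen, p - 1))
            p5 = reverse_complement_rna(rrna.slice1(p + 2, p + 1 + plen))
        else:
            p3 = _rand_rna(rng, plen)
            p5 = _rand_rna(rng, plen)
        # the outer/upper stems must not be extendable into the pockets,
        # or the scanner would annotate shifted pocket boundaries
        if not can_pair(p5[0], p3[-1]) and not can_pair(p5[-1], p3[0]):
            pockets = (p5, p3)
            break
    if pockets is None:
        return None
    pocket5, pocket3 = pockets
    for _ in range(50):
        hp1 = _make_hairpin(rng, 8, 5)
        outer5 = _rand_rna(rng, 7)
        upper5 = _rand_rna(rng, 5)
        apical = _rand_rna(rng, 4)
        if not can_pair(apical[0], apical[-1]):
            break
    else:
        return None
    hp2 = (
        outer5
        + pocket5
        + upper5
        + apical
        + reverse_complement_rna(upper5)
        + pocket3
        + reverse_complement_rna(outer5)
    )
    h_box = "A" + _rand_rna(rng, 1) + "A" + _rand_rna(rng, 2) + "A"
    gap1, gap2, gap3 = _rand_rna(rng, 2), _rand_rna(rng, 2), _rand_rna(rng, 1)
    seq = hp1 + gap1 + h_box + gap2 + hp2 + gap3 + "ACA" + _rand_rna(rng, 3)
    h_start = len(hp1) + len(gap1) + 1
    aca_start = len(hp1) + len(gap1) + 6 + len(gap2) + len(hp2) + len(gap3) + 1
    info = {
        "boxes": {"H": (h_start, h_start + 5), "ACA": (aca_start, aca_start + 2)},
        "guide_span": None,
        "length": len(seq),
        "mutable_local": set(),  # structure/pockets are load-bearing
    }
    return seq, info


def _validate_plant(
    transcript: RnaSequence,
    plant: PlantedSnoRna,
    rrnas: list[RnaSequence],
    scan_cfg: ScanConfig,
    duplex_cfg: DuplexConfig,
    thresholds: ScoreThresholds,
) -> bool:
    """Self-validation: the plant must be recovered by its scanner and
    produce the intended class (and site, for guides)."""
    scan = scan_cd if plant.subfamily == "CD" else scan_haca
    best = None
    for cand in scan(transcript, scan_cfg):
        ov = max(
            0, min(cand.context.end, plant.end) - max(cand.context.start, plant.start) + 1
        )
        if ov > 0.5 * (plant.end - plant.start + 1):
            best = cand
            break
    if best is None:
        return False
    if plant.subfamily == "CD":
        got = {b.kind: (b.start, b.end) for b in best.boxes}
        for kind, span in plant.boxes.items():
            if got.get(kind) != span:
                return False
    res = predict_targets(
        best, rrnas, duplex_cfg, scan_cfg, DuplexWeights(), thresholds
    )
    if plant.expected_class == "guide":
        return res.cls == "guide" and any(
            s.rrna_id == plant.target_rrna and s.position == plant.target_position
            for s in res.sites
        )
    return res.cls == "orphan"


def plant_snornas(
    seed: int,
    rrnas: list[RnaSequence],
    sites: list[ModificationSite],
    n_cd_guide: int = 10,
    n_haca_guide: int = 5,
    n_orphan: int = 5,
    mismatch_profile: str = "perfect",
    n_decoy_transcripts: int = 10,
    scan_cfg: ScanConfig = ScanConfig(),
    duplex_cfg: DuplexConfig = DuplexConfig(),
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> tuple[list[RnaSequence], list[PlantedSnoRna]]:
    """Transcripts with planted, self-validated snoRNAs plus ground truth.

    Orphans are split between the subfamilies (C/D first).  Each plant
    lives on its own transcript (``comp<k>_c0_seq1``); decoy transcripts
    carry no plant.
    """
    rng = np.random.default_rng(seed)
    rrna_by_id = {r.id: r for r in rrnas}
    nm_sites = [s for s in sites if s.mtype == "Nm"]
    psi_sites = [s for s in sites if s.mtype == "psi"]
    rng.shuffle(nm_sites)
    rng.shuffle(psi_sites)
    n_cd_orphan = (n_orphan + 1) // 2
    n_haca_orphan = n_orphan - n_cd_orphan
    jobs = (
        [("CD", "guide")] * n_cd_guide
        + [("HACA", "guide")] * n_haca_guide
        + [("CD", "orphan")] * n_cd_orphan
        + [("HACA", "orphan")] * n_haca_orphan
    )
    transcripts: list[RnaSequence] = []
    truth: list[PlantedSnoRna] = []
    nm_iter = iter(nm_sites)
    psi_iter = iter(psi_sites)
    for k, (subfamily, cls) in enumerate(jobs, start=1):
        tid = f"comp{k}_c0_seq1"
        planted = None
        site = None
        site_tries = 0
        for attempt in range(120):
            if cls == "guide":
                pool = nm_iter if subfamily == "CD" else psi_iter
                if site is None or site_tries >= 8:
                    try:
                        site = next(pool)
                    except StopIteration:
                        raise SequenceError(
                            "not enough eligible reference sites for the requested plants"
                        )
                    site_tries = 0
                site_tries += 1
                rrna = rrna_by_id[site.rrna_id]
            else:
                rrna = rrna_by_id[str(rng.choice(list(rrna_by_id)))]
            if subfamily == "CD":
                made = _make_cd_snorna(
                    rng, rrna, site, mismatch_profile=mismatch_profile
                )
            else:
                made = _make_haca_snorna(rng, rrna, site)
            if made is None:
                site_tries = 8  # ineligible site geometry: take the next one
                continue
            sno, info = made
            if subfamily == "CD":
                flank5 = _rand_rna(rng, int(rng.integers(20, 40)))
                flank3 = _rand_rna(rng, int(rng.integers(20, 40)))
                residues = list(flank5 + sno + flank3)
                offset = len(flank5)
            else:
                flank5 = _rand_rna(rng, int(rng.integers(30, 70)))
                residues = list(flank5 + sno)  # HACA plants end the transcript
                offset = len(flank5)
            boxes = {
                kind: (s + offset, e + offset) for kind, (s, e) in info["boxes"].items()
            }
            protected = set(range(offset, offset + len(sno))) - {
                offset + i for i in info["mutable_local"]
            }
            protected_boxes = [(s - 1, e) for s, e in boxes.values()]
            if not _sanitize(rng, residues, protected, protected_boxes):
                continue
            transcript = RnaSequence(tid, "".join(residues))
            guide_span = info["guide_span"]
            plant = PlantedSnoRna(
                id=f"sno_{subfamily}_{cls}_{k}",
                transcript_id=tid,
                group=f"comp{k}_c0",
                subfamily=subfamily,
                expected_class=cls,
                start=offset + 1,
                end=offset + len(sno),
                boxes=boxes,
                guide_span=(
                    (guide_span[0] + offset, guide_span[1] + offset)
                    if guide_span
                    else None
                ),
                target_rrna=site.rrna_id if site else None,
                target_position=site.position if site else None,
                target_mtype=site.mtype if site else None,
            )
            if _validate_plant(
                transcript, plant, rrnas, scan_cfg, duplex_cfg, thresholds
            ):
                planted = (transcript, plant)
                break
        if planted is None:
            raise SequenceError(
                f"could not construct a valid {subfamily} {cls} plant "
                f"(unsatisfiable mismatch profile or site pool)"
            )
        transcripts.append(planted[0])
        truth.append(planted[1])
    for j in range(n_decoy_transcripts):
        tid = f"comp{len(jobs) + j + 1}_c0_seq1"
        transcripts.append(RnaSequence(tid, _rand_rna(rng, 250)))
    return transcripts, truth


# ---------------------------------------------------------------------------
# Counts, population and time courses
# ---------------------------------------------------------------------------

def simulate_counts(
    seed: int,
    feature_ids: list[str],
    latex_abundant: dict[str, float],
    n_latex: int = 3,
    n_leaf: int = 3,
    base_mean: float = 100.0,
    dispersion: float = 0.1,
    prerrna_depth: float = 10_000.0,
    depth_sigma: float = 0.25,
    base_means: dict[str, float] | None = None,
) -> tuple[CountTable, tuple[str, ...], tuple[str, ...]]:
    """Negative-binomial leaf/latex counts with planted fold changes.

    ``latex_abundant`` maps feature id -> latex/leaf mean ratio; other
    features have ratio 1.  Per-feature variance is ``m + dispersion*m^2``.
    Each sample carries a log-normal library-depth factor (sigma
    ``depth_sigma``) applied to every feature including the pre-rRNA
    reference, which itself is Poisson around ``prerrna_depth`` -- the
    reference tracks sampling depth tightly, which is exactly what makes
    it usable for normalization.
    """
    rng = np.random.default_rng(seed)
    latex_samples = tuple(f"latex_{i + 1}" for i in range(n_latex))
    leaf_samples = tuple(f"leaf_{i + 1}" for i in range(n_leaf))
    n_samples = n_latex + n_leaf
    depth = np.exp(rng.normal(0.0, depth_sigma, n_samples))
    rows = {}

    def nb(means: np.ndarray) -> np.ndarray:
        r = 1.0 / dispersion
        means = np.maximum(means, 1e-9)
        return rng.negative_binomial(r, r / (r + means))

    for fid in feature_ids:
        mu = (base_means or {}).get(fid, base_mean)
        fc = latex_abundant.get(fid, 1.0)
        means = mu * depth * np.concatenate(
            [np.full(n_latex, fc), np.ones(n_leaf)]
        )
        rows[fid] = nb(means)
    rows[PRE_RRNA_ID] = rng.poisson(prerrna_depth * depth)
    df = pd.DataFrame(rows, index=list(latex_samples + leaf_samples)).T
    # guard: the reference row must be positive everywhere
    df.loc[PRE_RRNA_ID] = np.maximum(df.loc[PRE_RRNA_ID], 1)
    return CountTable(df), latex_samples, leaf_samples


def simulate_population(
    seed: int,
    rho_targets: dict[str, float],
    n_trees: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gaussian-copula F1 population: log-normal expression per snoRNA with
    chosen Spearman correlation against TSC/C.

    For a bivariate Gaussian copula the Spearman correlation is
    ``(6/pi) * arcsin(r/2)``; the latent Pearson ``r`` is chosen by the
    inverse, ``r = 2 sin(pi * rho_s / 6)``, so realized Spearman values
    concentrate around the targets (within ~0.15 at n=50).
    """
    if any(abs(t) > 0.95 for t in rho_targets.values()):
        raise SequenceError("|rho targets| must be <= 0.95")
    rng = np.random.default_rng(seed)
    tree_ids = [f"tree_{i + 1:02d}" for i in range(n_trees)]
    z_yield = rng.standard_normal(n_trees)
    tsc_c = np.exp(0.9 + 0.35 * z_yield)
    circumference = np.exp(rng.normal(np.log(45.0), 0.08, size=n_trees))
    tsc = tsc_c * circumference
    expr = {}
    for sno_id, rho_s in rho_targets.items():
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        z = r * z_yield + np.sqrt(1.0 - r * r) * rng.standard_normal(n_trees)
        expr[sno_id] = np.exp(2.0 + 0.8 * z)
    expression = pd.DataFrame(expr, index=tree_ids).T
    yields = pd.DataFrame(
        {
            "tree_id": tree_ids,
            "tsc": tsc,
            "circumference": circumference,
            "tsc_c": tsc_c,
        }
    )
    return expression, yields


def simulate_timecourse(
    seed: int,
    n_trees: int = 14,
    interval_min: int = 30,
    sharp_drop_points: int = 6,
    n_points: int = 12,
    plateau_level: float = 2.0,
    drop_factor: float = 5.0,
    noise_cv: float = 0.05,
) -> list[TappingSeries]:
    """Continuous-tapping TSC series: a strictly decreasing head over the
    first ``sharp_drop_points`` tappings, then a noisy plateau (reached by
    the 3-h tapping at 30-min intervals)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_trees):
        plateau = plateau_level * float(np.exp(rng.normal(0, 0.25))) if noise_cv else plateau_level
        times = tuple(float(interval_min * (k + 1)) for k in range(n_points))
        values = []
        for k in range(n_points):
            if k < sharp_drop_points - 1:
                frac = (sharp_drop_points - 1 - k) / (sharp_drop_points - 1)
                v = plateau * (1.0 + (drop_factor - 1.0) * frac ** 1.5)
                if noise_cv:
                    v *= float(np.exp(rng.normal(0, noise_cv / 2)))
            else:
                v = plateau * (
                    float(np.exp(rng.normal(0, noise_cv))) if noise_cv else 1.0
                )
            values.append(v)
        # enforce the strictly decreasing head
        for k in range(sharp_drop_points - 1, 0, -1):
            if values[k - 1] <= values[k]:
                values[k - 1] = values[k] * 1.05
        out.append(TappingSeries(f"tree_{i + 1:02d}", times, tuple(values)))
    return out


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def make_bundle(
    seed: int = 42,
    n_cd_guide: int = 10,
    n_haca_guide: int = 5,
    n_orphan: int = 5,
    n_blacklisted: int = 2,
    fc_latex_abundant: float = 4.0,
    n_trees: int = 50,
    scan_cfg: ScanConfig = ScanConfig(),
    duplex_cfg: DuplexConfig = DuplexConfig(),
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> SyntheticBundle:
    """The default study bundle: rRNAs + sites, planted transcripts
    (plus ``n_blacklisted`` extra guide plants copied into the EST/rRNA
    blacklist), counts, population and tapping series."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    rrnas, pre, sites = gen_rrna_and_sites(seeds[0])
    reference, ref_sites, _ = mutate_rrna(seeds[1], rrnas[0], sites)
    transcripts, truth = plant_snornas(
        seeds[2],
        rrnas,
        sites,
        n_cd_guide=n_cd_guide + n_blacklisted,
        n_haca_guide=n_haca_guide,
        n_orphan=n_orphan,
        scan_cfg=scan_cfg,
        duplex_cfg=duplex_cfg,
        thresholds=thresholds,
    )
    rng = np.random.default_rng(seeds[3])
    # the last n_blacklisted CD guide plants are leaked into the blacklist
    cd_guides = [t for t in truth if t.subfamily == "CD" and t.expected_class == "guide"]
    blacklisted = cd_guides[len(cd_guides) - n_blacklisted :] if n_blacklisted else []
    blacklist: list[RnaSequence] = [
        RnaSequence(f"EST_{i + 1}", _rand_rna(rng, 500)) for i in range(5)
    ]
    tx_by_id = {t.id: t for t in transcripts}
    for i, plant in enumerate(blacklisted):
        plant.blacklisted = True
        seq = tx_by_id[plant.transcript_id].slice1(plant.start, plant.end)
        blacklist.append(RnaSequence(f"EST_sno_{i + 1}", seq))
    # counts: every transcript is a feature; guide plants not blacklisted
    # are the latex-abundant set
    abundant = {
        t.transcript_id: fc_latex_abundant
        for t in truth
        if t.expected_class == "guide" and not t.blacklisted
    }
    for t in truth:
        t.latex_abundant = t.transcript_id in abundant
        t.fold_change = abundant.get(t.transcript_id, 1.0)
    counts, latex_samples, leaf_samples = simulate_counts(
        seeds[4], [t.id for t in transcripts], abundant
    )
    # population: planted latex-abundant snoRNAs, half with positive rho
    ab_ids = sorted(abundant)
    rho_targets: dict[str, float] = {}
    for i, sid in enumerate(ab_ids):
        rho_targets[sid] = 0.65 if i % 2 == 0 else 0.0
    expression, yields = simulate_population(seeds[5], rho_targets, n_trees=n_trees)
    tapping = simulate_timecourse(seeds[6])
    return SyntheticBundle(
        seed=seed,
        rrnas=rrnas,
        pre_rrna=pre,
        sites=sites,
        reference_rrna=reference,
        reference_sites=ref_sites,
        transcripts=transcripts,
        truth=truth,
        blacklist=blacklist,
        counts=counts,
        design_latex=latex_samples,
        design_leaf=leaf_samples,
        population_expression=expression,
        population_yield=yields,
        rho_targets=rho_targets,
        tapping=tapping,
    )
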