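"""Guide extraction, duplex enumeration, scoring, site calling and
classification, with brute-force oracle checks."""

import numpy as np
import pytest

from snolatex import (
    DuplexConfig,
    DuplexWeights,
    GenomicContext,
    RnaSequence,
    ScoreThresholds,
    SequenceError,
    call_methylation_site,
    classify_guide,
    enumerate_duplexes,
    extract_guides,
    predict_targets,
    reverse_complement_rna,
    score_duplex,
)
from snolatex.sno_scan import BoxMotif, SnoRnaCandidate, scan_cd, scan_haca
from snolatex.synthetic_data import plant_snornas
from snolatex.target_predict import DuplexAssignment, GuideElement

WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
GU = {("G", "U"), ("U", "G")}


def _cd_candidate(seq: str, d_start: int, c_span=(5, 11)) -> SnoRnaCandidate:
    return SnoRnaCandidate(
        id="cand",
        context=GenomicContext("t", 1, len(seq)),
        subfamily="CD",
        boxes=[
            BoxMotif("C", c_span[0], c_span[1], seq[c_span[0] - 1 : c_span[1]]),
            BoxMotif("D", d_start, d_start + 3, seq[d_start - 1 : d_start + 3]),
        ],
        sequence=seq,
    )


def test_guide_spans_window_ending_at_d_box_first_nucleotide():
    seq = "A" * 73
    cand = _cd_candidate(seq, d_start=70)
    (guide,) = extract_guides(cand, DuplexConfig(max_guide=12))
    assert (guide.start, guide.end) == (59, 70)
    assert len(guide.residues) == 12


def test_candidate_without_internal_boxes_yields_one_guide():
    cand = _cd_candidate("A" * 80, d_start=73)
    assert len(extract_guides(cand)) == 1


def brute_force_duplexes(guide: GuideElement, rrna: str, cfg: DuplexConfig):
    """Naive enumeration over (sub-length, window) with independent pair
    classification; returns comparable tuples."""
    out = set()
    g = guide.residues
    for L in range(cfg.min_guide, min(cfg.max_guide, len(g)) + 1):
        sub = g[-L:]
        for s in range(len(rrna) - L + 1):
            window = rrna[s : s + L]
            wc = gu = mm = 0
            for i, gb in enumerate(sub):
                tb = window[L - 1 - i]
                if (gb, tb) in WC:
                    wc += 1
                elif (gb, tb) in GU:
                    gu += 1
                else:
                    mm += 1
            if mm <= cfg.max_mismatch and gu <= cfg.max_gu:
                out.add((L, s + 1, wc, gu, mm))
    return out


def test_perfect_duplex_by_construction(small_rrnas):
    rrnas, _, _ = small_rrnas
    rrna = rrnas[0]
    guide_res = reverse_complement_rna(rrna.slice1(101, 112))
    guide = GuideElement("c", "D", 50, 61, guide_res)
    hits = [
        d
        for d in enumerate_duplexes(guide, rrna)
        if d.target_start == 101 and d.target_end == 112
    ]
    assert hits and hits[0].wc_pairs == 12 and hits[0].gu_pairs == 0
    assert hits[0].mismatches == 0


def test_enumerate_duplexes_matches_brute_force(small_rrnas):
    rrnas, _, _ = small_rrnas
    rng = np.random.default_rng(13)
    cfg = DuplexConfig()
    for rrna in rrnas:  # 400 + 600 + 120 nt, all <= 2 kb
        for trial in range(4):
            if trial % 2 == 0:
                res = "".join(rng.choice(list("ACGU"), 14))
            else:  # seed a near-complementary guide so hits exist
                s = int(rng.integers(1, len(rrna) - 14))
                res = reverse_complement_rna(rrna.slice1(s, s + 13))
            guide = GuideElement("c", "D", 1, len(res), res)
            got = {
                (
                    d.target_end - d.target_start + 1,
                    d.target_start,
                    d.wc_pairs,
                    d.gu_pairs,
                    d.mismatches,
                )
                for d in enumerate_duplexes(guide, rrna, cfg)
            }
            assert got == brute_force_duplexes(guide, rrna.residues, cfg)


@pytest.mark.parametrize("wc,gu,mm,expected", [(12, 0, 0, 24.0), (9, 2, 1, 18.0)])
def test_score_duplex_arithmetic(wc, gu, mm, expected):
    d = DuplexAssignment(
        "c", GuideElement("c", "D", 1, 12, "A" * 12), "r", 1, 12, {}, wc, gu, mm
    )
    assert score_duplex(d) == expected


def test_score_monotone_in_wc_pairs():
    rng = np.random.default_rng(5)
    for _ in range(50):
        wc, gu, mm = int(rng.integers(0, 15)), int(rng.integers(0, 3)), int(
            rng.integers(0, 2)
        )
        base = DuplexAssignment(
            "c", GuideElement("c", "D", 1, 12, "A" * 12), "r", 1, 12, {}, wc, gu, mm
        )
        more = DuplexAssignment(
            "c", GuideElement("c", "D", 1, 12, "A" * 12), "r", 1, 12, {}, wc + 1, gu, mm
        )
        assert score_duplex(more) >= score_duplex(base)


def test_methylation_site_from_pairing_map(small_rrnas):
    """The called site is the rRNA base paired to the guide position five
    nucleotides upstream of the D-box first nucleotide."""
    rrnas, _, _ = small_rrnas
    rrna = rrnas[0]
    w_start = 201
    L = 12
    guide_res = reverse_complement_rna(rrna.slice1(w_start, w_start + L - 1))
    guide = GuideElement("c", "D", 59, 70, guide_res)
    d = next(
        d
        for d in enumerate_duplexes(guide, rrna)
        if d.target_start == w_start and d.target_end == w_start + L - 1
    )
    site = call_methylation_site(d, rrna)
    # explicit bookkeeping oracle: invert the pairing map
    assert site.position == d.pairing[guide.end - 5]
    assert site.position == w_start + 5
    assert site.mtype == "Nm" and site.provenance == "predicted"


def test_methylation_site_needs_duplex_past_d_plus_5():
    guide = GuideElement("c", "D", 59, 70, "A" * 12)
    # duplex covering only guide positions 67..70 (4 nt upstream of the box)
    d = DuplexAssignment(
        "c", guide, "r", 1, 4, {67: 4, 68: 3, 69: 2, 70: 1}, 4, 0, 0
    )
    rrna = RnaSequence("r", "ACGUACGUAC", role="rRNA")
    assert call_methylation_site(d, rrna) is None


@pytest.mark.parametrize(
    "subfamily,score,exon,expected",
    [
        ("CD", 15.0, False, "guide"),  # > 14
        ("CD", 14.0, False, "orphan"),  # strict
        ("CD", 15.0, True, "orphan"),  # exon threshold 20 (inclusive)
        ("CD", 20.0, True, "guide"),
        ("HACA", 41.0, False, "guide"),  # > 40
        ("HACA", 40.0, False, "orphan"),
        ("HACA", 45.0, True, "guide"),  # exon >= 45
    ],
)
def test_classification_thresholds(subfamily, score, exon, expected):
    cand = SnoRnaCandidate(
        id="c",
        context=GenomicContext("t", 1, 100, exon_overlap=exon),
        subfamily=subfamily,
        boxes=[],
        sequence="A" * 100,
    )
    assert classify_guide(cand, score) == expected


def test_raising_threshold_never_increases_guide_count(bundle42, pipeline42):
    base = sum(1 for r in pipeline42.target_results.values() if r.cls == "guide")
    stricter = ScoreThresholds(cd_guide=20, haca_guide=46, cd_guide_exon=25, haca_guide_exon=50)
    n = 0
    for c in pipeline42.candidates:
        n += classify_guide(c, pipeline42.target_results[c.id].score, stricter) == "guide"
    assert n <= base


def test_exon_thresholds_must_dominate():
    with pytest.raises(SequenceError):
        ScoreThresholds(cd_guide=14, haca_guide=40, cd_guide_exon=10, haca_guide_exon=45)


def test_planted_guides_and_orphans_classified_end_to_end(small_rrnas):
    rrnas, _, sites = small_rrnas
    transcripts, truth = plant_snornas(
        11, rrnas, sites, n_cd_guide=3, n_haca_guide=2, n_orphan=2,
        n_decoy_transcripts=0,
    )
    for plant in truth:
        tx = next(t for t in transcripts if t.id == plant.transcript_id)
        scan = scan_cd if plant.subfamily == "CD" else scan_haca
        span = plant.end - plant.start + 1
        cand = max(
            scan(tx),
            key=lambda c: min(c.context.end, plant.end)
            - max(c.context.start, plant.start),
        )
        res = predict_targets(cand, rrnas)
        assert res.cls == plant.expected_class
        if plant.expected_class == "guide":
            assert any(
                s.rrna_id == plant.target_rrna and s.position == plant.target_position
                for s in res.sites
            )
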