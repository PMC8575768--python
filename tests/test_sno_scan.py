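"""Box scanning, stem folding and candidate detection against brute-force
oracles and planted ground truth."""

import numpy as np
import pytest

from snolatex import (
    RnaSequence,
    ScanConfig,
    find_boxes,
    fold_stems,
    max_nested_pairs,
    scan_cd,
    scan_haca,
    scan_transcripts,
)
from snolatex.sequences_io import match_degenerate
from snolatex.sno_scan import BOX_CONSENSUS, can_pair
from snolatex.synthetic_data import gen_rrna_and_sites, plant_snornas


def test_find_boxes_planted_consensus():
    hits = find_boxes(RnaSequence("x", "GGAUGAUGAGG"), "C", 0)
    assert [(h.start, h.end, h.seq) for h in hits] == [(3, 9, "AUGAUGA")]


def test_find_boxes_no_hit_in_poly_c():
    assert find_boxes(RnaSequence("x", "CCCCCCCC"), "D", 0) == []


@pytest.mark.parametrize("kind,mm", [("C", 0), ("C", 1), ("D", 0), ("H", 1), ("ACA", 0)])
def test_find_boxes_matches_exhaustive_window_matcher(kind, mm):
    rng = np.random.default_rng(7)
    s = "".join(rng.choice(list("ACGU"), 500))
    pattern = BOX_CONSENSUS[kind]
    w = len(pattern)
    oracle = [
        (i + 1, i + w)
        for i in range(len(s) - w + 1)
        if match_degenerate(pattern, s[i : i + w]) <= mm
    ]
    got = [(h.start, h.end) for h in find_boxes(s, kind, mm)]
    assert got == oracle


def brute_max_pairs(s: str, min_loop: int = 3) -> int:
    """Plain recursion over all nested structures (no memoization)."""

    def rec(i, j):
        if j - i < min_loop + 1:
            return 0
        best = rec(i, j - 1)
        for k in range(i, j - min_loop):
            if can_pair(s[k], s[j]):
                best = max(best, rec(i, k - 1) + 1 + rec(k + 1, j - 1))
        return best

    return rec(0, len(s) - 1)


def test_max_nested_pairs_matches_brute_force_enumeration():
    rng = np.random.default_rng(31)
    for _ in range(12):
        s = "".join(rng.choice(list("ACGU"), int(rng.integers(8, 19))))
        assert max_nested_pairs(s) == brute_max_pairs(s)


def test_fold_stems_designed_hairpin():
    ann = fold_stems("GGGGAAAACCCC")
    hp = ann.hairpins[0]
    assert hp.stem5 == (1, 4) and hp.stem3 == (9, 12)
    assert hp.pairs == 4


def test_fold_stems_poly_a_has_no_structure():
    assert fold_stems("A" * 30) is None


def _cd_transcript():
    # 80-nt sequence, C box at 5..11 and D box at 74..77 (clipped span = 1..80)
    rng = np.random.default_rng(3)
    while True:
        s = list("".join(rng.choice(list("ACGU"), 80)))
        s[4:11] = "AUGAUGA"
        s[73:77] = "CUGA"
        seq = "".join(s)
        spurious = [
            i
            for i in range(len(seq) - 3)
            if seq[i : i + 4] == "CUGA" and i != 73
        ]
        c_spurious = [
            i
            for i in range(len(seq) - 6)
            if match_degenerate("RUGAUGA", seq[i : i + 7]) <= 1 and i != 4
        ]
        if not spurious and not c_spurious:
            return seq


def test_scan_cd_planted_boxes_single_candidate():
    seq = _cd_transcript()
    cands = scan_cd(RnaSequence("t", seq))
    assert len(cands) == 1
    c = cands[0]
    assert (c.context.start, c.context.end, c.length) == (1, 80, 80)
    assert {b.kind: (b.start, b.end) for b in c.boxes if b.kind in "CD"} == {
        "C": (5, 11),
        "D": (74, 77),
    }


def test_scan_cd_rejects_below_length_minimum():
    seq = _cd_transcript()
    short = seq[:40]  # boxes cannot define a 50-nt candidate anymore
    assert scan_cd(RnaSequence("t", short)) == []


def test_scan_cd_recovers_planted_snornas_with_box_coordinates(small_rrnas):
    rrnas, _, sites = small_rrnas
    transcripts, truth = plant_snornas(
        1, rrnas, sites, n_cd_guide=6, n_haca_guide=0, n_orphan=0,
        n_decoy_transcripts=0,
    )
    for plant in truth:
        tx = next(t for t in transcripts if t.id == plant.transcript_id)
        cands = scan_cd(tx)
        match = [
            c
            for c in cands
            if (c.context.start, c.context.end) == (plant.start, plant.end)
        ]
        assert len(match) == 1
        got = {b.kind: (b.start, b.end) for b in match[0].boxes}
        for kind, span in plant.boxes.items():
            assert got[kind] == span


def test_scan_haca_planted_architecture_and_aca_mutation(small_rrnas):
    rrnas, _, sites = small_rrnas
    transcripts, truth = plant_snornas(
        3, rrnas, sites, n_cd_guide=0, n_haca_guide=3, n_orphan=0,
        n_decoy_transcripts=0,
    )
    for plant in truth:
        tx = next(t for t in transcripts if t.id == plant.transcript_id)
        cands = scan_haca(tx)
        span = plant.end - plant.start + 1
        overlapping = [
            c
            for c in cands
            if min(c.context.end, plant.end) - max(c.context.start, plant.start) + 1
            > 0.5 * span
        ]
        assert overlapping, f"plant {plant.id} not recovered"
        # knocking out the ACA motif kills every candidate anchored at it
        aca = plant.boxes["ACA"]
        assert any(
            b.kind == "ACA" and (b.start, b.end) == aca
            for c in overlapping
            for b in c.boxes
        )
        a0 = aca[0] - 1
        mutated = tx.residues[:a0] + "AGA" + tx.residues[a0 + 3 :]
        still = [
            c
            for c in scan_haca(RnaSequence(tx.id, mutated))
            for b in c.boxes
            if b.kind == "ACA" and (b.start, b.end) == aca
        ]
        assert not still


def test_scan_results_invariant_to_input_order(small_rrnas):
    rrnas, _, sites = small_rrnas
    transcripts, _ = plant_snornas(
        5, rrnas, sites, n_cd_guide=2, n_haca_guide=1, n_orphan=1,
        n_decoy_transcripts=3,
    )
    a = scan_transcripts(transcripts, "both")
    b = scan_transcripts(transcripts[::-1], "both")
    assert [(c.id, c.context.start) for c in a] == [(c.id, c.context.start) for c in b]


def test_candidates_satisfy_subfamily_invariants(bundle42):
    cands = scan_transcripts(bundle42.transcripts, "both")
    cfg = ScanConfig()
    for c in cands:
        assert cfg.len_min <= c.length <= cfg.len_max
        if c.subfamily == "CD":
            boxes = {b.kind: b for b in c.boxes}
            assert boxes["C"].start < boxes["D"].start
        else:
            boxes = {b.kind: b for b in c.boxes}
            assert boxes["H"].end < boxes["ACA"].start
            assert boxes["ACA"].end + cfg.tail_offset == c.context.end
            assert len(c.structure.hairpins) == 2
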