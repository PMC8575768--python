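"""Blacklist/redundancy filtering, pre-rRNA normalization, moderated-t DE
and the latex-abundant call."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snolatex import (
    CountTable,
    DeDesign,
    GenomicContext,
    RnaSequence,
    SequenceError,
    call_latex_abundant,
    dedupe,
    differential_expression,
    filter_blacklist,
    normalize_prerrna,
)
from snolatex.filter_de import check_telescoping, FilterReport
from snolatex.sno_scan import SnoRnaCandidate
from statsmodels.stats.multitest import multipletests


def _cand(cid, seq, group=None):
    return SnoRnaCandidate(
        id=cid,
        context=GenomicContext(cid.split(":")[0], 1, len(seq)),
        subfamily="CD",
        boxes=[],
        sequence=seq,
        group=group or cid,
    )


# ---------------------------------------------------------------------------
# blacklist filtering
# ---------------------------------------------------------------------------

def sw_local_oracle(a: str, b: str, match=2.0, mismatch=-3.0, open_=-5.0, ext=-2.0):
    """Pure-python Smith-Waterman (affine) returning (identity, coverage of a)."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + ext, H[i][j - 1] + open_ + ext)
            F[i][j] = max(F[i - 1][j] + ext, H[i - 1][j] + open_ + ext)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
    i, j = np.unravel_index(np.argmax(H), H.shape)
    matches = aligned = 0
    while H[i][j] > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if i and j and H[i][j] == H[i - 1][j - 1] + s:
            matches += a[i - 1] == b[j - 1]
            aligned += 1
            i, j = i - 1, j - 1
        elif i and H[i][j] == F[i][j]:
            while i and F[i][j] != H[i - 1][j] + open_ + ext:
                aligned += 1
                i -= 1
            aligned += 1
            i -= 1
        else:
            while j and E[i][j] != H[i][j - 1] + open_ + ext:
                j -= 1
            j -= 1
    return (matches / aligned if aligned else 0.0), aligned / len(a)


def test_exact_substring_candidate_is_dropped(small_rrnas):
    rrnas, _, _ = small_rrnas
    frag = rrnas[0].slice1(101, 180)
    cand = _cand("t1:frag", frag)
    retained, report = filter_blacklist([cand], rrnas)
    assert retained == []
    assert "18S" in report.drop_reasons[cand.id]


def test_random_candidate_is_retained(small_rrnas):
    rrnas, _, _ = small_rrnas
    rng = np.random.default_rng(2)
    cand = _cand("t1:rand", "".join(rng.choice(list("ACGU"), 100)))
    retained, _ = filter_blacklist([cand], rrnas)
    assert retained == [cand]


def test_blacklist_decisions_match_local_alignment_oracle(small_rrnas):
    rrnas, _, _ = small_rrnas
    rng = np.random.default_rng(13)
    blacklist = rrnas[:1]
    subject = blacklist[0].residues
    cands = []
    for k in range(100):
        kind = k % 3
        if kind == 0:  # unrelated
            seq = "".join(rng.choice(list("ACGU"), int(rng.integers(60, 120))))
        else:
            s = int(rng.integers(0, len(subject) - 120))
            seq = list(subject[s : s + int(rng.integers(60, 110))])
            rate = 0.02 if kind == 1 else 0.3  # clear keep/drop margins
            for i in range(len(seq)):
                if rng.random() < rate:
                    seq[i] = str(rng.choice([b for b in "ACGU" if b != seq[i]]))
            seq = "".join(seq)
        cands.append(_cand(f"t{k}:c", seq))
    retained, report = filter_blacklist(cands, blacklist)
    dropped = set(report.drop_reasons)
    for cand in cands:
        ident, cov = sw_local_oracle(cand.sequence, subject)
        oracle_drop = ident >= 0.9 and cov >= 0.8
        assert (cand.id in dropped) == oracle_drop, cand.id


# ---------------------------------------------------------------------------
# redundancy removal
# ---------------------------------------------------------------------------

def test_highest_expressed_isoform_survives():
    a = _cand("t1:a", "A" * 60, group="g")
    b = _cand("t2:b", "A" * 70, group="g")
    retained, report = dedupe([a, b], {"t1:a": 10.0, "t2:b": 5.0})
    assert retained == [a]
    assert report.drop_reasons == {"t2:b": "redundant with t1:a"}


def test_singleton_groups_all_retained():
    cands = [_cand(f"t{i}:c", "A" * 60) for i in range(4)]
    retained, _ = dedupe(cands, {})
    assert len(retained) == 4


def test_dedupe_matches_per_group_argmax_oracle():
    rng = np.random.default_rng(2)
    cands, abundance = [], {}
    for i in range(60):
        cid = f"t{i}:c"
        cands.append(
            _cand(cid, "A" * int(rng.integers(50, 90)), group=f"g{int(rng.integers(8))}")
        )
        abundance[cid] = float(rng.integers(0, 50))
    retained, _ = dedupe(cands, abundance)
    groups = {}
    for c in cands:
        groups.setdefault(c.group, []).append(c)
    oracle = {
        sorted(v, key=lambda c: (-abundance[c.id], -c.length, c.id))[0].id
        for v in groups.values()
    }
    assert {c.id for c in retained} == oracle


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _table(data: dict[str, list[int]], samples: list[str]) -> CountTable:
    return CountTable(pd.DataFrame(data, index=samples).T)


def test_normalization_equalizes_proportional_counts():
    t = _table({"f1": [10, 20], "pre_rRNA": [1000, 2000]}, ["A", "B"])
    norm = normalize_prerrna(t)
    assert norm.loc["f1", "A"] == pytest.approx(norm.loc["f1", "B"])
    assert norm.loc["pre_rRNA"].nunique() == 1


def test_normalization_is_scale_invariant_per_sample():
    rng = np.random.default_rng(8)
    counts = pd.DataFrame(
        rng.integers(1, 500, size=(20, 4)),
        index=[f"f{i}" for i in range(19)] + ["pre_rRNA"],
        columns=list("ABCD"),
    )
    base = normalize_prerrna(CountTable(counts))
    scaled = counts.copy()
    scaled["B"] *= 7  # library-size change, pre-rRNA included
    got = normalize_prerrna(CountTable(scaled))
    pd.testing.assert_frame_equal(got, base)


def test_zero_prerrna_names_the_sample():
    t = _table({"f1": [10, 20], "pre_rRNA": [1000, 0]}, ["A", "B"])
    with pytest.raises(SequenceError, match="B"):
        normalize_prerrna(t)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def test_identical_conditions_give_fc_one_and_no_calls():
    norm = pd.DataFrame(
        {"latex_1": [5.0, 8.0], "latex_2": [6.0, 9.0], "leaf_1": [5.0, 8.0],
         "leaf_2": [6.0, 9.0]},
        index=["f1", "f2"],
    )
    res = differential_expression(
        norm, DeDesign(("latex_1", "latex_2"), ("leaf_1", "leaf_2"))
    )
    assert all(r.real_fc == pytest.approx(1.0) for r in res)
    assert not any(r.de for r in res)


def test_bh_adjustment_matches_reference_step_up():
    rng = np.random.default_rng(3)
    pvals = rng.uniform(size=400)
    norm = pd.DataFrame(
        {"latex_1": np.ones(3), "leaf_1": np.ones(3)}, index=list("abc")
    )
    # compare the library call used internally against a manual step-up
    _, q, _, _ = multipletests(pvals, alpha=0.05, method="fdr_bh")
    n = len(pvals)
    order = np.argsort(pvals)
    manual = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        manual[i] = running
    assert np.allclose(q, manual)


def test_null_simulation_controls_fdr_small():
    rng = np.random.default_rng(17)
    fdp = []
    for _ in range(5):
        m = 200
        counts = rng.negative_binomial(10, 10 / 110, size=(m, 6)).astype(float)
        norm = pd.DataFrame(
            counts, index=[f"f{i}" for i in range(m)],
            columns=["latex_1", "latex_2", "latex_3", "leaf_1", "leaf_2", "leaf_3"],
        )
        res = differential_expression(
            norm, DeDesign(("latex_1", "latex_2", "latex_3"),
                           ("leaf_1", "leaf_2", "leaf_3"))
        )
        r = sum(x.de for x in res)
        fdp.append(1.0 if r else 0.0)
    assert np.mean(fdp) <= 0.05 + 2 * (np.std(fdp) / np.sqrt(len(fdp)) + 0.05)


def test_latex_abundant_threshold_and_ordering():
    res = differential_expression(
        pd.DataFrame(
            {
                "latex_1": [241.0, 150.0, 800.0],
                "latex_2": [241.0, 150.0, 800.0],
                "latex_3": [241.0, 150.0, 800.0],
                "leaf_1": [100.0, 100.0, 100.0],
                "leaf_2": [100.0, 100.0, 100.0],
                "leaf_3": [99.0, 99.0, 99.0],
            },
            index=["fc2.4", "fc1.5", "fc8"],
        ),
        DeDesign(
            ("latex_1", "latex_2", "latex_3"), ("leaf_1", "leaf_2", "leaf_3")
        ),
    )
    picked = call_latex_abundant(res, min_fc=2.0)
    names = [r.candidate_id for r in picked]
    assert "fc1.5" not in names  # below the fold-change floor
    assert names == sorted(
        names, key=lambda n: -next(r.real_fc for r in res if r.candidate_id == n)
    )
    if "fc2.4" in names:  # 2.41-fold is included when DE
        assert names[-1] == "fc2.4"


def test_filter_reports_telescope():
    reports = [
        FilterReport("a", 100, 80, {f"x{i}": "r" for i in range(20)}),
        FilterReport("b", 80, 80),
        FilterReport("c", 80, 50, {f"y{i}": "r" for i in range(30)}),
    ]
    assert check_telescoping(reports)
    reports[2] = FilterReport("c", 79, 50, {f"y{i}": "r" for i in range(29)})
    assert not check_telescoping(reports)
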