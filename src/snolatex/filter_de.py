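"""Candidate filtering cascade and pre-rRNA-normalized expression analysis.

Stages mirror the discovery workflow: blacklist removal (candidates that
are really rRNA / EST fragments), redundancy removal (one isoform per
assembly subcomponent, the highest expressed), normalization of counts to
the pre-rRNA reference transcript (the only rRNA species present in the
nucleus, hence a library-size-free internal reference), a two-condition
differential-expression test with Benjamini-Hochberg FDR control, and the
latex-abundant call (DE at FDR <= 0.05 and fold change >= ``min_fc``).

The DE test is an in-repo stand-in declared in the output metadata: a
Welch t-test on log2 normalized counts when both conditions have >= 3
replicates, otherwise a two-sided exact Poisson rate test on reference-
offset counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.rates import test_poisson_2indep

from .sequences_io import CountTable, RnaSequence, SequenceError, logger
from .sno_scan import SnoRnaCandidate


@dataclass
class FilterReport:
    """Accounting for one cascade stage (telescoping across stages)."""

    stage: str
    input_count: int
    retained_count: int
    drop_reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.retained_count > self.input_count:
            raise SequenceError("retained count exceeds input count")
        if self.input_count - self.retained_count != len(self.drop_reasons):
            raise SequenceError("drop reasons do not partition the input")


def reports_to_frame(reports: list[FilterReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"stage": r.stage, "input": r.input_count, "retained": r.retained_count}
            for r in reports
        ]
    )


def check_telescoping(reports: list[FilterReport]) -> bool:
    """Stage k's input must equal stage k-1's retained count."""
    return all(
        reports[k].input_count == reports[k - 1].retained_count
        for k in range(1, len(reports))
    )


# ---------------------------------------------------------------------------
# Blacklist filtering (local alignment)
# ---------------------------------------------------------------------------

_LOCAL_ALIGNER_PARAMS = dict(
    match_score=2.0, mismatch_score=-3.0, open_gap_score=-5.0, extend_gap_score=-2.0
)


def _best_local_identity(candidate: str, subject: str) -> tuple[float, float]:
    """(identity, coverage) of the best local alignment of candidate in
    subject: identity over aligned candidate positions, coverage as the
    aligned fraction of the candidate."""
    aligner = Align.PairwiseAligner(mode="local", **_LOCAL_ALIGNER_PARAMS)
    if aligner.score(candidate, subject) <= 0:
        return 0.0, 0.0
    aln = aligner.align(candidate, subject)[0]
    blocks_c, blocks_s = aln.aligned
    matches = aligned = 0
    for (cs, ce), (ss, se) in zip(blocks_c, blocks_s):
        aligned += ce - cs
        matches += sum(
            1 for a, b in zip(candidate[cs:ce], subject[ss:se]) if a == b
        )
    if aligned == 0:
        return 0.0, 0.0
    return matches / aligned, aligned / len(candidate)


def filter_blacklist(
    candidates: list[SnoRnaCandidate],
    blacklist: list[RnaSequence],
    min_identity: float = 0.9,
    min_cov: float = 0.8,
) -> tuple[list[SnoRnaCandidate], FilterReport]:
    """Drop candidates locally aligning to any blacklist sequence at
    >= ``min_identity`` identity over >= ``min_cov`` of their length."""
    if not blacklist:
        raise SequenceError("blacklist must be non-empty")
    retained: list[SnoRnaCandidate] = []
    reasons: dict[str, str] = {}
    for cand in candidates:
        hit = None
        for subject in blacklist:
            ident, cov = _best_local_identity(cand.sequence, subject.residues)
            if ident >= min_identity and cov >= min_cov:
                hit = subject.id
                break
        if hit is None:
            retained.append(cand)
        else:
            reasons[cand.id] = f"blacklist hit: {hit}"
            logger.debug("candidate %s dropped (blacklist %s)", cand.id, hit)
    return retained, FilterReport("blacklist", len(candidates), len(retained), reasons)


def dedupe(
    candidates: list[SnoRnaCandidate],
    abundance: dict[str, float],
    rank: dict[str, tuple] | None = None,
) -> tuple[list[SnoRnaCandidate], FilterReport]:
    """One candidate per redundancy group: the highest abundance, ties
    broken by ``rank`` (lower wins; e.g. guide calls before orphans when
    isoforms share a count row), then longer sequence, then id."""
    groups: dict[str, list[SnoRnaCandidate]] = {}
    for cand in candidates:
        groups.setdefault(cand.group or cand.id, []).append(cand)
    retained: list[SnoRnaCandidate] = []
    reasons: dict[str, str] = {}
    for key in sorted(groups):
        members = groups[key]
        winner = sorted(
            members,
            key=lambda c: (
                -abundance.get(c.id, 0.0),
                (rank or {}).get(c.id, ()),
                -c.length,
                c.id,
            ),
        )[0]
        retained.append(winner)
        for c in members:
            if c is not winner:
                reasons[c.id] = f"redundant with {winner.id}"
    retained.sort(key=lambda c: (c.context.transcript_id, c.context.start))
    return retained, FilterReport("redundancy", len(candidates), len(retained), reasons)


# ---------------------------------------------------------------------------
# Pre-rRNA normalization and differential expression
# ---------------------------------------------------------------------------

def normalize_prerrna(table: CountTable) -> pd.DataFrame:
    """Scale each sample by its pre-rRNA count.

    ``normalized(i, s) = count(i, s) / prerrna(s) * median_s(prerrna)``;
    the pre-rRNA row becomes constant, and multiplying an entire sample
    column by any factor leaves its normalized values unchanged.
    """
    counts = table.counts
    ref = counts.loc[table.prerrna_id]
    zero = ref[ref <= 0]
    if len(zero):
        raise SequenceError(
            f"pre-rRNA count is zero in sample(s) {list(zero.index)}; "
            "normalization undefined"
        )
    scale = float(ref.median())
    return counts.div(ref, axis=1) * scale


def _moderated_t_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sample moderated t on log-scale matrices (features x replicates).

    Per-feature pooled variances are shrunk toward a common prior by
    empirical Bayes: the prior degrees of freedom d0 and prior variance are
    estimated from the moments of log s^2 (which follows a scaled
    log-F(d, d0) distribution), and the posterior variance
    ``(d0*s0^2 + d*s^2) / (d0 + d)`` is used with d0 + d degrees of
    freedom.  Variance pooling is what makes a 3-vs-3 design usable: the
    per-feature variance estimate alone has too few degrees of freedom.
    """
    n1, n2 = x.shape[1], y.shape[1]
    d = n1 + n2 - 2
    s2 = (x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)) / d
    s2 = np.maximum(s2, 1e-8)
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    var_e = e.var(ddof=1) - float(special.polygamma(1, d / 2))
    if var_e > 0:
        d0 = float(
            optimize.brentq(
                lambda v: float(special.polygamma(1, v / 2)) - var_e, 1e-2, 1e6
            )
        )
        s2_prior = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
        s2_post = (d0 * s2_prior + d * s2) / (d0 + d)
        df = d0 + d
    else:  # observed spread below sampling noise: variances are common
        s2_post = np.full_like(s2, np.exp(e.mean()))
        df = 1e9
    t = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    return 2.0 * stats.t.sf(np.abs(t), df)


@dataclass
class DeResult:
    candidate_id: str
    mean_latex: float
    mean_leaf: float
    real_fc: float
    pvalue: float
    fdr: float
    de: bool
    latex_abundant: bool = False


@dataclass(frozen=True)
class DeDesign:
    latex_samples: tuple[str, ...]
    leaf_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.latex_samples or not self.leaf_samples:
            raise SequenceError("each condition needs at least one sample")


def differential_expression(
    normalized: pd.DataFrame,
    design: DeDesign,
    fdr: float = 0.05,
    pseudocount: float = 0.5,
    prerrna_id: str = "pre_rRNA",
) -> list[DeResult]:
    """Per-feature latex-vs-leaf test with BH FDR control.

    Fold change is ``(mean latex + pseudocount) / (mean leaf + pseudocount)``
    on the normalized scale, so it is finite for all-zero features.
    """
    features = [i for i in normalized.index if i != prerrna_id]
    latex = normalized.loc[features, list(design.latex_samples)].to_numpy(float)
    leaf = normalized.loc[features, list(design.leaf_samples)].to_numpy(float)
    n1, n2 = latex.shape[1], leaf.shape[1]
    mean_latex = latex.mean(axis=1)
    mean_leaf = leaf.mean(axis=1)
    real_fc = (mean_latex + pseudocount) / (mean_leaf + pseudocount)
    if min(n1, n2) >= 2:
        pvals = _moderated_t_pvalues(
            np.log2(latex + pseudocount), np.log2(leaf + pseudocount)
        )
        method = "moderated-t/log2"
    else:
        pvals = np.empty(len(features))
        for k in range(len(features)):
            c1, c2 = latex[k].sum(), leaf[k].sum()
            if c1 + c2 == 0:
                pvals[k] = 1.0
                continue
            pvals[k] = test_poisson_2indep(
                round(c1), n1, round(c2), n2, method="exact-cond"
            ).pvalue
        method = "poisson-exact"
    logger.debug("DE test method: %s", method)
    rejected, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return [
        DeResult(
            candidate_id=features[k],
            mean_latex=float(mean_latex[k]),
            mean_leaf=float(mean_leaf[k]),
            real_fc=float(real_fc[k]),
            pvalue=float(pvals[k]),
            fdr=float(qvals[k]),
            de=bool(rejected[k]),
        )
        for k in range(len(features))
    ]


def call_latex_abundant(results: list[DeResult], min_fc: float = 2.0) -> list[DeResult]:
    """DE features with fold change >= ``min_fc``, sorted by fold change
    descending (the reporting order of the latex-abundant table)."""
    picked = [r for r in results if r.de and r.real_fc >= min_fc]
    for r in picked:
        r.latex_abundant = True
    return sorted(picked, key=lambda r: (-r.real_fc, r.candidate_id))


def de_results_to_frame(results: list[DeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "candidate_id": r.candidate_id,
                "mean_latex": r.mean_latex,
                "mean_leaf": r.mean_leaf,
                "real_fc": r.real_fc,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
                "de": r.de,
                "latex_abundant": r.latex_abundant,
            }
            for r in results
        ]
    )
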