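# Methods

This note documents the models, parameter choices and numerical decisions
behind `snolatex`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Coordinates, alphabets, strands

All interface coordinates are 1-based inclusive, matching the rRNA
site notation used in the field (e.g. "U791") and GFF3. Input sequences
are normalized to the RNA alphabet `{A,C,G,U,N}` (T→U, upper-cased),
because transcript repertoires mix genome- and transcript-derived
records. Transcripts are scanned as given: assembled contigs already
carry the transcribed orientation, so reverse-strand scanning is not
performed (whether the original analyses scanned both strands is
unknowable from the published text; single-strand is this package's
choice).

## Modification-site transfer

Sites are lifted through a global pairwise alignment (Needleman–Wunsch,
affine gaps) of the model-organism rRNA onto the target rRNA. Defaults:
match +1, mismatch −1, gap open −4, gap extend −1 — ordinary rRNA-scale
parameters, all overridable. A transferred site must (i) map to an
ungapped column, (ii) reproduce the reference nucleotide on the target
(Ψ sites additionally require U), and (iii) sit in a conserved context:
≥ 80 % matching columns within ±5 nt. The context filter stands in for
the unreported identity cutoff of the original consensus-based transfer;
on the synthetic benchmark (3 % substitutions sparing site contexts,
three short indels) it transfers every preserved site to exactly the
generator's coordinate map and drops indel-deleted sites with reason
codes, so the drops plus outputs always partition the input.

## Box scanning

Box consensus motifs: C/C′ = RUGAUGA, D/D′ = CUGA, H = ANANNA,
ACA = ACA. Mismatch allowances (a repo default — the original tools'
tolerances are unpublished): C and H ≤ 1, D and ACA exact, internal
C′/D′ ≤ 1. Candidate boundaries are likewise a declared default:
C/D candidates span (C start − 4) … (D end + 4), clipped at the
transcript ends; H/ACA candidates span the first hairpin start to
(ACA end + 3). Length bounds 50–300 nt. Overlapping calls sharing more
than half of the shorter span collapse to one call per locus: fewest
total box mismatches, then longer span, then leftmost.

## Secondary structure

Hairpins are found by complementary-segment search: a maximal run of
contiguous pairs (Watson–Crick plus GU) with at least
`min_stem_pairs = 4` pairs enclosing a loop of ≥ 3 nt. Within the
region enclosed by an outer stem, an upper stem splits off an internal
loop — the pseudouridylation pocket. Because segment search in random
sequence is ambiguous, the scanner keeps the top-3 outer stems and, per
outer stem, the top-3 upper-stem decompositions; downstream pocket
matching tries all of them. Each hairpin also carries its maximal nested
pairing count (a Nussinov-style dynamic program over WC+GU pairs,
minimum loop 3), which is exactly the quantity a brute-force enumeration
of nested structures reproduces in the tests. Full thermodynamic folding
is deliberately out of scope; the architecture constraints, not free
energies, are what the published method states.

## Guide–target duplexes and site calls

The C/D antisense element ends at, and includes, the first nucleotide of
the D or D′ box. Sub-guides are 3′-anchored suffixes of 9–21 nt (the
canonical antisense-element range; the original length bounds are
unpublished); each is slid over every rRNA window of equal length.
Admissible duplexes are contiguous and antiparallel with ≤ 1 mismatch
and ≤ 2 GU pairs — bulges cannot occur by construction. The methylated
base is read from the explicit pairing map at the guide position five
nucleotides upstream of the D-box first nucleotide (D+5); the counting
convention (the D-box nucleotide itself is position 0) is a config flag
(`methyl_offset`).

H/ACA pocket geometry is not stated in the source method and is defined
here as: the 3′ pocket strand pairs the rRNA flank 5′ of the target U,
the 5′ pocket strand pairs the flank starting two nucleotides 3′ of it,
leaving the UN dinucleotide unpaired; the composite duplex obeys the
same ≤ 1 mismatch / ≤ 2 GU rule; and the pocket must lie 13–17 nt
upstream of its H or ACA box (measured from the 3′ pocket strand start
to the box start) — the canonical pocket-to-box distance.

## Scoring and classification

The published guide thresholds (C/D > 14, H/ACA > 40; exonic ≥ 20 /
≥ 45) are inherited from external tools whose scoring function is not
defined in the text. The package therefore uses a documented default:
duplex score = 2·WC + 1·GU − 2·mismatch; an H/ACA candidate scores the
sum of its two pocket duplexes plus one point per stem pair beyond
`min_stem_pairs` per hairpin, capped at 10. The weights were chosen so
that a canonical perfect 9–12-nt C/D duplex clears 14 and a two-pocket
H/ACA guide with designed stems clears 40; they are config-exposed and
echoed in every report header, with provenance tags separating
published thresholds from repo defaults. Plain thresholds are strict
(>) and exon thresholds inclusive (≥), exactly as printed.

## Filtering and expression

Blacklist removal drops candidates with a local alignment (BLASTn-like
scoring: +2/−3, gap −5/−2) to any rRNA/EST blacklist sequence at ≥ 0.9
identity over ≥ 0.8 of the candidate — declared defaults standing in for
unreported BLASTn cutoffs. Redundancy removal keeps one isoform per
assembly subcomponent: highest normalized abundance, with guide calls
preferred over orphans when isoforms share a count row, then longer
sequence.

Counts are normalized to the pre-rRNA reference transcript
(`normalized = count / pre-rRNA × median(pre-rRNA)`), which exists only
in the nucleus and therefore tracks sequencing depth independent of the
leaf/latex composition difference; normalization is invariant to any
per-sample rescaling, the property the reference exists to provide.

The DE test is an in-repo stand-in, declared in output metadata, for the
empirical-Bayes package used originally (out of scope here): a moderated
t-test on log2 normalized counts whose per-feature pooled variances are
shrunk toward a common prior (prior df estimated from the moments of
log s², following the standard limma construction), with BH control at
FDR 0.05. A plain Welch t at 3 replicates per condition cannot reach
useful power at the generator's dispersion (0.1) once BH thresholds
bite; variance moderation is the field-standard remedy and measures
~0.98 sensitivity for 4-fold changes at mean depth 100, with the null
false-discovery proportion within the BH guarantee. Designs with a
single replicate fall back to an exact two-sided Poisson rate test.
Fold change uses a 0.5 pseudocount so all-zero features stay finite;
the latex-abundant call requires DE at FDR ≤ 0.05 and fold change ≥ 2
(a declared default consistent with the smallest published
latex-abundant fold change, 2.41).

## Yield and regeneration

TSC/C is exact division of total solid content by trunk circumference.
Spearman ρ is the Pearson correlation of average ranks (ties averaged);
constant input is an error, never a silent NaN. *Yield-correlated*
applies the printed rule exactly: ρ > 0 and ρ² > 0.2, both strict; the
signed coefficient and ρ² are both reported so either reading of the
published "R²" is reproducible. Regeneration ability is the TSC at the
first tapping at or after 180 min (30-min intervals; the series plateaus
by the 3-h tapping); a coefficient-of-variation check (default 0.25)
warns when the post-3-h readings have not actually stabilized.

## Synthetic data: what it emulates and what it does not

The generator is the package's study design, with every parameter fixed
up front: rRNA analogues of 1800/3400/160 nt plus a pre-rRNA spanning a
200-nt ITS1; a reference catalogue of 80 Nm and 16 Ψ sites (desk-scale,
proportional to rRNA length); default plants of 10 C/D guides, 5 H/ACA
guides and 5 orphans, each on its own transcript, plus 2 extra C/D
guides leaked into the blacklist and 10 decoy transcripts; NB counts
(dispersion 0.1, mean depth 100, pre-rRNA depth 10,000 with Poisson
noise, per-sample log-normal depth factors σ = 0.25, 3 leaf vs 3 latex,
planted fold change 4); a 50-tree population from a Gaussian copula
(latent Pearson r = 2·sin(πρ_s/6) inverts the bivariate-normal Spearman
relation, so realized ρ concentrates within ±0.15 of target at n = 50);
and 14 tapping series declining over six tappings to a plateau reached
at 180 min.

Plants are self-validated at generation: each planted snoRNA must be
recovered by the scanner with its intended boxes (C/D) or architecture
(H/ACA), classified as intended, and — for guides — yield exactly the
assigned site; failing arrangements are resampled. Orphan H/ACA plants
admit no pocket duplex at all; orphan C/D plants are verified to score
at or below the guide threshold rather than to have literally zero
admissible duplexes, because a random 9-nt sub-guide almost always finds
some ≤ 1-mismatch window in 5.4 kb of rRNA — an instructive property of
the duplex rule itself.

Passing these tests shows the implementation is internally correct and
calibrated under its own generative assumptions. It does not show that
the box tolerances, scoring weights or filter cutoffs match the original
unpublished settings, nor that recovery rates transfer to real
assembled transcriptomes, where box-like motifs, repetitive rRNA
fragments and expression noise are all harsher than the generator's
sanitized transcripts.

## Problem sizes

The shipped defaults keep everything desk-scale: ~30 transcripts per
bundle, rRNAs ≤ 3.4 kb, DE calibration at 2,000 features × 10–20
replicate simulations, copula studies at 100–200 replicates of 50
trees. These sizes are the package's chosen study conditions and are
stated in the relevant docstrings.
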