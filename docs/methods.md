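# Methods

This note documents the models behind `ervkit`: what the simulator
generates, how each analysis step is computed, the defaults and why,
and what the synthetic benchmarks do and do not demonstrate about real
genomes.

## Substitution model and the simulator

`simulate.evolve` applies a single round of per-site mutation: site `i`
mutates with probability `1 − exp(−SR · t · m_i)`, the target base
uniform over the other three, with `m_i` the CpG multiplier (default
10) for the C and the G of every CpG dinucleotide and 1 elsewhere. No
indels evolve, so coordinates are stable and the generator can emit
exact multiple alignments of its own output. This "mutate at most once
per call" scheme approximates a continuous-time chain; branches are
composed by calling `evolve` per branch segment (ancestor for
`age − split`, then each descendant independently for `split`), which
restores multiple-hit behaviour across nodes. Within one call, back
and convergent mutations are only partially represented; the practical
consequence (a few percent missing divergence at 30 My) is visible in
the dating benchmarks below.

The provirus template is `LTR–PBS–pre-gag–gag–pro–pol–env–LTR`
(~9.2 kb; 600-nt LTR split U3 250 / R 60 / U5 290). Planted features:
an 18-nt PBS copied from the bundled tRNA-PBS library (the `Arg`
entry), Gag zinc fingers `Cx2Cx4Hx4C` and `Cx2Cx3Hx4C` in frame within
gag, `WxGPFxV` within pol, and a pre-gag leader that starts `GT`,
ends `AG`, and carries a `CTAAC` branch motif 33 nt and a 20-nt
polypyrimidine tract immediately upstream of the acceptor, plus a
933-nt ORF. Coding segments are built from a stop-free codon set that
also excludes Cys/His/Trp, so planted motif anchors cannot arise by
chance in frame; template construction additionally rejects (and
rebuilds from the next derived seed) any candidate whose de-novo scan
finds hits beyond the planted ones. Ground truth is therefore exact,
and recall/precision of the scanners are measurable without judgement
calls.

Subgroup variants (A, B, B1, B2) descend from the base template by
"stem" evolution — the exogenous viral divergence that preceded
endogenization. Stems use the plain rate (no CpG multiplier: CpG
hypermutation is a host-methylation effect on integrated DNA) with
planted functional sites protected, defaults 8 My-equivalents for A and
B and 4 for B1/B2 below B; these lengths are chosen so the subgroups
separate with the strong bootstrap supports characteristic of real LTR
subgroup structure. B-derived LTRs carry a 110-nt deletion inside U3;
B1 defines an optional ~200-nt insertion present in ~80% of B1
elements. Host background DNA likewise evolves at the plain neutral
rate; the CpG multiplier acts within elements, which is what the
dating pipeline's CpG stripping is calibrated against, and keeps flank
divergence at the `2·SR·split` expectation that orthology detection
relies on.

The two-species scenario plants insertions with 4-nt target-site
duplications at positions ≥1.5 kb apart. Insertions older than the
species split (default 19 My) are placed once in the common ancestor —
hence orthologous with identical flanks at the split — and both genomes
then evolve independently; younger insertions are species-specific.
Defaults emulate the target system at reduced scale: shared subgroup-A
proviruses at 20–26 My, private B1/B2/other proviruses at 10–18 My,
solitary LTRs ~3.0× and ~2.3× the provirus counts, and two processed
pseudogenes per species (transcript-shaped `R+U5 … U3+R` copies with a
20-nt poly-A starting ≤10 nt downstream; half additionally splice out
the pre-gag, mirroring the observation that loci lacking the pre-gag
are processed pseudogenes).

## Annotation

LTRs are found as the best near-terminal direct repeat by local
alignment of the two terminal windows (match +1, mismatch −1, affine
gaps −5/−2), accepted at ≥0.60 identity and 300–750 nt. The identity
floor is deliberately low — a 30-My-old LTR pair sits near 0.70 — and
specificity comes from the length requirement. PBS assignment scans
18-nt windows over the 30 nt downstream of the 5'LTR against every
library entry; presence needs ≥14/18 identity. Motif scanning
translates the three forward frames and reports every regex occurrence
of the zinc-finger and GPY/F patterns; a stop codon inside a hit's span
flags it `internal_stop` rather than hiding it, and provirus-level
presence counts only intact hits. The dot-plot intactness score merges
exact shared 12-mers on common diagonals into segments ≥50 nt and
reports reference coverage; 0.6 coverage is the default
"reasonably intact" threshold, and 0.2 coverage of the terminal 1000-nt
internal probes decides whether an LTR locus has internal proviral
sequence at all.

A note on the affine gap penalty: with a flat −2 gap cost the optimal
alignment of two ~20%-diverged LTRs starts absorbing clusters of real
mismatches (decayed CpG sites come in adjacent pairs) into 1-column
indels. Pairwise deletion then drops those columns and ages flatten by
~10% at the old end. Gap opening −5 removes the artefact; measured on
600-nt LTR pairs the estimated-vs-true age slope moves from 0.85 to
0.94.

## Genome scanning and classification

The genome scan seeds exact 12-mers from the LTR and internal
references (low-complexity 12-mers excluded), groups them on consistent
diagonals (band 30, positional gap ≤600), and merges groups within
800 nt into one candidate. A candidate requires a strong anchor group
(≥5 seeds spanning ≥50 nt) — chance background seed pairs never reach
that — while weak 2-seed groups refine an anchored candidate's
boundary when their reference coordinates continue the anchor's
reference outward (this recovers the short fragment upstream of the
subgroup-B deletion). Boundaries are then extended along the outermost
diagonals with an ungapped X-drop walk that stops at the reference
ends, which lands within a few nt of the planted element edges.

Classification: no internal-probe coverage anywhere in the candidate or
its flanks ⇒ solitary LTR; otherwise pseudogene hallmarks are tested —
U3 (or U5) reference columns ≥50% unaligned in the terminal LTR
regions, plus a poly-A run (≥12 nt, ≤1 internal mismatch) starting
within 30 nt downstream (the search window includes the candidate's
last 40 nt to absorb boundary slop). `(U3-deleted or U5-deleted) and
poly-A` calls a processed pseudogene; everything else full-length is a
provirus. The B-subgroup 110-nt U3 deletion removes only ~44% of U3
columns, safely below the 50% hallmark threshold.

Orthology scores all cross-species locus pairs by flank identity: the
5' flanks and 3' flanks (500 nt each), the first trimmed by 25 nt and
aligned within the second with free end gaps so that small scan-boundary
offsets do not register as divergence. A pair is supported when both
identities reach 0.75 over ≥200 columns — expected identity at a 19-My
split is ~0.83–0.78 versus ~0.55 for unrelated flanks — and greedy
matching keeps each locus in at most one pair.

## Phylogeny

Distances: p-distance or K2P, always with pairwise deletion (gap/N in
either row excludes the column); K2P raises a saturation error when a
log argument is non-positive. Neighbor joining follows the Saitou–Nei
Q-criterion with ties broken by the smallest index pair; negative
branch lengths are clamped to zero with a log warning. On additive
matrices the implementation recovers topology and branch lengths
exactly (the suite checks this against an exhaustive least-squares
topology search up to six taxa, and against scikit-bio's NJ on noisy
matrices). The bootstrap resamples alignment columns (default 1000
replicates), skipping (and counting) replicates with undefined
distances; support is the percentage of replicate trees containing
each original bipartition. An alignment of identical sequences is
reported as having no internal structure rather than fabricated
supports.

Subgroup extraction works on supported bipartitions because the tree is
unrooted: for each edge with support ≥ threshold (default 70; the
nested-B2-style structure needs ≤68) the side whose tips sit at the
more uniform distance from the edge is the subgroup candidate — loci
descending from one ancestral element are clock-like, the remainder of
the tree is not. Candidates of ≥5 tips are accepted greedily into a
laminar family; maximal sets become subgroups A, B, … by decreasing
size, and ≥2 supported sets directly nested inside one subgroup become
its sub-labels (B1, B2). If exactly two subgroups partition the tree,
only one side of their single separating edge is proposed, so a
clock-like residual complement that is itself a side of a supported
edge is rescued as the second subgroup.

Majority-rule consensus takes the most frequent base per column (ties
alphabetical; N ignored) and drops columns where the gap outnumbers
every base.

## Dating

Per locus, two routes: (i) LTR–LTR — global-align the pair, strip every
column belonging to a CpG in either row (both columns of the
dinucleotide, pairing across gaps), p-distance with pairwise deletion,
`T = D/SR/2`; fewer than 100 comparable sites flags low confidence.
(ii) gag versus the subgroup's majority-rule gag consensus, `T = D/SR`,
only for loci assigned to a labelled subgroup (a consensus over the
heterogeneous "others" is unreliable and deliberately not built). The
combined age averages the available routes unless their coefficient of
variation exceeds 0.20, in which case the LTR-based age — the method
applicable to every locus — is reported alone and the exclusion
flagged. The "SD > 20%" exclusion is interpreted as relative
(CV > 0.20): an absolute 0.2-My cutoff would exclude essentially every
multi-method locus at 15–25-My scales; `sd_mode="absolute"` is
available. Dataset summaries report per-subgroup mean/min/max and a
Welch t-test of subgroup-A ages against all others, skipped with a note
under zero variance or <2 members.

Calibration facts worth knowing, all measurable with the simulator: at
CpG multiplier 10 the stripped LTR estimator is nearly unbiased (slope
≈0.95–1.0 over 5–30 My) because divergence inflation from ancestral
CpG sites that decayed in both copies — and therefore escape stripping —
compensates the saturation and created-CpG losses. The gag-consensus
route has no such compensation (the consensus retains ancestral CpGs,
so those columns are always stripped) and runs ~15–20% young at the
old end; dispersion-based exclusion bounds its influence on combined
ages. Without hypermutation (multiplier 1) the stripped estimator is
biased ~15% young across the range — CpG stripping removes real signal
when there is no fast clock to remove.

## Numerical and degenerate-input choices

Ties: NJ Q-minimum by smallest index pair; PBS by smaller offset then
library order; ORFs by length then 5'-most start; consensus bases
alphabetically. Zero comparable sites raise an error rather than
returning 0. Empty datasets produce empty tables with exit code 0.
Coordinates are 0-based half-open internally and rendered 1-based
inclusive in all reports; converting twice is the identity.

## Problem sizes

The bundled benchmarks run at desk scale by design: two ~0.5-Mb genomes
with ~100 insertions, 50 proviruses for age recovery, 20 orthologous
pairs, bootstraps of a few hundred replicates on ≤60-tip alignments.
These sizes make every result reproducible in seconds while keeping
each estimator in the statistical regime the full-size analyses occupy
(hundreds of loci, 1000 replicates); nothing in the implementation is
specific to these sizes.

## What the synthetic benchmarks do not show

The generator emulates the statistical structure the analyses assume —
neutral clock, independent LTR evolution, CpG hypermutability,
subgroup-level indels, orthologous placement — but not: insertions
nested inside other repeats, indel evolution within loci (real LTR
alignments need gap handling the exact-alignment shortcut sidesteps),
segmental duplications or non-uniform host composition (the background
is i.i.d. uniform, so scan specificity on real genomes, where simple
repeats and related ERV families abound, will be lower), selection, or
recombination between elements. Coding segments use one fixed codon
per amino acid, so simulated base composition is T-biased rather than
purine-biased as in real gammaretroviral elements; the composition
report is descriptive and nothing downstream depends on it. Passing
benchmarks therefore demonstrate correctness of the estimators under
their own model assumptions, not field performance on genome
assemblies.
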