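# Methods

This note records the models implemented, the defaults and why, the
numerical conventions, and what the simulator does and does not emulate.

## CDS filtering

A protein-coding gene enters codon-usage analysis only if its spliced,
strand-corrected sequence (i) is at least `min_length` = 300 bp, (ii) has
length divisible by 3, (iii) begins with a codon in `valid_starts`
(default {ATG}; GTG/TTG can be enabled for plastid genes using
alternative starts), (iv) ends with a codon in {TAA, TAG, TGA}, and (v)
contains no internal stop. Genes duplicated by the inverted repeat are
analyzed once (first annotated copy). A codon containing an ambiguous
base is dropped from counting; a gene with more than 5 % such codons is
excluded with a logged warning. Coordinates are 0-based half-open
internally and converted to 1-based inclusive only at the GenBank
boundary, which keeps junction-overlap arithmetic free of off-by-one
ambiguity.

The genetic code is the standard table; the bacterial/plastid table
agrees on every sense-codon degeneracy used here. Isoleucine is the sole
three-fold family; Met and Trp are excluded from all bias statistics.

## Codon-usage indices

**RSCU.** RSCU(c) = x_c · k / Σ_family x. A family with zero usage gets
*missing* values rather than zeros: a fabricated 0 would mimic extreme
bias in downstream ΔRSCU comparisons. Family RSCU values sum to the
degeneracy whenever the family is used (property-tested).

**ENC.** Wright's estimator with the F̂ form; amino acids counted once
(n ≤ 1) are excluded from class means because F̂ is undefined there. If
the three-fold class (Ile) is missing it is imputed as (F̄₂ + F̄₄)/2,
following the convention of the classic implementations; if a two-,
four- or six-fold class is missing the gene's ENC is reported missing.
Values are capped at 61.

**GC3 vs GC3s.** GC3 (the neutrality plot's x-axis) is computed over the
third positions of all sense codons including ATG/TGG; GC3s excludes
non-synonymous codons. The two quantities are deliberately distinct, as
in the classic codon-usage tool chains.

**PR2.** A3/(A3+T3) and G3/(G3+C3) over third positions of the five
four-fold families only; (0.5, 0.5) is the strand-symmetric point.

## Selection analyses

The expected-ENC curve is ENC* = 2 + s + 29/[s² + (1 − s)²] with
s = GC3s; "below curve" uses strict `enc < enc*`. The neutrality fit is
ordinary least squares of GC12 on GC3, one fit per taxon across its
genes; the decomposition is 100·b (relative neutrality), 100·(1 − b)
(relative constraint) and b/(1 − b). When several taxa are analyzed, the
pipeline reports per-taxon slopes and their mean.

ENC groups take the ⌈fraction·n⌉ lowest- and highest-ENC genes
(default fraction 0.05, minimum one gene, ties broken by gene name for
determinism and order invariance). Group RSCU is computed from counts
*pooled within each group*, not from averaged per-gene RSCU — pooling is
stable for short genes and matches how a single value per group is
reported in practice. ΔRSCU is low-ENC (high-bias) minus high-ENC
(low-bias), so optimal codons have positive ΔRSCU; the optimality rule
is ΔRSCU > 0.08 ∧ RSCU(high-bias) > 1 ∧ RSCU(low-bias) < 1. All values
are carried at full precision and rounded only when written.

## Sliding-window diversity and HVRs

π in a window is the mean over sequence pairs of the proportion of
differing sites among compared sites. Gap handling is per-window
complete deletion — a column with any gap or N is excluded in that
window — matching the default sites treatment of the standard DNA
polymorphism software; the denominator is the number of compared sites,
not the nominal window length. Windows start at column 0 (defaults
600/200); a trailing window shorter than the window length is kept if at
least half the window length, else dropped (logged either way). The HVR
threshold is mean + 2·SD with the sample (n − 1) SD — at realistic track
sizes the ddof choice is numerically irrelevant at four significant
figures, but determinism requires fixing one. Windows with π strictly
above threshold are selected and merged when their spans overlap or
abut; a region's peak π is its maximum member-window π. Coordinates are
alignment columns, liftable to a named taxon's ungapped coordinates. An
optional mask supports computing the track with one IR removed.

## Quadripartite partition and junctions

IR detection is seed-and-extend: exact 25-mers shared between the
sequence and its reverse complement are grouped by anti-diagonal, merged
into maximal exact runs (circularly, across the origin), and bridged
across short gaps while the total mismatch rate stays ≤ 0.1 %; run ends
remain exact-match bounded, so junction coordinates are unambiguous. The
top-scoring disjoint pair defines the IRs; the longer single-copy gap is
the LSC. Region labels follow the forward reading direction of the
input (IRb is the IR after the LSC), and a canonical representation
(rotate LSC to 0; of the two strand representatives keep the
lexicographically smaller string) is provided so that detection is
invariant to rotation and full reverse complement.

Junction placement reports, for each gene of interest, either the two
positive part lengths when the gene straddles a junction (they sum
exactly to the gene length) or a signed distance to the nearest junction
(negative = the gene ends before the junction). Default genes tracked:
rps19, rpl2, ycf1, ndhF, trnH.

## Simulator

The generator builds an ancestral circle LSC + IRb + SSC + IRa with IRa
the exact reverse complement of IRb, places protein-coding genes
(minus-strand fraction 0.25), junction-straddling genes with configured
overhangs, and evolves taxa along a newick tree under Jukes–Cantor with
per-region rate multipliers. Design choices:

- **Codon bias model.** Within each synonymous family codon
  probabilities are proportional to weights w(c) = t(c)·b(c): t(c) is
  `gc3_target` for G/C-ending codons and 1 − `gc3_target` otherwise, and
  b(c) is the preferred-codon boost (`codon_weight`, times
  `high_bias_weight` in the high-bias gene subset, which may also have
  its own `high_bias_gc3`). Expected RSCU is k·w/Σw in closed form,
  giving analytic recovery targets. Per-gene amino-acid composition is
  Dirichlet-distributed (`aa_alpha`, default 5) and per-gene GC3 jitters
  by ±`gc3_jitter` (default 0.08) so gene profiles are non-degenerate.
- **Defaults.** Mini scale: 20 kb genome, 4-kb IRs, 2-kb SSC, 12 genes
  of 300–900 bp, `gc3_target` 0.30 (plastid-like third-position GC),
  star tree of 4 taxa at 0.005 substitutions/site, one rps19-like gene
  with a 110-bp IRb overhang, one gene fully inside the IR (annotated in
  both copies, second flagged as the IR duplicate). A full-scale
  ~151 kb/25.8-kb-IR mode is used for integration runs; the mini scale
  keeps the default test suite fast.
- **Substitutions only.** Jukes–Cantor; indels are off, so the taxon
  sequences are their own true alignment and window coordinates are
  exact for hotspot-recovery tests. Mutations that would break a start
  or stop codon or create an internal stop are rejected, keeping
  generated CDSs filter-compliant. IRa sites are never mutated
  independently: IRb substitutions are mirrored, preserving the
  quadripartite invariant in every taxon; IRb positions whose mirror
  falls inside a gene annotated in IRa are held fixed so the mirror
  cannot silently break a coding constraint. Junction-flanking bases are
  adjusted once (and then held fixed) so a planted IR cannot be extended
  by a coincidental base pairing — planted junction coordinates are
  exactly the maximal-repeat boundaries.
- **Determinism.** All randomness flows from one integer seed through
  one generator (layout planning uses seed + 1); the same configuration
  reproduces byte-identical sequences and manifests, and the JSON truth
  manifest regenerates the family exactly.

What the simulator does **not** emulate: indel and rearrangement
evolution, IR expansion/contraction (the partition is fixed within a
family), recombination and gene conversion beyond perfect IR mirroring,
rate heterogeneity beyond step-function hotspots, and realistic gene
content (tRNA/rRNA genes, introns beyond multi-span bookkeeping).
Passing recovery tests therefore demonstrates correctness of the
analysis arithmetic and calling rules under the stated model, not
robustness to alignment error or structural variation in real data.

## Clustering

Distances between taxon RSCU profiles are euclidean by default
(1 − Pearson available); missing entries are handled pairwise-complete.
Neighbor joining is the standard Saitou–Nei algorithm with the
Q-criterion, implemented directly so that ties are broken
deterministically by the smallest (label_i, label_j) pair and negative
branch-length estimates are clamped to zero with a log note; it is exact
on additive matrices (property-tested against independently constructed
random trees, with an independent tree library used only as the
comparator). Heatmap row/column orderings come from average-linkage
hierarchical clustering; the orderings, not rendered images, are the
tested artifact.

## Numerical conventions and degenerate inputs

Missing values are NaN throughout and propagate to "missing" table
entries, never to zeros. Output TSVs round to 4 decimal places at write
time only. Degenerate inputs fail loudly: fewer than 3 genes or constant
GC3 for the neutrality fit, fewer than 2 defined windows for the HVR
threshold, empty or overlapping ENC groups, non-symmetric distance
matrices, sequences shorter than 4× the minimum IR length. The layout
planner validates that the configured genes fit the LSC before any
sequence is sampled.

## Known limitations

- IR detection assumes near-identical IRs (tolerance 0.1 %); highly
  diverged or lost IRs correctly raise a "no quadripartite structure"
  error rather than returning a guess.
- The ΔRSCU optimal-codon rule inherits the small-sample noise of the
  pooled extreme-ENC groups; with few short genes per group, codons near
  the RSCU = 1 boundary can flip. The simulator's recovery scenarios use
  gene sizes where the planted margins are several standard errors wide.
- Per-window complete deletion makes π conservative in gappy alignment
  regions; the compared-site denominator partially compensates.
- The neutrality decomposition treats the OLS slope as the
  mutation-pressure share; it is a descriptive index, not a causal
  estimate.
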