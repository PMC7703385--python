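# Methods

This note records the models, conventions and numerical choices behind
`edsel`, and what its synthetic-data tests do and do not establish.

## Data model and conventions

Coordinates are 0-based, half-open everywhere internally; the editing-site
TSV reader accepts a one-based flag because published supplementary tables
are 1-based. Editing levels (EL — the fraction of transcript copies carrying
inosine at a site) are stored as fractions in [0, 1]; inputs above 1 are
interpreted as percent and divided by 100 with a warning. Transcripts are
sense-strand mRNA; no reverse-complement logic exists. Ambiguity codes map
to N and are excluded from every count, as are gap cells. An editing site
must sit on an A of its transcript; violations are rejected with a warning,
not an error, since published tables and assemblies drift apart.

## Ancestral states and the substitution matrix

With only three informative species per comparison, ancestral states are
reconstructed by maximum parsimony from the sister species and an outgroup
only — the focal descendant is deliberately excluded because its
substitutions are the quantity being counted. The ancestral nucleotide is
the one shared by sister and outgroup (disagreement → undetermined); an
ancestral adenine counts as *edited* (state E) only when both informative
species are edited at the homologous position. The completion for the
one-edited/one-not case — ancestor A, editing not parsimoniously ancestral —
is tallied separately (`n_edit_xor`) so its effect is auditable.

Diagonal (no-change) counts stay in the matrix: every probability in the
R/Q statistics is per opportunity, and the row sum is the only auditable
opportunity count. Focal E columns below an optional `el_min` threshold are
dropped entirely rather than reclassified as A, so the unedited-adenine
class is never contaminated with weakly edited sites.

Known bias: parsimony homoplasy. Parallel substitutions to A in the two
informative lineages misassign a small number of truly non-A ancestors to
the A row, where the focal state (usually the retained ancestral base, e.g.
G) then counts as an apparent A→G substitution. At branch lengths ~0.05–0.1
this inflates p(A→G) by a few percent and biases R<sub>→G</sub> slightly
below 1 under neutrality. The E row is largely immune (an E ancestor
requires editing in both lineages). This is a property of the MP
construction itself; it is visible in the neutral-coverage test, which
absorbs it within its tolerance band.

## R, Q and their uncertainty

* Undirected, extant pair: R<sub>N</sub> = p(E,N)/p(A,N), with p(E,N) the
  fraction of aligned E columns (optionally within an EL bin) whose partner
  state is N. Denominators are aligned columns with an unambiguous partner
  (the aligned-only convention; recorded in output counts).
* Directed: R<sub>→N</sub> = [c(E→N)/rowsum(E)] / [c(A→N)/rowsum(A)];
  R<sub>N→</sub> = p*(N→E)/p*(N→A) with the density normalization
  p*(N→E) = p(N→E)/(#E/(#E+#A)). #E and #A default to the focal E/A column
  totals of the matrix and can be overridden with transcriptome-wide counts.
* Y pools C and T **counts** before any ratio is formed (not an average of
  two ratios). Q<sub>→*</sub> = R<sub>→G</sub>/R<sub>→Y</sub> and
  Q<sub>*→</sub> = R<sub>G→</sub>/R<sub>Y→</sub>; in both, shared
  normalizers cancel algebraically, which a property test verifies.
* Synonymous/nonsynonymous splits classify each column by whether an A↔G
  interchange at the focal position (in the focal codon with that base
  forced to A) changes the amino acid; NONCODING positions are excluded.
  This single forced-A rule serves both directions: for E/A sites it is the
  ordinary synonymy of the editing site, for ancestral-N columns it is the
  "A and G encode the same amino acid here" condition.

Confidence intervals follow the observed-frequency binomial resampling
scheme: each constituent count c with opportunity n is redrawn from
Binomial(n, c/n), the statistic recomputed (default 10⁵ replicates), and
the 2.5/97.5 percentiles reported. Replicates with a zero resampled
denominator are dropped before taking percentiles. The two-sided p-value
against the neutral value 1 is twice the smaller tail fraction, floored at
1/replicates. No pseudocounts are ever added by default: statistics with a
zero denominator are emitted as undefined with their counts shown, because
pseudocounts would silently bias the headline ratios. At ~50 numerator
events the percentile CI undercovers by roughly one point — inherent to
percentile bootstraps of ratio statistics, and the reason the coverage test
carries a ±3% band.

## Editing-aware dN/dS

The edited-vs-unedited comparison is a ratio of ratios per 10% EL bin:
[dN(E→G)/dS(E→G)] / [dN(A→G)/dS(A→G)], with dN from nonsynonymous sites in
all codons and dS from synonymous sites restricted to third positions of
four-fold degenerate codon families — including the four-fold subfamilies
of the six-fold Leu/Arg/Ser families, excluding two-fold sites (a literal
reading of "four- and six-fold degenerate"). The trend across bins is
summarized by Pearson's r against bin midpoints with an F-test
(F(1, k−2) = t², identical to the usual correlation t-test).

The positive-selection form takes nonsynonymous substitutions at edited
adenines against synonymous ones at unedited adenines,
[p(E<sup>non</sup>→G)/p(A<sup>syn</sup>→G)]·(ξ<sup>non</sup>/ξ<sup>syn</sup>),
where ξ<sup>non/syn</sup> = 1/Σ<sub>codons</sub> f(c)·K<sup>non/syn</sup>(c)
and K counts the nonsynonymous/synonymous A→G opportunities of each codon
(for every codon, K<sup>non</sup>+K<sup>syn</sup> equals its adenine
count). Values above 1 at high EL thresholds indicate positive selection on
the E→G transition. Both the EL-bin sweep and the EL-threshold sweep are
implemented, since the two parameterizations answer slightly different
questions (trend vs high-EL excess).

## Sequence context

Motif profiles report per-position nucleotide frequencies over ±k flanks
(default k = 5) and information content 2 − H in bits, without small-sample
correction. The ±1 mismatch analysis counts, at editing-status-discordant
(E–A) and concordant (A–A) homologous adenine pairs, flank mismatches per
side and type; R<sup>±1</sup> = [#(EN₁,AN₂)/#(E,A)] / [#(AN₁,AN₂)/#(A,A)],
with significance from a chi-squared test on the 2×2 matrix
[[#(EN₁,AN₂), #(AN₁,AN₂)], [#(E,A), #(A,A)]] exactly as constructed, and a
Bonferroni factor m = 12 (the ordered N₁≠N₂ pairs per flank position),
printed in the output so alternative conventions are auditable. A–A flank
mismatches are counted in both orientations (totals doubled), making the
statistic invariant to which species is listed first.

The window-span analysis correlates |ΔEL| of conserved editing sites
(edited in both species of a close pair; the absolute difference is the
symmetric reading of "editing-level difference") with the number of
nucleotide mismatches inside a window of span W centered on the site,
excluding the focal position and gap columns, clipping at transcript ends;
the argmax over W estimates the span of context that shapes editing. Both
flanks are counted jointly (a centered window).

## Structure

Structural potential is Z = (E − μ)/σ, where E is the window's folding
energy and μ, σ summarize the energies of dinucleotide-preserving shuffles
(Altschul–Erickson Euler-path construction, preserving length, first
nucleotide and the exact dinucleotide multiset; default 50 shuffles per
window). Windows span 20–350 nt; starts and lengths are strided (defaults 5
and 10; exhaustive enumeration is quadratic and supported but slow). A
position keeps the minimum Z over covering segments if below −2, else null.
σ = 0 (degenerate shuffle sets) yields Z = 0, flagged.

The original analysis used RNASurface's internal energy model, which is not
reproducible from its description; the default here is a deliberately
simple stacking approximation — the best single helical stem found over all
pairing registers, scored with per-pair weights GC −3.4, AT −2.2, GT −1.2
(kcal/mol-like), minimum loop 3, single pairs scoring 0 — behind a
pluggable energy-function interface, with the model id stamped into every
profile. All Z-dependent results are therefore model-relative: the Z-score
*construction* is faithful, the energies are not RNASurface's, and
structure comparisons should be read qualitatively. ΔZ tail asymmetry
between edited and unedited members of homologous pairs (|ΔZ| > 2) is
tested with a two-sided binomial test, optionally backed by a
Wilcoxon signed-rank comparison of random 100-pair samples per site class.

## Fixation race

For a strongly selected new mutation (4N<sub>e</sub>s ≫ 1; a warning fires
below 4N<sub>e</sub>s = 10) in a mutation-limited population
(N<sub>e</sub>µ ≪ 1), expected fixation waiting time is 1/(4N<sub>e</sub>sµ),
and the first of two competing mutation classes to fix is decided by the
products µs: P(editing first) = Mµ₂s₂/(µ₁s₁ + Mµ₂s₂). The race is modeled
as competing exponential clocks with rates proportional to µ·s; a
Monte-Carlo simulation of those clocks cross-checks the closed form. No
standing variation is modeled, matching the regime of validity.

## Synthetic-data generator

The generator emulates the statistical structure the estimators assume, at
the scale the analyses state:

* Root CDS drawn codon-wise uniformly over the 61 sense codons (no internal
  stops); per-transcript lengths Poisson around the configured mean.
* Editing sites at a configurable fraction of root adenines (default 0.01,
  the coleoid-like density) with Beta(1, 9) ELs by default — a modeling
  choice (no generative EL model exists to copy), configurable.
* Latent editable positions at the same density among non-A root bases: a
  non-A ancestor there that mutates to A yields an edited adenine. Without
  these, ancestral G→E and Y→E events would be structurally impossible and
  the backward statistics undefined even under neutrality. Only the G→A
  channel carries the k<sub>GE</sub> multiplier.
* An ADAR-like ±1 motif (G depleted at −1, enriched at +1) planted by
  resampling neighbors of edited sites, redrawing if a stop codon would
  arise; optional perfect hairpins (12-bp stems) planted disjointly around
  edited sites for structure tests.
* Branch evolution: star topology, K80 with ts/tv κ = 2 by default,
  normalized to the configured expected substitutions/site; multipliers
  k<sub>EG</sub>, k<sub>EY</sub> scale the A→G and A→Y channels at editing
  sites, k<sub>GE</sub> the G→A channel at editable sites. One transition
  matrix per branch and site category (mid-branch category switching is
  ignored — adequate at branch lengths ≤ 0.1).
* Editing status is inherited iff the base remains A; descendant ELs blend
  the root EL with a fresh Beta draw (correlation ρ = 0.9 by default).
  Alignments are the true, gapless homology. All randomness flows from one
  seed through spawned per-transcript streams; outputs are byte-identical
  across runs.

What a green test does **not** establish: the generator has no indels, no
rate heterogeneity beyond the editing multipliers, no tissue-specific ELs,
no alignment error, and its editing levels and motif are stylized. Recovery
of planted parameters validates the estimators' algebra and calibration,
not the biological conclusions on real data.

The |ΔEL|-context coupling planter overwrites conserved-site EL pairs with
a monotone function of the mismatch count inside the chosen window plus
Gaussian noise, so the planted span is recoverable as the correlation
argmax; windows narrower than the span lose signal, wider ones dilute it
with independent mismatches, giving the characteristic peak.

## Reproducing the published full-data numbers

The published cephalopod values (pooled squid–cuttlefish Q<sub>→*</sub> ≥
3.49; R<sub>G</sub> ≈ 8 at high EL in the *Octopus* lineage) require the
upstream per-species transcriptomes and editing-site tables and orthogroup
alignments built from them (e.g. BLASTn merging), which involve large
downloads and are outside the desk-scale test suite. With those inputs laid
out as described in the README, the same `edsel subst`/`edsel rq` pipeline
applies unchanged.

## Open choices made

* NONCODING sites are kept for R/Q (flagged) and excluded from dN/dS.
* The "strongly edited" default threshold is 0.8 (the source analyses never
  print their cutoff); it is configurable everywhere it is used.
* Bonferroni correction is applied only where the context analysis states
  it; all other p-values are reported raw.
* The resampling seed is a required argument and is surfaced, with every
  other tunable, in the pipeline manifest.
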