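# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the `rumivirome` pipeline. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates, presence, and coverage summaries

All genomic intervals are 0-based, half-open. A taxon is *present* in a
sample when its share of the sample's classified reads strictly exceeds
0.001% (1e-5); presence is therefore invariant to library size. *Core*
taxa are those present in 100% of samples — strictly, so a single absence
excludes. Coverage summaries follow mapping-tool conventions: the trimmed
mean discards the lowest and highest 5% of per-position depths by default
(the trim fraction is configurable and surfaced in every call signature,
since upstream tools do not agree on one value), and *breadth* is the
fraction of positions at or above a depth floor.

## Synthetic community generator

The generator is the pipeline's substrate for validation and defines the
study conditions of every simulation-based check:

- **Genomes.** Host genome background is i.i.d. uniform nucleotides. This
  is deliberate: a neutral background minimizes accidental repeats that
  would confound the CRISPR detector's false-positive measurements. A
  consequence is that synthetic genomes lack the compositional biases,
  mobile elements and low-complexity tracts of real MAGs, so detector
  false-positive rates measured here are optimistic relative to real
  genomes (real CRISPR tools carry extra guards for the same reason).
  Conspecific strains diverge by 0.5% substitutions from a common ancestor.
- **Prophages.** About half of strains carry one integrated prophage
  (prophage_rate = 0.5, matching the roughly one-in-two carriage rate
  typical of gut/rumen genome catalogs), inserted as a contiguous copy of
  a simulated viral genome with ≥5 kb of host flank on each side. No
  attachment-site duplication is modeled; the analyses never use att sites.
- **CRISPR arrays.** Each array has 4–6 identical repeats (23–47 bp)
  separating 3–5 spacers (26–50 bp); a configurable fraction of spacers
  (default 0.7) are verbatim substrings (≥30 bp) of a designated viral
  genome, which defines the planted (strain, vOTU) linkage truth table.
- **Abundances.** Per-sample taxon proportions are log-normal with
  configurable σ and group effects in log2-fold units, then multinomial
  read counts at each sample's library size.
- **Coverage.** Per-position depths are i.i.d. Poisson; prophage induction
  multiplies the rate inside the prophage interval.
- **SNVs.** Candidate point mutations arise per site and are accepted with
  probability ∝ 1 (synonymous) or ∝ ω (nonsynonymous), standard genetic
  code, stop-introducing changes rejected. This is an opportunity-weighted
  acceptance model, not a population-genetic forward simulation: it
  controls the nonsynonymous/synonymous flux ratio directly, which is what
  pN/pS estimation needs, but carries no linkage, frequency spectrum, or
  demography.
- **Network abundances.** Latent multivariate Gaussian draws with a given
  sparse precision matrix are mapped through softmax to proportions and
  multinomial counts; the truth edge set is the precision support.

All generators are pure functions of (config, seed); a fixed seed gives
byte-identical output. What passing tests show about real data is limited
by the generator's idealizations: uniform background, i.i.d. coverage (no
GC or edge effects), well-separated strains, and noise-free annotation
inputs.

## Prophage catalog

The calling rule consumes external discovery annotations (provirus flags
and gene→VOG assignments) and applies the two-category rule: flagged
intervals pass through as `checkv_integrated` regions; contigs with no
flag but at least one lysogeny marker (integrase VOG00021, excisionase
VOG00006/VOG05065, Cro VOG00002, CI VOG00692) become whole-contig
`marker_gene` regions. For the marker category the true prophage
boundaries within the contig are unknowable from markers alone, so the
whole contig is recorded and the interval flagged as approximate.

vOTU clustering is greedy centroid clustering at ≥95% ANI over ≥85% of the
shorter sequence: sequences are visited longest-first (ties by id), so the
representative is always the longest member and the output is independent
of presentation order. ANI is fragment-based: the shorter sequence is cut
into 500 bp fragments, each locally aligned (+1/−1/−2 match/mismatch/gap)
to the longer; a fragment counts as aligned when the local alignment spans
at least half of it. Desk-scale only — for catalogs beyond a few thousand
sequences a k-mer prefilter would be needed.

Activity calls compare prophage and flanking-host depth vectors: *active*
requires both a median depth ratio ≥1.65 and Cohen's d ≥ 0.6 (thresholds
mirroring prophage-activity tools; both configurable), *untested* when
either region has breadth <0.5 or the flank is shorter than 1 kb. A
prophage is non-cryptic when active in any sample (an OR-fold across
samples).

## CRISPR detection and host linkage

The detector is an exact-repeat scanner in the CRT family: 8-mer seeds
recurring at spacings compatible with one repeat+spacer period (49–97 bp)
are chained into runs, and repeat boundaries are then extended by
consensus across *all* copies — extension stops at the first position
where any copy disagrees. Pairwise extension (using only two copies) was
rejected because a chance boundary-base match between two copies shifts
the repeat and corrupts every spacer; consensus extension mis-extends only
when all copies agree by chance (probability 4^−(c−1) per boundary for c
copies). Arrays whose spacers are mutually >60% identical are rejected as
tandem repeats. Repeats are required to be exact copies; degenerate
repeats with internal mismatches, which real arrays occasionally have, are
not chained — a deliberate simplification that trades recall on degraded
arrays for a near-zero false-positive rate.

Protospacer matching is full-length, ungapped, both strands, because 100%
identity over a ≤50 bp spacer leaves no meaningful role for gapped
alignment. Perfect matches qualify for linkage; single-mismatch hits are
reported separately as candidate escape mutations and never create
linkages. Strain presence uses two conjunctive gates (≥5 mapped reads AND
≥50% aggregate breadth — the standard strain-profiling recommendation);
vOTU presence needs ≥70% covered fraction. A linkage requires a perfect
spacer match plus co-occurrence of strain and vOTU in at least one sample.

Per-sample host-specificity classes each *present* linked vOTU:
`multi_species` when its present linked hosts span ≥2 species,
`conspecific_partial` when they are a strict subset of the present strains
of one species, `single_strain` otherwise; fractions are over the sample's
classified vOTUs (the denominator choice — linked vOTUs rather than all
vOTUs — is configurable in spirit but fixed here, as the alternative is
not computable without full infection knowledge).

## pN/pS

Opportunity counting is Nei–Gojobori: each codon's 9 point mutations
partition into synonymous and nonsynonymous fractions (stop-producing
changes count as nonsynonymous), so synonymous + nonsynonymous sites sum
to exactly 3 per codon and to the gene length over a gene. A gene in a
sample is evaluated only at >99% breadth (strict) and ≥10× mean coverage;
otherwise the value is missing rather than zero. Two modes exist because
practice varies: `site_normalized` (default) returns
(N_obs/N_sites)/(S_obs/S_sites); `raw_counts` returns N_obs/S_obs.
S_obs = 0 with N_obs > 0 yields +∞ (a real signal, kept distinct from
missing). Multi-allelic positions contribute each alternate allele as a
separate event. A gene is flagged as under diversifying selection when
pN/pS > 1 in a strict majority of its gate-passing samples.

## VHR

VHR = prophage trimmed-mean coverage / host-species read count, with
deliberately mixed units: it is a within-linkage relative quantity, never
compared across linkages. Host reads enter raw (no library-size
normalization): the group comparison is a rank-based Kruskal–Wallis within
each linkage, so any monotone per-linkage rescaling leaves the test
unchanged. Groups with fewer than six samples are dropped before testing;
p-values are BH-adjusted across linkages and significance reported at
q < 0.01. For total n ≤ 12 per linkage the exact permutation distribution
of H is fully enumerated instead of the χ² approximation, so small
two-group designs attain their exact attainable minimum p.

## Diversity statistics

PERMANOVA is the one-factor adonis2-style partition of squared
distances, with p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm). Restricted
permutations shuffle labels only within blocks, the appropriate null when
a blocking factor (e.g. breed) confounds the grouping; a block lying
entirely in one group triggers a warning since no rearrangement within it
is possible. PCoA drops negative-eigenvalue axes and reports their total
magnitude rather than applying a correction (Cailliez-style corrections
change distances, which we prefer to surface, not hide). Differential
abundance applies the pre-test filters first (microbes: >0.01% relative
abundance in ≥60% of samples; vOTUs: non-zero in ≥50%), then a linear
model on CLR-transformed counts with BH correction and significance at
q < 0.1. The CLR model is an uncorrected compositional regression — a
simple, transparent stand-in for bias-corrected methods; its per-feature
effects are CLR mean differences and inherit CLR's compositional coupling.

## Networks

The precision estimator minimizes tr(SΘ) − log det Θ + λ‖Θ‖₁,off by
proximal gradient descent with backtracking: the gradient step uses
S − Θ⁻¹, the proximal step soft-thresholds off-diagonals (yielding exact
zeros, so the support *is* the edge set), and positive-definiteness is
maintained by the line search. It agrees with an independent
coordinate-descent implementation to ~1e-3 on test fixtures. A
Meinshausen–Bühlmann neighborhood-selection fallback (per-node lasso, OR
rule) sits behind the same interface. The default penalty path is 30
log-spaced values from λ_max (largest absolute off-diagonal covariance)
down two decades.

Penalty selection is StARS: the path is refitted on row subsamples, edge
instability 2θ̂(1−θ̂) is averaged over node pairs, monotonized from the
sparse end, and the smallest λ with instability ≤ 0.05 is chosen (largest
λ, with a warning, when none qualifies — which on null data correctly
yields an empty graph). The subsample size is the canonical
b(n) = min(⌊0.8 n⌋, ⌊10√n⌋): at n in the hundreds, 0.8 n subsamples share
most of their rows, instability never registers, and selection drifts
over-dense; the √n rule keeps subsamples near-independent and restores the
method's published operating characteristics.

Graph metrics use the unweighted simple graph (edge signs are stored as
partial-correlation signs but not used): CNM greedy modularity with
deterministic smallest-pair tie-breaking, returning the partition at the Q
maximum along the merge path; unnormalized Brandes betweenness (so the
keystone thresholds, degree >15 and betweenness >15 000, are on the raw
scale — for small synthetic graphs the thresholds must be rescaled by the
caller); categorical assortativity from the edge mixing matrix, undefined
(NaN) for single-category graphs. In the virus–microbe network, viral
nodes carry their predicted host's phylum as category, so assortativity
measures whether viruses connect within their predicted host clade. The
microbe-only vs combined comparison is a paired one-tailed t-test on
per-microbial-node degree (alternative: combined > microbe-only), with
t = 0, p = 0.5 for identical networks.

## Problem sizes used in validation

Simulation-based checks run at desk scale, chosen once as realistic for
the data-generating models: chain-precision recovery and null-network
checks use 30 taxa at n = 500 samples; the paired network comparison uses
30 microbes + 15 viruses (3 phyla, 2 hosts per virus, couplings 0.45) at
n = 400 over 20 seeds; pN/pS recovery uses 300-codon genes at 20× depth
over 200 paired replicates; PERMANOVA calibration uses 500 null data sets
of 20 samples with 199 permutations; VHR power uses 50 linkages (20%
induced 5×) at 10 samples per group over 50 replicates.

## Known limitations

- The ANI routine is alignment-based and quadratic per fragment; it is not
  meant for large catalogs.
- The CRISPR detector requires exact repeat copies and forward-orientation
  scanning (both protospacer strands are searched instead); degraded
  arrays are missed by design.
- The marker-gene prophage category cannot localize the prophage within
  its contig.
- The CLR differential-abundance model is not bias-corrected; effects on
  low-abundance features inherit compositional coupling.
- Repeat-boundary recovery is ambiguous when every spacer happens to share
  its first or last base with the repeat; such arrays (rare under the
  generator, unavoidable for any detector) are recovered with a
  one-base-shifted repeat.
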