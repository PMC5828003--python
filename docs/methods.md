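# Methods

## Problem and model

`regshare` post-processes GWAS summary statistics for several related
phenotypes measured against a common background (the motivating setting is
three lung-cancer subtypes genotyped on one chip with shared controls).
The analysis makes no attempt to re-estimate association; it consumes
p-values and asks a downstream question: *which genes are plausibly
regulated by the moderately associated germline variation of each
phenotype, and how much of that regulatory signal is shared?*

The causal chain assumed is: a genotyped tag SNP with p below a selection
threshold stands in for a set of correlated variants; any member of that
LD set that is a significant eQTL for a gene, or falls inside an enhancer
with a known target, links the association signal to that gene. The union
of such target genes over all evidence sources is the phenotype's
*germline-regulated gene set*. Because LD expansion deliberately smears
signals over megabase windows, genes are further collapsed into
*independent loci* before cross-phenotype comparison, so one physical
signal is not counted as several shared genes.

## Stages and parameters

| parameter | default | meaning |
| --- | --- | --- |
| `p_select` | 1e-3 | per-phenotype SNP selection threshold (strict `<`) |
| `r2_expand` | 0.8 | LD-proxy threshold, strict `>` on haplotype r² |
| `window_bp` | 1,000,000 | physical half-window for expansion (± around tag) |
| `r2_prune` | 0.5 | pruning threshold, `>=` removes one pair member |
| `prune_window_variants` / `prune_step_variants` | 50 / 5 | sliding-window size/step (variant counts) |
| `q_max` | 0.05 | single-tissue eQTL q-value cut, inclusive `<=` |
| `posterior_min` | 0.8 | multi-tissue eQTL posterior cut, strict `>` |
| `cluster_bp` | 1,000,000 | max inter-span gap within one locus |
| `n_trials` | 10,000 | randomization draws |
| `alpha` | 0.05 | enrichment significance on adjusted p |

Boundary semantics are part of the contract and pinned by tests: q uses
`<=`, posterior uses `>`, expansion uses `>`, pruning uses `>=`.

**r² on haplotypes.** r² = D²/(p_A q_A p_B q_B), D = p_AB − p_A p_B, with
frequencies counted over phased haplotype columns, not genotype dosages —
the reference panel is phased by construction, and haplotype counting
avoids the EM step unphased data would require. Monomorphic loci have no
defined r²; `compute_r2` raises, and the vectorised matrix path returns
NaN, which consumers treat as "no evidence of linkage".

**Pruning.** PLINK-style greedy sliding window per chromosome: within
each window of 50 consecutive kept variants, while any pair has
r² ≥ 0.5, one member is removed, then the window advances by 5 kept
variants. The removal rule — drop the member with the smaller minor
allele frequency, tie broken by dropping the larger coordinate — is an
implementation detail PLINK does not specify; it is fixed here for
determinism and favours better-tagged variants. The published analysis
states only r² = 0.5; the window/step defaults are conventional values
and are configurable. Monomorphic variants are always kept (undefined r²
cannot certify strong linkage). Tags absent from the panel are skipped
with a count, never fatal: chip↔panel identifier mismatch is the norm
with real data.

**Annotation.** Exactly four categories — coding, UTR, intron,
intergenic — with precedence coding > UTR > intron applied across all
transcripts overlapping the position; in-span positions in no CDS/UTR are
intronic (this also absorbs exonic-but-noncoding positions of ncRNA-style
models), and the categories partition any SNP list by construction.
Identifier/coordinate remapping is a pure table join (the table being the
output of an external liftover/dbSNP-merge computation, out of scope
here); when several old identifiers merge into one new one, the smallest
p-value is kept.

**Probe catalog cleaning.** Rows without an annotated gene name are
dropped; duplicate probes for one (SNP, gene) merge keeping the smallest
q-value — "merged" admits several rules, and the minimum preserves every
significance decision the unmerged table would have made. The probe
catalog is treated as pre-filtered upstream (its published form ships at
10% FDR), so membership in the expanded SNP set is the only filter
applied by default; a `q_max` knob exists.

**Predicted enhancers.** Zero-RPKM transcript targets are removed
*before* transcript→gene collapsing, so an unexpressed transcript cannot
rescue a gene via a sibling transcript; hits merge across cell lines and
deduplicate on (SNP, gene).

**Locus clustering.** Single-linkage chaining per chromosome (bedtools
`cluster -d` semantics): sort spans by start; a span joins the open
cluster iff the gap from the cluster's running max end is ≤ 1 Mb, with
overlap counting as gap 0. Cross-phenotype locus overlap is computed by
clustering the union of all phenotypes' genes once and marking each locus
with the phenotypes whose gene set intersects it, so locus identity is
shared across phenotypes by construction.

**Randomization null.** Each trial draws one subset per phenotype,
size-matched to the pruned per-phenotype SNP sets, uniformly without
replacement from the pruned chip pool, *independently across phenotypes*
(one SNP may appear in several subsets — mirroring independent
size-matched selection), and records the size of the all-sets
intersection. The analytic expectation N·Π(nᵢ/N) provides an exact
cross-check. The empirical p uses the (1 + k)/(1 + n_trials) correction
to avoid p = 0 from finite trials; the raw frequency is preserved in the
reported distribution. The generator is numpy's PCG64; drawing is
vectorised by ranking a uniform matrix, which is exact, and chunked to
bound memory.

**Enrichment.** Upper-tail hypergeometric P(X ≥ k) including the observed
point mass (standard over-representation convention), computed with
scipy's survival function; BH step-up via statsmodels. The background
universe defaults to all genes reachable through any regulatory catalog —
an explicit, reproducible choice where web tools keep their universe
implicit — and can be overridden by file. Pathways are intersected with
the background before testing; results sort by raw p with ties broken by
pathway id.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions end to end. LD blocks use
founder-copy-with-flips: every SNP in a block copies the block founder
with per-haplotype flip probability ε = (1 − r²_target^¼)/2, which gives
expected pairwise r² = (1 − 2ε)⁴ exactly at founder frequency ½ and
approximately elsewhere; blocks are mutually independent and separated by
3 Mb so no expansion window crosses blocks. This gives exact control of
the target r² with no external simulator, at the cost of realism: no
recombination gradient within blocks, no allele-frequency spectrum, no
population structure.

Default study conditions: 60 blocks × 8 SNPs (480 panel SNPs), 600
haplotypes, within-block r² 0.9, MAF ∈ [0.1, 0.5], three phenotypes with
3 shared planted signal SNPs (one per block) and 2 private SNPs each,
planted p ~ U(0, 10⁻⁴), null p ~ U(0, 1), a 200-gene universe (9 planted
targets + 191 decoys), 20 pathways. The three shared target genes sit
within 600 kb of each other (one locus); every private or decoy gene sits
on its own locus. Planted (SNP, gene) pairs are assigned cyclically to
the five evidence sources so each mapping path is exercised; decoy
catalog rows are built to fail their source's filter (q ∈ (0.06, 1],
posterior < 0.8, unannotated gene names, RPKM = 0, enhancers in empty
territory). Per-phenotype SNP counts at the selection threshold are
configurable through the number of planted signals and the panel size;
matching chip-scale counts (~550 per phenotype at p < 10⁻³) would require
a half-million-SNP panel, which the generator supports in principle but
the default study does not use.

Null p-values are uniform with no inflation modelling — the pipeline
consumes association statistics, it does not produce them — so passing
tests demonstrate correct *post-processing* under clean nulls, not
robustness to confounded GWAS input. Similarly, the planted-recovery
tests show the mapping machinery is correct, not that real eQTL catalogs
have the assumed error structure.

## Numerical and design notes

- Internal coordinates are 0-based half-open everywhere; VCF positions
  convert on read/write, SNP records keep their 1-based `pos` field with
  a `pos0` accessor. Unnamed BED intervals get canonical
  `chrom:start-end` names so joins have stable keys.
- Multi-allelic panel records are skipped with a counted warning
  (biallelic-only contract); unphased or missing genotypes are fatal and
  name the record.
- r² values are clipped to [0, 1] against floating error; the exhaustive
  n = 8 configuration test agrees with exact rational arithmetic to
  1e-12.
- Empirical-p and overlap distributions are exactly reproducible for a
  fixed seed; sub-generators of the study derive independent seeds via
  numpy `SeedSequence.spawn`.
- Degenerate inputs: empty tag lists, empty pools, oversized draws, empty
  GMT gene lists, inverted BED intervals and out-of-range thresholds all
  raise before any computation; the pipeline wraps stage failures with
  the stage name.
- Test problem sizes (480-SNP panels, 100 × 200-SNP pruning scans,
  50,000-trial nulls, N ≤ 25 enumeration sweeps) were chosen so the
  whole suite exercises every oracle in well under a minute of compute
  per file while keeping Monte-Carlo checks at 3σ discrimination.

## Known limitations

- No liftover computation, no eQTL discovery, no enhancer calling, no
  phasing: those live upstream and enter as tables.
- The pruning survivor set depends on the declared removal rule; other
  tools' survivor sets will differ even at the same r² threshold (the
  no-linked-pair-within-window property is the stable contract).
- Locus overlap treats any shared gene membership as locus sharing;
  partial physical overlap of loci without a shared gene is not counted.
- Published headline counts from the motivating study (thousands of
  expanded SNPs per subtype, hundreds of genes) depend on proprietary or
  large external datasets and are not reproduced at fixture scale; the
  acceptance script reports the quantities the synthetic study computes.
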