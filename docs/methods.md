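# Methods

This note records the models, estimators, numerical choices and known
limitations behind `minorlens`, in the order of the pipeline.

## Intron catalog

Coordinates are 0-based half-open internally; GTF input is 1-based
inclusive, BED output 0-based half-open. One intron is emitted per gap
between consecutive exons of a transcript; introns identical in
(contig, start, end, strand) across transcripts are deduplicated, with
the host gene taken from the first contributing transcript (cross-gene
sharing is logged). The 1-based `intron_index` counts introns of a
gene in transcription order, so minus-strand genes are indexed from
the genomic right. Introns shorter than 30 nt are skipped with a
warning: the branch-point search needs the −40..−3 window upstream of
the 3' splice site, and 30 nt leaves room for at least one 9-nt motif
window after truncation. Each intron carries two strand-aware sequence
windows: the first 9 transcribed nucleotides (the extended U12 5'
splice-site region) and the last 40 (covering the branch-point search
window). Intervals containing `N` are retained; scoring treats `N` as
the 0.25 background.

## Splice-site scoring and classification

Position weight matrices are built from equal-length training k-mers
with pseudocount smoothing, `p[i][b] = (count + c) / (n + 4c)`,
default `c = 0.25` per base; `N` in training data contributes 0.25 of
a count to each base. A k-mer is scored as the normalized likelihood

    score(s) = Π_i p_i(s_i) / Π_i max_b p_i(b) ∈ (0, 1],

which equals 1 exactly on per-position-argmax (consensus) sequences
and is invariant to a common rescaling of the probabilities. This
bounded scale is what makes fixed thresholds meaningful: an intron is
called minor (U12-type) when its 5'ss score is ≥ 0.07 **and** its best
branch-point score is ≥ 0.14, the thresholds used in the original
human minor-intron annotation. Both thresholds, the motif lengths and
the matrices themselves are configurable, because the exact matrix
construction of the original annotation tool is not published; the
bundled training sets in `motifs.py` are synthetic curated variant
alignments of the canonical U12 5'ss ([AG]TATCCTTT) and branch point
(TTCCTTAAC), constructed so that every training member itself scores
above the thresholds (asserted in the test suite). They are **not**
the original tool's matrices, and the package accordingly makes no
claim to reproduce the published human catalog (179 A-type / 441
G-type introns), which depends on hg38 RefSeq and those matrices.

The branch point is located by scoring every 9-nt window fully
contained in transcribed positions −40..−3 (position −1 = last
intronic base) and keeping the maximum; ties are broken toward the 3'
splice site, since the published procedure specifies only "highest
scoring". Introns too short for any admissible window score 0 and can
only be called minor via the allowlist, which mirrors the manually
appended introns of the original catalog (typically poor branch
points) and is supplied as a TSV of intron keys.

Subtype follows the donor dinucleotide alone: AT → A-type, GT or GC →
G-type. This matches the published grouping of AT-AN introns versus
GT-AN/GC-AG introns and deliberately ignores the acceptor, so e.g.
AT-AA and AT-AG introns are A-type.

## Retention counting and Ψ

Alignment records are reduced to reference-aligned blocks: match/
mismatch and deletion operations extend a block, skipped regions (`N`)
split blocks, insertions and clips are ignored. Unmapped, secondary
and supplementary records are skipped. Three counts are collected per
intron and sample with a common anchor `k = 8` nt (guards against
spurious 1-nt overlaps):

* `J` — a consecutive block pair whose gap equals the intron exactly,
  with ≥ k aligned nt on each side (at most once per read per intron);
* `B` — a block crossing an exon–intron boundary with ≥ k nt on both
  sides, counted per boundary (at most twice per read per intron);
* `R` — ≥ k aligned nt strictly inside the intron, for reads not
  already counted in `J` for that intron (boundary reads therefore
  also contribute body evidence).

Mates of a pair are counted independently; multi-intron-spanning
records may increment `J` for several introns.

Boundary-mode Ψ pools counts across a condition's replicates and uses
`Ψ = (B/2) / (B/2 + J)`: a retained molecule presents two boundaries
where a spliced molecule presents one junction, hence the B/2
correction. Body mode (`R` scaled by the number of read placements
fully inside the intron) is provided for comparison only. A zero
denominator yields an undefined Ψ which propagates as missing. The
published analyses used two external tools whose internal estimators
are not restated; this estimator is the package's own declared choice,
validated by parameter recovery on simulation (≥ 95% of introns within
±0.05 of truth at pooled coverage 200). That recovery check is run
without replicate overdispersion (ρ = 0), because with ρ > 0 each
replicate's true retention itself varies around the class value and
the comparison would measure planted biology rather than estimator
error.

Two read-count filters mirror the published analyses and are selected
per analysis by the caller: total junction reads ≥ 5 across the
comparison's samples, or mean intron-body reads ≥ 5 across samples
(equality survives).

## Differential test

Per intron, replicate j provides retained `r_j` and total `n_j`
informative units (from boundary evidence: `r = B/2`, `n = B/2 + J`).
The model is beta-binomial with condition mean μ and intra-replicate
correlation ρ (`a = μ(1−ρ)/ρ`, `b = (1−μ)(1−ρ)/ρ`), ρ shared between
conditions; the null fits one μ, the alternative one μ per condition;
`2(ℓ_alt − ℓ_null)` is referred to χ²(1). Means are optimized on the
logit scale in [−10, 10], ρ in [10⁻⁶, 0.5]; binomial-coefficient terms
cancel between hypotheses and are dropped, and the kernel reduces
continuously to the binomial log-likelihood as ρ → 0. ΔΨ is the
pooled-count difference (treatment − control), chosen over the mean of
per-replicate Ψ for stability at low counts.

With 3 vs 3 replicates a per-intron ρ estimate is too noisy for the
χ² reference: simulations showed type-I error near 0.12 when ρ is
freely refit per intron, and over-conservative behaviour when ρ is
instead pinned to each intron's null fit. `differential_table`
therefore moderates the nuisance the way genome-scale count tools
share dispersion across genes: ρ is estimated once across all introns
of the table — the mean of per-intron moment estimates from the
Pearson statistic around the condition means, left unclipped per
intron so the average stays unbiased, then clipped to [0, 0.5] — and
held fixed in every per-intron likelihood-ratio test. Under null
simulations (2,000 introns, 3 vs 3, coverage ≈ 67 per replicate) this
yields empirical type-I error of about 0.033 (ρ = 0), 0.063
(ρ = 0.02) and 0.060 (ρ = 0.05) at α = 0.05. `betabin_test` remains
available standalone with a free per-intron ρ, or with ρ fixed;
`fix_rho=0` is exactly the closed-form binomial LRT. If the free-ρ
optimizer fails to converge the test falls back to the binomial LRT
with a warning.

P-values are Benjamini–Hochberg adjusted (the published analysis named
BH explicitly; for the co-evolution stage only "FDR correction" is
stated and BH is used there as well, recorded as a choice). An intron
is `affected_ir` at `P_adj < 0.05` and `affected_strict` when
additionally `ΔΨ > 0.1` (one-sided: increased retention). The BH
step-up is not idempotent; the suite asserts its true guarantees
(never decreases a p-value, monotone in p-rank).

The subtype summary reports, per A/G subtype, the number analyzed, the
fraction affected (optionally unioned per intron with cryptic-site
activation, matching the published combined statistic), mean and
median ΔΨ, and an A-vs-G two-sided Mann–Whitney comparison of ΔΨ. The
Mann–Whitney test uses the exact null distribution when the combined
sample size is ≤ 20 without ties, otherwise the normal approximation
with tie and continuity corrections; a degenerate tie-corrected
variance yields p = 1.

Hierarchical clustering of the intron × sample Ψ matrix is
average-linkage on Euclidean distances via scipy; rows with missing Ψ
are dropped with a warning. Exact-tie merge order follows scipy's
deterministic internal convention rather than a lowest-row-index rule;
ties have measure zero on real-valued Ψ and the brute-force oracle
tests use tie-free fixtures.

## Cryptic splice sites

For each minor intron, observed junctions sharing one boundary (within
a 50-nt flank window) with the canonical intron while the other
boundary differs are candidate alternatives. Usage
`ψ_alt = J_alt / (J_alt + J_canonical)` is compared between conditions
with the same beta-binomial test; activation requires `P_adj < 0.05`
and `|Δψ_alt| > 0.1`. The original analysis used a posterior
probability cutoff (Pr > 0.9) from a different tool; substituting the
adjusted-p criterion on the junction-ratio test is a recorded
simplification: this stage re-bases the decision rule on the
package's own test rather than porting the original
alternative-splicing caller.

## Co-evolution screen

Profiles are binary presence/absence vectors over species. Similarity
to the query is the Pearson correlation of the two 0/1 vectors, which
equals the 2×2 phi coefficient; constant profiles have undefined
correlation and rank last. Co-occurring genes are those with r
strictly greater than 0.5 (query excluded). Term enrichment uses the
upper-tail hypergeometric probability per term with BH adjustment and
reports fold enrichment `(k/n)/(K/N)`. Ortholog assignment itself
(building the matrix) is an upstream input, not computed; no
correction for phylogenetic non-independence of species is applied.

## Synthetic data

`simulate_genome` places one single-intron gene per contig
(exon–intron–exon, 100/150/100 nt, alternating strands). Minor introns
receive a 5'ss motif sampled from the bundled training variants and a
branch-point variant planted at a uniform offset in [−40, −11]; major
introns receive the major-spliceosome consensus (GTAAGTAAG, or
ATAAGTAAG with AT-AC termini for the major AT-AC decoy class) and an
unconstrained 3' region. Because every planted motif scores above the
thresholds and the major 5'ss scores orders of magnitude below 0.07,
planted classes are recoverable by construction — which is the point:
the generator tests the machinery, not the biology.

`simulate_counts` draws per replicate a negative-binomial number of
informative units (default mean 67 per replicate, dispersion 0.1,
i.e. ≈ 200 pooled per 3-replicate condition) and a beta-binomial
retained count around the condition's true Ψ with ρ = 0.02. Default
truth values are anchored to the published study: baseline Ψ 0.115
(A-type), 0.130 (G-type), 0.05 (major); treatment shifts ΔΨ 0.36
(A-type), 0.07 (G-type), 0 (major); 3 vs 3 replicates. Counts can be
realized as SAM records (one junction read per spliced unit, two
boundary reads per retained unit, sequences omitted), which re-count
exactly to the emitted J and B. The generator does not model sequencing
error, GC or positional bias, paired-end inserts, multi-mapping, or
expression-level changes — so passing tests demonstrate correctness of
the counting and inference machinery under the declared noise model,
not robustness to real-library artifacts.

`simulate_profiles` plants one shared loss pattern across a module of
genes (query included), independent random profiles elsewhere, and
per-entry flip noise (default 0.05 over 60 species).

All generators are pure functions of (config, seed).

## Problem sizes

The default study design (250 introns, 3 vs 3 replicates, coverage
≈ 200 pooled) and the benchmark sizes (2,000 introns for null
calibration, 1,000 random regions for the branch-point oracle, 100
seeded co-occurrence runs) were chosen as desk-scale stand-ins for the
genome-scale originals: large enough for stable fractions, small
enough to regenerate from scratch on every run.

## Known limitations

* The classifier does not reproduce the published human minor-intron
  catalog; matrices and thresholds are configurable stand-ins.
* Mates are counted independently; no duplicate marking or multimapper
  handling; SAM text only (no BAM/CRAM requirement at desk scale).
* The differential test's ρ moderation assumes a common overdispersion
  scale across introns; introns with genuinely extreme replicate
  variability will be anticonservative relative to a per-intron model.
* The cryptic-site decision rule is a declared substitute for the
  original posterior-probability cutoff.
* The phi-coefficient screen treats species as independent samples.
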