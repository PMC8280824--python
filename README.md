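# minorlens

Minor (U12-type) intron annotation, intron-retention quantification,
differential testing and phylogenetic co-occurrence screening — a
desk-scale, fully testable re-implementation of the computational
analyses used to show that loss of a minor-spliceosome factor
selectively increases retention of AT-AN ("A-type") minor introns.

## The problem

About 700 human introns are excised not by the major (U2-dependent)
spliceosome but by the low-abundance minor (U12-dependent)
spliceosome. Minor introns are recognized by long, highly conserved 5'
splice-site and branch-point sequences, not by their terminal
dinucleotides alone: most carry AT-AC or GT-AG termini, and AT-AC
termini also occur on ordinary major introns. When a minor-spliceosome
factor is depleted or mutated, minor introns are retained in mature
transcripts, and the two minor subtypes — A-type (AT-AC, AT-AA, AT-AG,
AT-AT termini) and G-type (GT-AG, GT-AT, GT-TG, GC-AG) — can respond
very differently. Measuring that response requires a chain of steps
that this package implements end to end:

1. **Intron catalog** (`annotation_io`) — extract deduplicated introns
   with strand-aware donor and 3'-terminal sequence windows from a
   genome FASTA + transcript GTF.
2. **U12 classification** (`u12_classifier`) — score each intron's 5'
   splice site and branch point against position weight matrices. The
   score of a k-mer *s* is the normalized likelihood
   `score(s) = Π_i p_i(s_i) / Π_i max_b p_i(b)` in (0, 1]; the branch
   point is the best-scoring window inside transcribed positions
   −40..−3 upstream of the 3' splice site. An intron is minor when
   `s5 ≥ 0.07` and `s_BPS ≥ 0.14` (or is allowlisted), A-type when its
   donor dinucleotide is AT, G-type when GT or GC.
3. **Retention quantification** (`retention_quant`) — count, per intron
   and sample, spliced junction reads *J*, exon–intron boundary reads
   *B* and intron-body reads *R* from SAM alignments (anchor ≥ 8 nt),
   and estimate retention as `Ψ = (B/2) / (B/2 + J)`.
4. **Differential retention** (`differential_ir`) — a replicate-aware
   beta-binomial likelihood-ratio test on (retained, total) counts
   with overdispersion ρ shared across introns, Benjamini–Hochberg
   correction, affected flags at `P_adj < 0.05` (strict flag adds
   `ΔΨ > 0.1`), subtype summaries with Mann–Whitney comparisons,
   hierarchical clustering of Ψ profiles, and cryptic (alternative)
   splice-junction activation testing.
5. **Co-evolution screen** (`coevolution`) — rank genes by the phi
   coefficient (Pearson correlation of binary presence/absence
   profiles across species) against a query gene, select co-occurring
   genes at `r > 0.5`, and test annotation-term enrichment with the
   hypergeometric tail and FDR correction.
6. **Synthetic data** (`synthetic_data`) — generators for a toy genome
   with planted U12 motifs, two-condition overdispersed read counts
   with known retention shifts (A-type ΔΨ = 0.36, G-type ΔΨ = 0.07 by
   default), and phylogenetic matrices with a planted co-occurring
   module, so every stage is testable without downloads.
7. **Pipeline** (`pipeline` / `minorlens` CLI) — deterministic
   orchestration with a run manifest.

## Worked example

Simulate the default study design (25 minor-A, 25 minor-G, 180 major
and 20 major AT-AC introns; 3 control vs 3 treatment replicates at
about 200 pooled informative reads per intron), then classify and test:

```python
import json
import minorlens as ml
from minorlens.differential_ir import differential_table

cfg = ml.SimulationConfig(seed=7)
genome, transcripts, truth = ml.simulate_genome(cfg)
introns = ml.extract_introns(transcripts, genome)
classes = ml.classify_catalog(introns)
print("catalog:", len(introns), "introns;",
      (classes.spliceosome_type == "minor").sum(), "minor")

counts, design = ml.simulate_counts(truth, cfg)
filtered = ml.filter_introns(counts, min_junction=5)
result = differential_table(filtered, design, "control", "treatment")
summary = ml.summarize_by_subtype(result, classes, flag="affected_strict")
print(json.dumps(summary, indent=2))
```

Output:

```
catalog: 250 introns; 50 minor
{
  "subtypes": {
    "A": {
      "n": 25,
      "fraction_affected": 1.0,
      "mean_delta_psi": 0.37603664312157925,
      "median_delta_psi": 0.3778846153846154
    },
    "G": {
      "n": 25,
      "fraction_affected": 0.12,
      "mean_delta_psi": 0.09260916246059883,
      "median_delta_psi": 0.081869918699187
    }
  },
  "a_vs_g_mannwhitney": {
    "U": 625.0,
    "p": 1.4156562248495537e-09
  }
}
```

All 50 planted minor introns are recovered (none of the 20 major AT-AC
decoys is called minor); the differential stage recovers the planted
subtype asymmetry: essentially all A-type introns are significantly
more retained (mean ΔΨ ≈ 0.38 against a planted 0.36) while G-type
introns (planted ΔΨ = 0.07) mostly fall below the `ΔΨ > 0.1` cutoff,
and the A-vs-G retention difference is highly significant.

The same analysis is available from the shell:

```sh
minorlens simulate --outdir sim/ --seed 7 --with-sam
minorlens run --genome sim/genome.fa --gtf sim/annotation.gtf \
    --counts sim/counts.tsv --design sim/design.tsv --outdir out/
minorlens coevolve --matrix sim/profiles.tsv --query QUERY --out ranked.tsv
```

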