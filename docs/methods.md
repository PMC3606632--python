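# Methods

## The measurement model

5′-SAGE tags are short (15–20 bp) sequences read from the 5′ end of mRNAs,
ligated tail-to-tail in pairs ("ditags", ~100 bp with adapters) and
sequenced. Each tag carries two signals: its count measures transcript
abundance, and its genome-mapped 5′ position marks a candidate transcription
start site. The pipeline treats a two-library experiment (two developmental
stages, unequal depths) as two independent multinomial samples over tag
species; all inference downstream is on counts.

### Tag extraction

Reads are filtered on Phred qualities (defaults: mean ≥ 20, every base
≥ 10 — the chemistry defines no canonical cutoff, so both are parameters),
then parsed by exact match of the 5′ adapter, linker and 3′ adapter. The
second tag is stored reverse-complemented in the read (blunt tail-to-tail
ligation geometry) and is flipped back to transcript orientation on
extraction. Failures return a reason code (`no_adapter`, `no_linker`,
`bad_tag_length`) rather than raising; a tag containing `N` is invalid
because exact-match mapping cannot place it. Identical tags are summed and
singletons (count 1) dropped by default — applied per library after
collapsing and **before** mapping; the ordering relative to mapping is a
package choice, documented here because nothing downstream constrains it.

### Mapping

Exact matching on both strands via a per-length hash index of genomic
k-mers — at the few-hundred-kilobase scales this package targets, hashing
is simpler than suffix structures and the contract (complete exact-match
lookup) is easy to verify against a naive full scan. Hit positions use the
5′-end-in-transcript-orientation convention: minus-strand hits report the
higher genomic coordinate, so a hit position is directly the candidate TSS.
Tags are binned as unique / 2–4 / 5–10 / ≥11 matches / unmapped; the
occurrence-weighted bin counts partition the library total exactly.
Multi-mapped tags cannot be confidently assigned and are excluded from
annotation and expression. Class percentages are occurrence-weighted
(per tag occurrence, not per distinct tag).

### Annotation

Gene models are flat (single-CDS) records; the putative 5′-UTR window is
the 500 bp immediately upstream of the start codon and the 3′-UTR window
the 500 bp downstream of the stop, derived on demand and clipped at
chromosome ends (a clipped window keeps its category). Offsets are computed
in transcript orientation, so minus-strand genes use mirrored arithmetic.
Each uniquely mapped position gets exactly one of seven categories. Where
windows of several genes overlap, priority is
`utr5_sense > cds_sense > utr3_sense > utr5_antisense > cds_antisense >
utr3_antisense > unclassified`, with smallest distance to a start codon as
the final tie-break — overlap handling is a package choice; a tag is never
assigned to two genes. "Preferred TSS" is operationalised as the
top-occupancy site, plus the runner-up when it holds at least half the top
site's tags (matching the qualitative "one or two preferred sites"
observation in tag data).

### Expression and differential calls

Expression is tags per hundred thousand:
`tphk = (sense 5′-UTR tag count) / (library's genome-mapped tag total) × 10⁵`.
The library denominator is the **uniquely** mapped total by default; the
alternative (all valid tags) is configurable because either reading of
"genome-mapped" is defensible. Genes with zero counts in both stages are
not assessed.

Differential expression per gene uses the two-sided Fisher exact test on
`(c₁, N₁−c₁; c₂, N₂−c₂)` at unadjusted α = 0.05 (Benjamini–Hochberg is
available but off by default, matching the unadjusted-p convention of
classic SAGE comparisons). The two-sided p-value follows the
minimum-likelihood rule — sum all tables with the observed margins whose
point probability is at most the observed one, with a 1 + 10⁻⁷ relative
tolerance for floating-point ties. For supports up to 512 the sum is
evaluated in exact big-integer arithmetic (weights
`C(r₁,a)·C(r₂,c₁−a)`), making tie decisions exact; larger supports fall
back to scipy's implementation of the same rule. Degenerate margins give
p = 1.

Log₂ ratios are computed from tphk values after replacing zeros with a
pseudo value of 1.0 tphk. This choice reproduces the published two-decimal
ratios of one-sided genes exactly (log₂ 879.2 = 9.78, log₂ 620.5 = 9.28)
and is configurable. Ratios for genes with small nonzero minority counts
are computed from unrounded tphk, so they may differ in the second decimal
from tables that were typeset from rounded values.

### Enrichment and lineage

Domain enrichment is a one-sided hypergeometric tail (over-representation)
per domain, DEG set vs the ORF universe, at p < 0.05 with no multiple-
testing correction. Presence is counted at the ORF level: an ORF carrying
a domain twice counts once (occurrence-level counting is the other
defensible reading; ORF-level was chosen because the 2×2 margins are then
whole ORFs). Assignments are pre-filtered at e < 10⁻²⁰.

Lineage calls consume per-species best-hit e-values from 12-column tabular
homology reports. A gene is *basidiomycete-unique* when ≥ 2
fruiting-body-forming species (the gene's own genome excluded) have hits at
e < 10⁻¹⁰ and no outgroup species has a hit at e ≤ 10⁻²; it is
*species-unique* when no species at all reaches e < 10⁻¹⁰. A weak outgroup
hit (between the two thresholds) blocks basidiomycete-uniqueness but not
species-uniqueness, since it does not constitute homology.

### Validation

Cross-platform agreement is complete-case Pearson correlation of log₂
ratios (≥ 3 complete pairs and nonzero variance required). The 18-gene
reference panel is packaged so the stage runs offline. Pearson (not rank)
correlation is used because the panel's published microarray correlation is
reproduced exactly by Pearson on its printed columns; its published qPCR
correlation is not reproducible from the printed values under any standard
correlation we tried, and presumably was computed from unrounded qPCR
measurements not present in the table.

## The synthetic study generator

The generator emulates the study conditions a two-stage 5′-SAGE comparison
presents to the pipeline, at roughly 1/20 scale:

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 70 kb | smallest scale at which multi-chromosome and strand logic is exercised |
| genes | 60, 0.6–1.4 kb, ≥ 1.1 kb apart | every gene's ±500 bp windows fit its chromosome without overlaps |
| library depths | 3,000 / 4,000 reads (6,000/8,000 tags) | preserves the ~0.73 depth ratio of real paired libraries |
| tag length | uniform 15–20 bp | conceptual 15–17 bp extraction, ~20 bp enzymatic tags |
| DEG fraction | 1/3, folds 3–8 | roughly one-third of assessed genes differential, all above the 3-fold reporting threshold |
| antisense fraction | 0.15 per gene | observed antisense proportions of 14–17% |
| TSS profile | 1–3 sites within 500 bp, ~exp(60 bp) upstream | TSS arrays concentrated within 200 bp with one or two preferred sites |
| qualities | constant Q40; optional degraded-read fraction at Q8 | exercises the mean/min quality filter deterministically |

Expected DEG shares are constructed so each DEG's between-stage share ratio
equals its drawn fold *exactly* and both stages' shares sum to one: each
gene's per-stage masses are split as `2f/(1+f)` vs `2/(1+f)` around its
baseline, and the up-in-stage-2 group's baselines are rescaled by one
common factor to balance total mass between stages (a scalar on both stages
of a gene leaves its fold untouched). Non-DEG genes keep identical shares
in both stages. In the degenerate case of a single DEG direction the
stages are normalised separately and the realised fold recorded.

Antisense tags are drawn uniformly from within the gene body on the
opposite strand; sense tags start exactly at a profile TSS. Substitution
errors are applied per base. Every emitted tag is recorded with its read,
gene, TSS coordinate and strand, giving an exact truth multiset.

**What the generator does not emulate** — introns and splice-junction tags
(a real minor unmapped class), PCR/ligation bias, quality-dependent error
profiles, strain polymorphism (a real source of unmapped tags), and real
promoter sequence composition. Passing round-trip tests therefore
demonstrates correctness of the bookkeeping (extraction, mapping,
windowing, counting, testing) under the stated model, not robustness to
every artefact of real pyrosequencing data.

## Numerical and design notes

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; a pipeline run is byte-reproducible given
  (config, seed), and the global seed is fanned out to stages by fixed
  offsets.
- TSS-catalogue and preferred-site ties break on (count desc, coordinate
  asc); multiplicity classes depend only on hit counts.
- The calibration checks in the test suite use count-level multinomial
  simulation (2,500 genes at 50k/75k tags for the null; 600 genes with
  8-fold DEGs for power) rather than sequence-level reads: DEG calling
  consumes only counts, and this keeps the suite fast while testing the
  inferential path at realistic depths.
- The one-sided-gene log₂ ratios (±9.78/9.55/9.28/6.63 style values)
  depend only on the zero-replacement rule, not on simulation scale, and
  are verified as exact arithmetic.
- Known limitations: no mismatch-tolerant or splice-aware mapping, no
  fuzzy adapter matching, no dispersion-based DE model (the Fisher test
  assumes pure sampling noise between libraries), and enrichment without
  multiple-testing correction reports many weak candidates by design.
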