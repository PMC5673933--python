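# Methods

## Study design emulated

The synthetic study mirrors a three-group gastric-tissue design: patients
without cancer, tumor-adjacent tissue and tumor, default 8 samples per
group. Under the `field_effect` preset, each planted circRNA draws a base
mean junction-read count log-uniform over 10^−1.5 … 10^1.5 (mostly below
10 reads with a high tail, the regime reported for tissue circRNAs), and
per-group means scale it by 1.0 (adjacent), 0.3 (tumor) and 0.08
(no-cancer). These multipliers were chosen once so that presence-detection
of the abundance spectrum reproduces the qualitative field-effect ordering
adjacent > tumor > no-cancer seen in gastric data; the `null` preset gives
all groups equal means. Per-sample counts are negative binomial with
dispersion φ = 0.2 under the field preset and Poisson under the null. The
NB(0.2) choice is a modeling decision, made to match the differential-
expression model so parameter recovery is well-posed; no distributional
form is available from tissue data at this scale.

Reads are single-end 150 nt, error-free by default (substitution-only
noise up to 5% is supported; no indels). Each junction read crosses the
back-splice point with the breakpoint uniformly at least one anchor length
(20 nt) from both ends; spliced linear mRNA reads are added as decoys.
Genomes are uniform-random A/C/G/T; gene models are non-overlapping
single-isoform transcripts (3–6 exons of 150–350 nt, introns 100–400 nt)
with a CDS covering the interior exons so UTR classification is
exercisable. What this generator does *not* emulate: splice-site motifs,
repeat and low-complexity sequence, GC bias, rRNA/RNase-R enrichment
chemistry, adapter contamination, paired-end protocols, and isoform
mixtures within a gene's linear transcripts. Detector recall/precision of
1.0 on this material therefore bounds only algorithmic correctness, not
performance on real libraries, where anchor multi-mapping and sequencing
error dominate.

## Back-splice detection and junction identity

The caller takes the two terminal k-mers (k = 20 by default, minimum 12)
of each read that cannot be explained by a contiguous genome match on
either strand, requires both to map uniquely (multi-mapping anchors
discard the read), and emits a call when the 5′ anchor maps downstream of
the 3′ anchor on the same chromosome and strand within a configurable
maximum span (default 2 Mb) — the head-to-tail signature. Anchors are
extended inward; any breakpoint consistent with both extensions yields the
same circle, and the leftmost genomic representation is chosen, analogous
to indel left-alignment.

Because the flanking bases of a junction may repeat, one circle admits
several equivalent coordinate pairs. Three consequences are handled
explicitly: (1) evaluation against simulation truth compares junctions in
canonical (leftmost) form (`bsj.canonical`); (2) before annotation the
pipeline snaps each junction to the representation coinciding with exon
boundaries of an overlapping transcript when one exists within the
homology window (`annot.realign_to_models`), which is the convention
annotation databases use; (3) consensus between two call sets is exact by
default (slack 0), with a ± slack option because real callers disagree on
breakpoints. Consensus read counts take the minimum of the two callers —
a conservative choice; the reconciliation rule used by published
dual-caller studies is not stated. CIRI2 tables (1-based inclusive) and
CIRCexplorer2/BED tables (0-based half-open) are normalized to the
internal 0-based half-open convention on ingestion.

## Annotation

Host assignment prefers, among same-strand overlapping transcripts, one
whose exon boundaries coincide with both junction endpoints; ties go to
most contained exons, then longest contained spliced length, then
transcript id. Origin classification is total with precedence intergenic
< intronic < exon_intron < exonic: no host → intergenic; both endpoints
inside the same intron → intronic (the ciRNA case); one endpoint exonic,
one intronic (or endpoints in different introns) → exon_intron (the
EIciRNA case); otherwise exonic, sub-typed CDS > 5′UTR > 3′UTR by the
genomic overlap of the contained exons with the host CDS. These category
definitions and the precedence order are this package's choices — origin
taxonomies in the literature are rarely formalized. Hosts without an
annotated CDS fall through to the 3′UTR branch of the sub-typing rule.

Transcript features for boundary-matched circles are computed from exons
fully contained in the junction interval: exon count, spliced length
(sum of contained exon lengths) and spliced sequence (concatenation in
transcription order, reverse-complemented on the − strand). Because some
public circRNA length annotations appear to report genomic span rather
than spliced length, output tables carry both columns and a
`--length-mode` switch selects which one populates `length`.

## Differential expression

Library sizes default to per-sample total junction reads, and
normalization is library-size equalization only: counts are mapped through
the mid-probability of their NB distribution at the sample's library size
onto the NB quantile at the geometric-mean library size. TMM-style
composition normalization is deliberately not applied — its assumptions
are questionable on sparse circRNA counts — and is noted as a flag point
for future work.

Dispersion: per-feature method-of-moments φ̂_g = max(0, (s²−m̄)/m̄²) on
the equalized counts within each group, pooled across groups by residual
degrees of freedom; the common dispersion is the count-weighted mean of
the φ̂_g; tagwise values shrink φ̂_g toward the common value with weight
n₀/(n₀+d), prior df n₀ = 10 (chosen, not data-derived), d = total
residual df.

The test conditions on each feature's grand total t: with side sizes n_A,
n_B and dispersion φ_g, the side-A total is beta-binomial(t, n_A/φ_g,
n_B/φ_g) under equal means (exactly the conditional law of a sum of NB
variables given the total; binomial when φ ≤ 10⁻⁶). Two-sided p-values
sum the probabilities of all splits with probability ≤ that of the
observed split; totals above 5000 use a normal approximation with
continuity correction and tail doubling. Features with zero total get
p = 1 by convention. FDR control is Benjamini–Hochberg (via statsmodels).
The default contrast pools adjacent and tumor samples against no-cancer;
log2 fold changes are reported pooled-over-no-cancer with a 0.5-count
offset. This is a qCML-flavoured simplification with the same contract as
common NB count-model packages, not a re-implementation of any of them;
its calibration (type-I error, p-value uniformity, dispersion recovery,
power against planted 4-fold changes) is measured by
`scripts/acceptance.py` rather than asserted here.

## Sponge candidates

The seed is mature miRNA positions 2–8 (a 7-mer, configurable); a target
site is an exact Watson–Crick reverse complement of the seed in the
circle's spliced sequence — no wobble pairing and no 8mer/7mer-A1 site
grading, since the procedure being modeled specifies only seed
complementarity. Scanning is wrap-aware by default: the sequence is
extended by its own first seed_len−1 bases so sites spanning the
back-splice point count once; distinct start positions count as distinct
sites, including overlaps (the counting rule for published "number of
seed matches" columns is unstated; this one is explicit and matches a
doubled-sequence oracle). Candidates must pass all three filters —
validated interaction with the host gene, ≥1 site, presence on the DE
miRNA list. The DE miRNA list is an input, not a computed product: the
matched small-RNA experiment it would come from is outside this package's
scope. Scope restriction to the top-expressed circles per group (default
7 per group) is applied by the pipeline driver via `diffexp.top_expressed`.

## Enrichment

Plain upper-tail hypergeometric per pathway with Bonferroni correction
over tested terms; the background defaults to all genes in the supplied
annotation, not the genome. This deliberately diverges from web-service
enrichment scores (e.g. the EASE-modified Fisher statistic), which are
out of scope. Enrichment bar plots use −log10 p and label the axis as
such.

## Pipeline orchestration

`run-all` executes simulate → detect → consensus → annotate → quantify →
de → sponge → enrich, writing plain files per stage plus a manifest with
all parameters and a SHA-256 checksum per artifact; identical configs
give identical manifests. With only the internal caller available the
dual-algorithm consensus degenerates to self-consensus; external CIRI2 or
CIRCexplorer2 tables can be intersected through the `consensus`
subcommand. When no pathway table is supplied, a synthetic GMT over the
simulated gene universe is generated so the stage remains exercisable.

## Numerical and degenerate-input choices

- Every generator and stage is deterministic under a fixed seed; RNG
  streams are keyed per stage and per sample.
- Equal-count ties in top-expressed ranking break lexicographically by
  circ id; breakpoint ties break leftmost; host-assignment ties as above.
- All-zero count matrices are rejected ("no expressed features");
  zero-total features get p = 1; variance-below-mean features floor
  φ̂ at 0.
- Planted seed sites are placed only in exon interiors at least a seed
  length from the breakpoint (wrap sites are constructed explicitly in
  evaluation), never overlapping a circle whose site count was already
  verified; miRNAs are re-drawn when a spurious match would break the
  planted count.

## Evaluation problem sizes

Evaluation runs use 50-circle studies (3×8 samples) for detector and
annotation fidelity, 1000 features for null calibration, 200 for
dispersion recovery, 160 (40 with planted 4-fold changes) for power, and
20 simulation seeds for the field-effect ordering — sizes at which the
measured quantities are stable while the whole evaluation completes in
seconds.

## Known limitations

- The caller has no paired-end or chimeric multi-segment logic, no
  quantification of linear/circular ratios, and discards multi-mapping
  anchors rather than resolving them; sensitivity on repetitive genomes
  will suffer accordingly.
- GT–AG splice-motif filtering exists but is off by default because the
  synthetic genomes carry no splice motifs.
- The matched (paired) structure of the tumor/adjacent design is not
  exploited by the test, which treats samples as independent — matching
  the analysis being emulated, but leaving power on the table.
- Hypergeometric enrichment on circRNA-derived genes inherits gene-length
  and expression biases that dedicated methods correct for.
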