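# Methods

This note documents the models, conventions and numerical choices behind
`hgtscan`, and what the synthetic-data generator does and does not
emulate.

## Placement-based HGT classification

The unit of inference is one focal transcript in one gene tree. Trees are
consumed with bootstrap supports stored as integer internal-node labels
(the RAxML rapid-bootstrap convention) and are rooted on the outgroup:
the root is placed on the edge subtending the smallest clade containing
every outgroup tip. Rerooting operates on an undirected edge graph in
which supports are edge attributes, so each support value stays attached
to the bipartition it measures regardless of root position. If the
outgroup tips are not monophyletic in the unrooted topology, the root
goes on the edge subtending the largest pure-outgroup clade and the tree
is flagged `outgroup-conflict` in the per-transcript report.

Classification ascends from the focal tip to the first ancestor that
contributes at least one non-focal tip; the genomes of those tips form
the sister set. Conventions:

* **Focal paralogs.** Additional tips of the focal taxon encountered
  while ascending are treated as part of the focal lineage and skipped —
  transcripts, not clusters, are classified, and each focal tip is
  classified independently.
* **Support attribution.** The support used is that of the edge
  subtending the (focal ∪ sister) clade, i.e. the edge above the
  ancestor. If that ancestor is the root (support undefined), the
  transcript is unassigned — the conservative reading of "placed with
  ≥ τ% support".
* **Polytomies.** A polytomous sister set is evaluated as a whole: every
  genome in it must fall within a single rule set.
* **Mixed or reference-taxon sister sets** (any genome outside both rule
  sets, e.g. *Oryza*, *Arabidopsis*) are unassigned regardless of
  support.
* **Cluster retention.** A cluster is analysed only if it contains the
  outgroup, the focal taxon, at least one close relative and at least one
  transfer-side taxon; this mirrors the study design and guarantees that
  both VGT and HGT are expressible outcomes for every analysed tree.
* **Threshold sweep.** The sister placement is computed once (it is
  threshold-free); only the support cut varies over τ ∈ {50, 55, 60, 65,
  70}. The sweep's HGT percentage uses resolved transcripts
  (#HGT / (#HGT + #VGT)) as denominator; a threshold with no resolved
  transcript reports an undefined percentage, never zero.
* **Controls.** Background discordance is measured by re-running the
  identical procedure with *Manihot* or *Ricinus* as the focal taxon
  (transfer side still {*Vitis*}); *Populus* remains accepted in
  relative sets but is not used as a control focal taxon.

## Substitution-rate comparison

No explicit rate measure is attached to the trees we consume, so the
package uses the focal tip's **terminal branch length**
(substitutions/site) as the rate proxy — the minimal tree-derived
quantity requiring no further inference. Root-to-tip distance is
available behind a flag, and the proxy used is recorded in the output
metadata. The partner rate for a transcript is the mean terminal branch
length of its sister-set tips. Group comparisons use Welch's
unequal-variance *t* test: t = (x̄₁−x̄₂)/√(s₁²/n₁+s₂²/n₂) with
Welch–Satterthwaite degrees of freedom and two-sided p-values (the
p-value from `scipy.stats.t`; the statistic and df are computed
directly). Groups with fewer than two members skip the test with a
logged reason. Both variances zero with equal means defines t = 0,
p = 1.

## Genomic verification and introns

Zero-mismatch alignment of k-mers is exactly substring search, so the
verification contract is specified as such: reads are divided into
consecutive non-overlapping k bp fragments (k = 25; a 150 bp read gives
6, a trailing remainder is discarded) and every exact occurrence of a
fragment or its reverse complement in the transcript set is a hit. A
transcript is verified when ≥ 1 genomic-read fragment hits it
(`min_hits` configurable; the most permissive reading of "positively
mapped"). Verification percentages are reported overall and stratified
by bootstrap-support decade bins from τ upward and by transcript-length
quartiles, per category — equal HGT/VGT verification is the
anti-contamination argument.

Intron detection is split-read logic on the same fragments: a genomic
read whose early fragments map at transcript offset c₁ and later
fragments at offset c₂ < c₁ spans an insertion of length c₁−c₂. The two
k-mer-anchored flanks are then extended base by base (still exact
matching) toward each other. Because chance matches can carry an
extension a few bases past the true junction, the junction is chosen
inside the resulting ambiguity window to satisfy the canonical GT donor
/ AG acceptor motifs where possible (falling back to the maximal
extension otherwise; for one-sided partial calls the backtrack window is
8 bp). Requiring instead that the flanking fragments be exactly adjacent
on the k-mer grid would miss any intron whose boundaries do not align
with a read's fragment grid, so anchored extension is the package's
design. A read anchored on one side only yields a partial call whose
unobserved motif flag is `None`; a read entirely inside one exon, or one
that merely runs off a transcript end, yields no call.

Parasite–host divergence uses Biopython global alignment with match +1,
mismatch −1, linear gap −2 (fixed defaults, recorded in metadata);
divergence = mismatched columns / aligned non-gap columns × 100, so gap
columns are not counted as differences.

## Expression

A cDNA read counts toward a transcript when ≥ 1 of its fragments matches
exactly; multi-mapped reads count once per matched transcript (the
simplest deterministic rule, recorded in metadata). Counts are
normalized by the window formula R = N/(L − k + 1 + l − k). The flat
formula is ambiguous as printed in its source; the denominator is
grouped as (L − k + 1 + l − k), the number of read placements with ≥ k
overlapping bases, which keeps R finite and positive. The stated read
length for this normalization is l = 25 (with k = 25 the denominator
reduces to L − k + 1); both k and l are configurable. RPKM is computed
from the raw counts N (RPKM = 10⁹·N/(L·ΣN)); both R and RPKM columns are
emitted so either convention is inspectable. The HGT-vs-VGT comparison
runs Welch's test on log₁₀ RPKM over expressed transcripts.

## Coding properties

A profile concatenates three independently normalized blocks: 4
nucleotide, 16 dinucleotide and 61 sense-codon frequencies (stop codons
TAA/TAG/TGA excluded from numerator and denominator; codons counted in
frame 0; a trailing partial codon dropped; N bases excluded from all
blocks). Per-block normalization makes the blocks contribute comparably
to the distance; joint normalization is a documented alternative. The
distance is the symmetric χ² histogram distance Σ(pᵢ−qᵢ)²/(pᵢ+qᵢ) with
jointly absent features skipped.

Affinity calls use the smallest distance to each side within the
cluster: Malpighiales side {*Manihot*, *Ricinus*} (not *Populus*, which
is excludable by default and includable by argument), host side
{*Vitis*}. The margin is (best Malpighiales distance − best Vitis
distance); margin > 0 is Vitis-like and an exact tie goes
Malpighiales-like — the direction conservative against the convergence
claim. A transcript lacking a homologue on either side is excluded, not
defaulted.

The excess of Vitis-like calls is tested with an exact upper-tail
binomial test computed in log space (lgamma-based log PMF summed via
log-sum-exp, so the p-value is exact to double precision even at
p ≈ 10⁻¹⁴⁰). The null proportion defaults to the larger control-genome
Vitis-like rate and is always explicit in the output; when both controls
are 0% at desk scale, the larger Laplace-smoothed control rate
(k+1)/(n+2) is used so the null stays proper. The expression relation
uses Spearman rank correlation between the affinity margin and RPKM,
reported undefined when either variable is constant.

## The synthetic study

The generator emulates the study's structure, not its sequences:

* **Trees.** Each cluster restricts the accepted species topology to a
  random taxon subset (each optional taxon kept with probability 0.7)
  that always satisfies the retention filter. With probability
  `hgt_fraction` (default 0.021, the parasite HGT rate observed in the
  real system) the parasite tip is pruned and regrafted as sister to
  *Vitis* — HGT is simulated at the tree level because that is the
  classifier's operational definition. With probability
  `noise_fraction` (default 0.05) one random NNI is applied inside the
  ingroup (the outgroup tip never moves, keeping rooting well defined).
  Branch lengths are Gamma(2, 0.05) (mean 0.1 subst/site, a typical
  terminal-branch scale for these divergences); supports are drawn
  uniformly from 85–100 on undisturbed internal edges and 30–80 on the
  rearranged edge — supports are simulated, not bootstrapped, because
  tree inference is out of scope and the classifier consumes only the
  numbers.
* **Codon profiles.** One Dirichlet draw per clade (concentration 30
  over the 61 sense codons — clades clearly distinct), then one
  concentrated Dirichlet draw per genome around its clade mean
  (concentration 500 — within-clade resemblance). This gives the
  tunable within/between-clade contrast the affinity analysis needs.
* **Sequences.** Transcripts are 150–400 codons sampled i.i.d. from the
  genome's profile (no internal stops by construction). An HGT-truth
  parasite transcript is sampled from the *Vitis* profile (the
  transferred copy carries the donor's coding properties); a VGT-truth
  one from its own profile, except with probability
  `host_like_vgt_fraction` (default 0) from the host profile — the
  planted convergence signal.
* **Genomic copies and reads.** With probability `intron_rate` (default
  0.5) a genomic copy receives one intron "GT" + random + "AG" of
  60–140 bp at a uniform position ≥ one read length from each end.
  cDNA read counts per transcript come from the expression model
  (default lognormal with mean-log 3.5, σ 1.0, Poisson-sampled —
  heavy-tailed like real libraries); gDNA coverage is a constant 20
  reads per transcript, deliberately category-independent so
  verification parity is a property of the pipeline, not the generator.
  Reads are 150 bp exact substrings: **error-free**. The zero-mismatch
  contract means sequencing errors would only exercise the rejection
  path, which unit tests cover directly.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: sequencing error and quality, indels and
alignment uncertainty, real bootstrap resampling (supports are draws,
not replicates), incomplete lineage sorting and paralogy as genuine
biological discordance (noise is a generic NNI), assembly artefacts, and
host contamination itself. The pipeline's behaviour under those
conditions must be argued from its contracts (e.g. exact matching can
only under-verify, never over-verify), not from the simulation.

Determinism: one `numpy.random.Generator` seeded from the config drives
every draw in a fixed order, so identical configs give byte-identical
outputs; every emitted run records the config including the seed.

## Problem sizes

The test suite and the acceptance script size their simulations for
statistical resolution at interactive scale: 1000 clusters for
classifier-recovery and background-rate checks (the 99% binomial
interval at h = 0.05 is then ±1.8 points), 2000 tree-only clusters for
the headline rate simulation, 150–250 clusters with full sequences for
verification, intron and affinity checks, and 400 replicates for the
5% ± 2.5% calibration checks of Welch's test and the rank correlation.

## Known limitations

* The rate proxy (terminal branch length) is not a model-based rate
  estimate; relative-rate or local-clock tests are out of scope.
* Intron calls assume clean splice junctions; small deletions or
  junction-adjacent polymorphism would break the exact-extension logic.
* The binomial null for the convergence test is a design choice (control
  rate), not a derived quantity; it is always printed alongside the
  p-value.
* Expression quantification is not isoform-aware and uses whole-read
  multi-mapping, which can inflate counts for recently duplicated
  homologues.
* The serialized TSV schema for clusters with multiple same-genome
  transcripts is this package's own convention.
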