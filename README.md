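# hgtscan

Phylogenomic detection of host-to-parasite horizontal gene transfer (HGT)
from transcriptome data.

## The problem

Endophytic holoparasites such as *Rafflesia* live embedded in the tissue of
their obligate host (*Tetrastigma*, grapevine family), an intimacy that
favours gene exchange. A parasite transcript is evidence for HGT when its
gene tree places it next to the host lineage instead of next to the
parasite's own closest relatives — but gene trees also disagree with
species trees for mundane reasons (incomplete lineage sorting, paralogy,
noise), and an apparently host-like transcript may simply be host
contamination. A credible genome-wide HGT survey therefore needs, beyond
the placement rule itself: background rates measured on non-parasitic
control genomes, verification that candidate transcripts are integrated in
the parasite's genome, and evidence that they are genuinely expressed.

`hgtscan` implements that whole analysis as a tested, reusable pipeline,
driven by a synthetic-data generator with planted ground truth so every
stage can be validated end to end without the original sequencing data.

## What the pipeline computes

Given gene trees over a 12-taxon panel (parasite, host lineage, their
sequenced relatives, reference genomes, *Oryza* outgroup):

1. **Classification** (`hgtscan.classify`). Each focal transcript is
   classified from its outgroup-rooted gene tree by its sister group *S*
   and the bootstrap support *b* of the (focal ∪ *S*) clade:
   **VGT** if *S* ⊆ {*Manihot*, *Populus*, *Ricinus*} and *b* ≥ τ,
   **HGT** if *S* ⊆ {*Vitis*} and *b* ≥ τ (τ = 50 by default, swept over
   50–70), otherwise **unassigned**. The same rule applied to *Manihot*
   and *Ricinus* yields the background discordance rate.
2. **Substitution rates** (`hgtscan.rates`). Terminal branch lengths as a
   rate proxy; Welch's unequal-variance *t* test between groups.
3. **Genomic integration** (`hgtscan.verify`). Each genomic read is split
   into 25 bp fragments and matched exactly (zero mismatches, both
   strands) against the transcripts; a transcript with ≥ 1 genomic-read
   fragment hit is verified. Split reads whose flanks map at two offsets
   reveal introns; calls report the canonical GT (donor) / AG (acceptor)
   motifs. Parasite–host divergence comes from global alignment.
4. **Expression** (`hgtscan.expression`). Per-transcript mapped-read
   counts *N* normalized as R = N / (L − k + 1 + l − k) and as standard
   RPKM = 10⁹·N / (L·ΣN).
5. **Coding properties** (`hgtscan.coding`). Each coding sequence becomes
   an 81-feature profile (4 nucleotide + 16 dinucleotide + 61 sense-codon
   frequencies); profiles are compared within a cluster by the symmetric
   χ² distance d(p,q) = Σᵢ(pᵢ−qᵢ)²/(pᵢ+qᵢ). A transcript whose smallest
   distance is to a host-side homologue is "Vitis-like"; an excess over
   the control rate is tested with an exact upper-tail binomial test, and
   host-likeness is correlated with expression (Spearman).
6. **Synthetic study** (`hgtscan.simulate`). Gene trees with a planted
   HGT fraction (parasite tip regrafted sister to *Vitis*) and NNI noise,
   genome-specific codon profiles, codon-sampled transcripts, genomic
   copies with planted GT..AG introns, and error-free cDNA/gDNA reads —
   all with recorded truth.

## Worked example

```python
from hgtscan.simulate import SimulationConfig
from hgtscan.pipeline import run_pipeline

cfg = SimulationConfig(seed=7, n_clusters=100, hgt_fraction=0.1,
                       host_like_vgt_fraction=0.3)
report = run_pipeline(cfg, "runs/demo")
c = report["classification"]["Rafflesia"]
print(c["n_hgt"], c["n_total"], c["pct_hgt"])
print(report["coding"]["affinity_rates"]["Rafflesia"]["pct_vitis_like"])
print(report["coding"]["binomial_test"]["p_value"])
```

prints

```
12 100 12.0
37.34939759036145
8.044100566383978e-32
```

meaning: of 100 simulated parasite transcripts with a planted 10% HGT
fraction, 12 were classified HGT (within binomial noise of the planted
count; both control genomes came out at 0% background on this run);
37.3% of the parasite's vertically inherited transcripts were closer in
coding properties to *Vitis* than to the Malpighiales controls (30% was
planted), an excess the exact binomial test finds overwhelming. The full
report also contains the threshold sweep, rate and expression
comparisons, verification percentages stratified by support and length
(100% for both categories here — reads are error-free), intron calls
(15 complete calls on this run, all with GT/AG motifs) and parasite–host
divergence (mean 23.8% across the 10 comparable HGT transcripts).

The same stages are available from the shell:

```sh
hgtscan simulate --seed 7 --n-clusters 100 --out sim/
hgtscan classify --trees sim/trees --tip-genome sim/tip_genome.tsv --sweep --out calls.tsv
hgtscan verify --transcripts sim/transcripts.fasta --gdna-reads sim/gdna_reads.fasta --out verified.tsv
hgtscan run --out runs/full
```

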