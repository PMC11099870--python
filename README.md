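# glymem

Analysis pipeline for **glucose-induced transcriptional and chromatin
"memory"** in endothelial cells, and for its reversal by NRF2-pathway
activation.

Transient hyperglycemia leaves endothelial cells with persistent
("memory") changes: genes stay mis-expressed and chromatin regions stay
abnormally accessible after glucose normalisation. `glymem` implements the
integrated bulk RNA-seq / ATAC-seq analysis of such a study — differential
expression, Poisson differential accessibility, enhancer annotation by
histone-mark co-overlap, TAD-constrained enhancer→gene linkage with
direction concordance, restoration classification under sulforaphane (SF)
or NRF2 overexpression (OE), and PWM motif enrichment — together with a
synthetic-study generator with planted ground truth, so every stage is
exercised and validated without external downloads.

It is aimed at computational biologists who want a transparent, fully
tested reimplementation of this analysis pattern that runs on gene-level
count TSVs, peak/mark/TAD BED files, FASTA and JASPAR-style PFMs.

## Methods at a glance

**Differential expression** (per gene *g*, treatment *B* vs reference *A*):
counts are normalised by median-of-ratios size factors
*s<sub>j</sub>* = median<sub>g</sub> *K<sub>gj</sub>* / (∏<sub>j</sub>*K<sub>gj</sub>*)<sup>1/m</sup>;
with normalised group means μ̂<sub>A</sub>, μ̂<sub>B</sub> and a pooled
moment dispersion α̂ (NB variance μ + αμ²),

> log2FC = log₂((μ̂_B + ½)/(μ̂_A + ½)),  
> SE² = (1/ln 2)² [(1/μ̂_A + α̂)/n_A + (1/μ̂_B + α̂)/n_B],  z = log2FC/SE

with two-sided normal *p* and Benjamini–Hochberg adjustment. A gene is a
**DEG** at padj < 0.05 and |log2FC| > 0.5.

**Differential accessibility**: replicates pooled per condition, scaled to
tags per 10 million; with λ = max(ref, 1) the gain tail is the exact
Poisson sum P(X ≥ ⌈treat⌉ | λ) (and symmetrically for losses). A region is
a **DAR** at fold > 1.5 (either direction) and *p* < 10⁻⁴.

**Enhancers and targets**: a DAR overlapping ≥ 1 bp of both an H3K4me1 and
an H3K27ac peak is a **DAE**; its candidate targets are the shared DEGs
whose TSS lies in the same TAD (midpoint assignment, half-open
coordinates); a link is *concordant* when accessibility and expression
change share a sign.

**Restoration**: a baseline differential feature is *restored* when the
intervention arm no longer calls it differential versus the same control.
All printed percentages are integers, rounded half away from zero.

**Motifs**: JASPAR-style PFMs with pseudocount 0.25, log-odds ZOOPS
scanning of both strands at a threshold of 0.8 × max score, hypergeometric
enrichment against an explicit background or a seeded 3× dinucleotide
shuffle of the targets.

## Worked example

```python
from glymem import (SyntheticConfig, simulate_study, nb_wald_contrast,
                    deg_set, set_algebra)

study = simulate_study(SyntheticConfig(seed=0))
hg  = nb_wald_contrast(study.expression, "control", "HG")
mem = nb_wald_contrast(study.expression, "control", "memory")
out = set_algebra(deg_set(hg), deg_set(mem))
print(out["n_a"], out["n_b"], len(out["shared"]),
      out["percent_shared_of_a"], out["percent_shared_of_b"])
```

prints

```
269 263 201 75 76
```

— 269 high-glucose DEGs and 263 memory DEGs, of which 201 are shared
(75 % of HG, 76 % of memory): most expression changes persist after
glucose normalisation, which is the transcriptional memory. The generator
planted 200 shared genes, so the recovered signature is essentially exact.
The scripts in `examples/` walk through each capability the same way
(accessibility: 200 HG DARs, 90 % gains, intron/intergenic-dominated;
enhancer linkage: 101 DAEs, 96 % concordant with their same-TAD targets;
restoration: 50 % of memory DEGs remain under SF, 24 % under NRF2 OE, 75 %
of memory DARs restored by SF; motifs: the planted bZIP core TGA(C/G)TCA
ranks first at padj ≈ 7e-33).

A thin CLI mirrors the library:

```bash
glymem run --outdir out --seed 0          # simulate + full pipeline + report
glymem simulate --outdir study --seed 0   # artifacts only
glymem de --counts study/expression_counts.tsv --treatment HG --out de.tsv
```

`out/report.json` is byte-identical across re-runs with the same seed.

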