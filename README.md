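# polpause

Strand-aware analysis of RNA polymerase II (Pol II) occupancy **downstream of
the 3′ end of annotated genes** (EAGs) from ChIP-seq tag data.

After transcribing a gene, Pol II does not disappear at the annotated 3′
boundary: it pauses on the template before termination. On most
protein-coding genes — whose transcripts are polyadenylated — this downstream
occupancy decays slowly and remains detectable 4–6 kb past the EAG. On
replication-dependent core histone genes, whose non-polyadenylated mRNAs are
3′-processed by a distinct stem-loop/U7 machinery, occupancy drops sharply
within a few hundred bp. `polpause` turns aligned short tags (BED6) plus gene
annotations (BED12 / refFlat / GTF) into:

- orientation-normalised, binned occupancy matrices anchored at the TSS, the
  EAG, or a proportionally rescaled gene body (metagene profiles);
- K-means partitions of the downstream-of-EAG patterns (narrow,
  core-histone-like vs broad, poly(A)⁺-like), with adjusted-Rand-index
  evaluation against known labels;
- per-gene pause metrics: extent of downstream signal above a mock-derived
  background threshold, exponential decay length λ, TSS/downstream pausing
  indices, and a narrow/broad/none shape call;
- expression stratification (replicate-averaged tables, highly-expressed
  gene selection, per-cluster expression summaries) and sense/antisense
  fractions for stranded nascent-transcription (GRO-seq-like) reads;
- a two-condition perturbation comparator (e.g. polyadenylation inhibition)
  reporting mock-normalised region signals and bootstrap CIs on
  treated/untreated ratios at qPCR-style offsets.

A first-class synthetic-data module plants these phenomena with known
parameters (TSS-proximal peak 20–50 nt past the TSS, gene-body plateau,
exponential 3′ pause with λ = 250 bp for histone-type and λ = 1500 bp for
poly(A)⁺-type genes, uniform mock background, sense-stranded nascent reads),
so every stage of the pipeline is testable against ground truth.

## Model

Per-base occupancy intensity of a gene with strand-aware anchors TSS and EAG:

```
intensity(x) = background
             + A_tss · exp(−(x − (TSS+δ))² / 2σ²)          promoter-proximal pause (δ≈30 nt, σ≈150 bp)
             + body · 1[x in gene body]
             + A_pause · exp(−d/λ) · 1[0 < d ≤ cap]         3′ pause, d = distance past EAG
```

32-bp tags are sampled from this intensity, extended to 200 bp in read
orientation (the tag marks only the fragment end), binned at 50 bp, and
rpm-normalised. The decay length λ is recovered per gene by least-squares
against the extension-convolved model, and the pause extent is the distance
to the last smoothed bin above `mean + 2·sd` of the gene's mock row.

## Worked example

```python
import polpause as pp
from polpause import coverage as cov, clustering as clu, pause_metrics as pm

sc = pp.simulate_scenario(n_genes=200, seed=1)          # 100 histone-type + 100 poly(A)+-type
sizes = sc.chrom_sizes
sig  = cov.build_coverage(cov.extend_reads(sc.reads["polii"], 200, sizes), 50, sizes, normalization="rpm")
mock = cov.build_coverage(cov.extend_reads(sc.reads["mock"],  200, sizes), 50, sizes, normalization="rpm")
ms = cov.anchor_matrix(sig,  sc.genes, "EAG", 4000)     # genes x 160 bins, downstream rightward
mm = cov.anchor_matrix(mock, sc.genes, "EAG", 4000)

cr = clu.kmeans_cluster(ms, k=2, seed=1)
truth = [sc.truth.classes[g] for g in ms.genes]
print("ARI vs planted classes:", clu.adjusted_rand_index(truth, cr.labels_for(ms.genes)))

mets = pm.compute_pause_metrics(ms, mm, sig, sc.genes)
import numpy as np
for cls, lam in (("core_histone", 250), ("other", 1500)):
    sub = [mets[g] for g in ms.genes if sc.truth.classes[g] == cls]
    print(cls, "median lambda:", round(float(np.nanmedian([m.decay_length_bp for m in sub])), 1),
          "(planted", lam, ")")
```

prints

```
ARI vs planted classes: 1.0
core_histone median lambda: 242.1 (planted 250)
other median lambda: 1384.5 (planted 1500)
```

i.e. the two planted pause classes are recovered perfectly by k=2 clustering,
and the per-gene decay fits land within a few percent of the planted decay
scales at ~200 reads per gene.

The same pipeline is scriptable from the shell:

```
polpause simulate --n-genes 200 --seed 1 --out scen/
polpause run-all --config analysis.yaml --seed 1 --out results/
polpause perturb --config perturb.yaml
```

where the YAML config names the read tracks, annotation, chromosome sizes and
parameters (flank 4000 bp, bin 50 bp, extension 200 bp, k, seed, …). Each run
writes matrices, cluster tables, per-gene metrics, profiles, and a manifest
with per-stage gene counts; a fixed seed makes reruns byte-identical.

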