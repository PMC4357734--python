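# uvtx

UVC light stalls elongating RNA polymerase II at photolesions (cyclobutane
pyrimidine dimers and 6-4 photoproducts), so nascent transcription of a gene
of length *L* is suppressed roughly in proportion to its lesion target size:
with a per-strand lesion density *d*, the chance a polymerase reaches
position *x* without arrest is e^(−dx), and the chance a whole gene is
lesion-free is the Poisson zero class e^(−dL). As transcription-coupled
nucleotide excision repair (TC-NER) clears the transcribed strand from the
5′ end and global-genomic repair (GG-NER) removes lesions everywhere,
synthesis recovers as a 5′→3′ wave — last at the 3′ ends of long genes.

`uvtx` is a tested pipeline for studying this process in silico. It is aimed
at researchers analyzing nascent-RNA (Bru-seq-style) coverage after DNA
damage who want a mechanistic generator of realistic synthetic data and the
matching analytics:

- **`uvtx.genome`** — gene/coverage containers, a synthetic gene-set
  generator (log-normal lengths 1 kbp–1 Mbp, gamma-with-zeros expression),
  BED6/BED12, bedGraph and RPKM-TSV I/O.
- **`uvtx.lesions`** — dose → lesion-density conversion (1 lesion per 14 kb
  per strand at 10 J/m²), Poisson lesion placement, lesion-class and
  readthrough closed forms.
- **`uvtx.repair`** — removal times under a deterministic TC-NER wave
  (t = x / w on the transcribed strand of expressed genes) and exponential
  GG-NER, with WT / XP-C / CS-B / no-repair genotype presets.
- **`uvtx.simulate`** — a bromouridine-labeling-window simulator: Poisson
  initiation, constant elongation, permanent arrest at unrepaired lesions,
  multinomial sequencing sampling; full condition grids with paired lesion
  realizations.
- **`uvtx.analysis`** — RPKM, TSS-anchored metagene profiles, ≥2-fold
  induced/repressed gene sets with median lengths, expression-bin
  stratification, aggregate percent recovery (total-variation distance to
  the control profile) and per-gene regional recovery.
- **`uvtx.qpcr`** — the long-qPCR lesion estimator: −ln of the
  blank-corrected fluorescence ratio gives lesions per fragment (Poisson
  zero class), rescaled per 10 kb, halved per strand and corrected by repair
  in non-transcribed DNA; plus a fluorescence simulator and a 50% template
  QC check.

## Worked example

```python
import numpy as np
import uvtx
from uvtx import analysis

# lesion statistics for a short gene (10.8 kbp) at 10 J/m2
p = uvtx.lesion_class_probabilities(10_800, uvtx.lesion_density(10.0), k_max=3)
print("lesion classes (0,1,2,>=3):", np.round(100 * p, 1), "%")

# simulate a wild-type recovery experiment on 500 synthetic genes
genes = uvtx.generate_gene_set(500, seed=1)
cfg = uvtx.SimulationConfig(doses=(10.0,), timepoints=(0.0, 6.0, 24.0),
                            genotypes=("WT",), reads_per_condition=500_000, seed=2)
res = uvtx.simulate_experiment(genes, cfg)

ctrl = res.rpkm[res.control("WT").label]
prof_ctrl = analysis.metagene(res.tracks[res.control("WT")], genes, rpkm_ctrl=ctrl)
prof_t0 = analysis.metagene(res.tracks[res.condition(10, 0, "WT")], genes, rpkm_ctrl=ctrl)
for t in (6.0, 24.0):
    prof_t = analysis.metagene(res.tracks[res.condition(10, t, "WT")], genes, rpkm_ctrl=ctrl)
    rep = analysis.percent_recovery(prof_t, prof_ctrl, prof_t0)
    print(f"WT recovery at {t:g} h: {rep.percent_recovery:.1f}% ({rep.n_genes} genes >100 kbp)")

fs = analysis.fold_change_sets(res.rpkm[res.condition(10, 0, "WT").label], ctrl, genes)
print(f"2-fold repressed median length {fs.median_repressed_length/1e3:.1f} kbp "
      f"vs induced {fs.median_induced_length/1e3:.1f} kbp")
```

Output:

```
lesion classes (0,1,2,>=3): [46.2 35.7 13.8  4.3] %
WT recovery at 6 h: 16.0% (18 genes >100 kbp)
WT recovery at 24 h: 72.6% (18 genes >100 kbp)
2-fold repressed median length 74.9 kbp vs induced 15.4 kbp
```

At 10 J/m² a 10.8 kbp gene is lesion-free in ~46% of cells, so short genes
keep transcribing; by contrast the ≥2-fold repressed genes are ~5× longer
than the induced ones (read counts are compositional: when long-gene bodies
lose synthesis, short genes gain relative share). Aggregate recovery of the
>100 kbp metagene climbs from 16% at 6 h to 73% at 24 h as the repair wave
moves 3′-ward.

There is also a CLI for the same operations: `uvtx simulate --config
cfg.yaml --out dir`, `uvtx metagene`, `uvtx recovery`, `uvtx foldsets`,
`uvtx qpcr` (see `--help` for options).

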