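# Methods

## Lesion model

UVC photolesions (CPDs plus 6-4 photoproducts, pooled as a single class of
transcription-blocking lesions) are placed as a homogeneous Poisson process
on each strand of each gene. The dose calibration is linear: 10 J/m²
produces on average one blocking lesion per 14 kb of a single strand (one
per 7 kbp of duplex), so the per-bp per-strand density is
d(dose) = dose / 10 / 14000. No saturation is modeled (the simulated doses,
10 and 20 J/m², sit in the linear regime) and no sequence-context weighting
is applied — lesion positions are uniform.

Closed forms follow directly: the lesion-class distribution of a gene of
length L is Poisson(λ = dL) per strand, and the probability that a
polymerase starting at the TSS reaches position x immediately after
irradiation is the target-theory form e^(−dx).

## Repair model

Two pathways, combined as the per-lesion minimum of removal times:

- **TC-NER** (requires CSB): a deterministic 5′→3′ wave on the transcribed
  strand of expressed genes; a lesion at offset x is removed at t = x / w.
  Default w = 6000 bp/h: a 150 kbp transcribed strand is cleared in ~25 h,
  so completion of long-gene recovery within 24 h in wild type requires the
  joint action of GG-NER, while the 3′ ends of the longest genes remain the
  last repaired — the defining kinetic signature the package exists to
  reproduce. The wave is an effective description; multiple successive
  polymerase–lesion encounters are absorbed into the single speed
  parameter, and wave restarts are not modeled.
- **GG-NER** (requires XPC): every lesion on either strand, in expressed
  and silent genes alike, is removed after an independent
  Exponential(g) waiting time. Default g = 0.08 h⁻¹ (~38% of lesions
  removed by 6 h, ~85% by 24 h), chosen once so that the GG-NER-only
  genotype shows the characteristic partial late recovery intermediate
  between wild type and no repair.

Genotype presets: WT = both pathways, XPC = TC-NER only, CSB = GG-NER only,
NONE = neither. Dose does not alter repair rates.

## Labeling-window simulator

Polymerases initiate at the TSS as a Poisson process at the gene's basal
rate (events/min), elongate at a constant default 1500 bp/min, and arrest
*permanently* at the first transcribed-strand lesion that is unrepaired at
the moment of passage — no resumption, no translesion bypass. Whether
arrested complexes are in fact degraded rather than resuming cannot be
decided from coverage data; permanent arrest plus fresh initiation is a
modeling commitment, not a biological claim.

A 30-minute labeling window starting t hours after irradiation counts only
RNA polymerized inside the window: a polymerase contributes coverage
exactly over the interval it traverses between window start and window end
(or its arrest point). Initiations are integrated from t − L/v onward, so
polymerases already in transit at window start supply 3′-end coverage of
genes longer than the ~45 kbp of travel per window. This pre-window
occupancy is the post-irradiation quasi-steady state: the arrest rule is
applied to pre-window initiations as if the lesion field had always been
present. The short transient of elongation complexes that happened to be
beyond lesion positions at the instant of irradiation is deliberately not
modeled; immediately after UV, body coverage therefore decays exactly as
e^(−dx), which is also the oracle the tests check against.

The expected per-bin mass given one lesion realization is computed by
midpoint quadrature over initiation times (step 0.5 min; the integrand is
piecewise linear, so the error is second-order in the step and negligible
next to sequencing noise). Sequencing is emulated by a single multinomial
draw of a fixed read total over all bins of all genes, making counts
compositional as in a real library: when long-gene bodies lose mass, short
genes gain relative share, which is what produces apparent "induction" of
short genes immediately after UV.

A per-gene restart-competence flag reproduces the phenotype of genes that
repair normally yet do not resume synthesis: an incompetent gene behaves in
the simulator as if its lesions were never cleared from the template, while
its repair (and hence its qPCR readout) proceeds normally.

### Library-size calibration

A few hundred simulated genes stand in for a ~23 000-gene transcriptome, so
using the in-simulation read total as the RPKM denominator would inflate
RPKM ~40-fold. `simulate_experiment` instead fixes one effective library
size, reads × 10⁹ / Σ(rate·length), computed from the gene set and shared
by all conditions. Control RPKM of a gene then equals its basal rate on the
conventional RPKM scale (so the familiar 0.3 / 1 / 5 RPKM expression
cutoffs apply directly), while per-condition read totals stay fixed and the
compositional redistribution after UV is preserved.

## Synthetic gene sets

Gene lengths are log-normal (median 30 kbp, log-sd 1.2) clipped to
[1 kbp, 1 Mbp]; basal rates are zero with probability 0.40 and
Gamma(shape 0.64, scale 2.84) otherwise, giving an overall mean of ~1.09
and median of ~0.15 RPKM-equivalents — the qualitative structure of a
fibroblast nascent-transcription profile: most genes silent or weak, a
heavy expression tail, lengths spanning three orders of magnitude. Genes
are placed without overlap on one synthetic chromosome with 10 kbp gaps.
The generator does **not** emulate isoform structure, intergenic
transcription, replication timing, chromatin state, GC/pyrimidine content,
or correlated length–expression structure of a real annotation; passing
tests therefore demonstrate the mechanics of blocking, repair and the
estimators, not re-analysis of any real dataset. p53-driven transcriptional
induction after UV is likewise outside the default model (basal rates are
constant in time).

## Recovery statistics

The aggregate statistic compares TSS-anchored metagene profiles (each gene
normalized to its own mean over the span, genes weighted equally, bins past
a gene's end excluded). The deviation of profile p from the control profile
c is the total-variation distance D = ½ Σ|p̂ − ĉ| of the normalized
profiles, and percent recovery at time t is 100 (1 − D_t / D_t0), clipped
to [0, 100]. No formula for "percent recovery" is standard; total variation
is used because it is bounded, scale-free, and exactly zero at an even,
control-like read distribution. The default long-gene analysis uses genes
>100 kbp with control RPKM >0.5 and a 300 kbp span: a span extending well
past the 24 h repair-wave front (~144 kbp) is required for the statistic to
see the unrepaired 3′ ends that separate wild type from GG-NER-deficient
cells.

Aggregate total variation cannot localize recovery within genes (a
uniformly suppressed slice renormalizes to flat), so the 5′→3′ wave is
measured per gene with `regional_recovery`: for a gene-fraction window
(e.g. first or last fifth), the region's library-normalized coverage ratio
to control r(t) deviates from 1 after UV — above 1 at the 5′ end (read
pile-up), toward 0 deep in the body — and recovery is the shrinkage of that
deviation, 100 (1 − |r_t − 1| / |r_t0 − 1|), averaged over genes whose
region deviated by at least 0.1 at t = 0.

Fold-change sets use ratio (uv + 0.01) / (ctrl + 0.01) RPKM (pseudocount
against division by zero), restricted to genes with control RPKM ≥ 0.3;
expression strata are (0.3, 1), (1, 2) and (>5) RPKM with the gaps left
unassigned.

## Long-qPCR estimator and simulator

Amplification of a ~10 kbp fragment requires a lesion-free template, so
−ln((F_irr − F_blank)/(F_ctrl − F_blank)) estimates the mean lesion count
per duplex fragment (Poisson zero class). Estimates are rescaled per 10 kb,
and the strand-specific statistic halves the duplex count and subtracts the
per-strand repair observed in non-transcribed DNA:
remaining = L_gene(t)/2 − (L_nt(0) − L_nt(t))/2, clipped at 0. The
arithmetic of the background correction admits a second reading — subtract
the non-transcribed *remaining* level directly — which is available as
`mode="direct"` without endorsing either as canonical. Negative estimates
are clipped to 0 with a warning; an irradiated signal at or below blank
returns +inf with a warning (no amplification). A 50% template control must
yield 0.5 ± 0.15 of the full-template fluorescence for the PCR to count as
quantitative.

The matched simulator computes the zero-class fraction either exactly
(P = e^(−λ_surviving), used where determinism matters) or by drawing
n template fragments with Poisson lesions and repair-law removal times
(default 1000, reproducing sampling error), then applies mean-one
log-normal noise (CV default 0.1) to both fluorescence channels.
Replicate spread is summarized with percentile bootstrap confidence
intervals rather than analysis-of-variance significance marks.

## Numerical and design notes

- Coordinates are 0-based half-open; gene-local bin 0 sits at the TSS on
  either strand; strand is resolved only at bedGraph import/export.
- Binning is 500 bp; the final bin of a gene may be partial.
- Paired design: one lesion realization per (gene, dose), reused across
  timepoints and genotypes (removal times re-drawn per genotype), so
  between-condition contrasts are not confounded by placement noise.
- Seeds: every stochastic step derives a child seed from (run seed, stage,
  gene, dose, genotype, timepoint) indices; identical configuration and
  seed give identical output byte-for-byte.
- A lesion exactly at a bin edge truncates coverage at that edge; a lesion
  removed exactly at the passage time does not block (strict inequality).
- Test and acceptance problem sizes: 400–1000 genes, 0.4–2 M reads per
  condition, 3–5 seeded replicates, 10⁴ polymerase realizations for the
  readthrough oracle, 8 × 1000 template draws per qPCR lambda. These sizes
  put Monte-Carlo error well below the effect sizes under test while
  keeping a full run in seconds.

## Known limitations

- The TC-NER wave is deterministic and common to all genes; real repair
  kinetics are heterogeneous, so simulated aggregate profiles have sharper
  recovery fronts than real ones.
- Permanent arrest + fresh initiation is one of several mechanisms
  (backtracking, bypass, polymerase degradation) consistent with coverage
  data; the simulator commits to it.
- No FASTQ/SAM read-level output, no splicing or RNA degradation, no
  isoforms, no enrichment analytics.
- The expression and length distributions are convenient parametric stand-
  ins, not fits to an annotation; absolute recovery percentages depend on
  the chosen span and gene filters and should be compared only within a
  configuration.
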