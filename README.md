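# syngs

Forward-in-time simulation of **recurrent genomic selection in synthetic
populations**.

Synthetic populations — the classical source material of recurrent
selection in allogamous crops such as maize — are created by intermating
a small number of parent lines (Np) and random-mating their progeny for a
few generations (NR). `syngs` simulates the complete breeding scheme to
study how Np, NR, ancestral linkage disequilibrium (LD), training-set
size and marker density shape the *persistency* of genomic prediction
accuracy and the cumulative genetic gain over many selection cycles
without retraining.

The pipeline:

1. **Ancestral populations.** Wright–Fisher random mating with mutation
   on a 10-chromosome, 1913 cM genetic map until mutation–drift
   equilibrium, then a strong bottleneck (which builds long-range LD) and
   re-expansion → population *LR*; continued random mating at large size
   breaks the long-range associations → population *SR*.
2. **Synthetics.** Np parental gametes are drawn and doubled in silico
   into homozygous lines, all Np(Np−1)/2 single crosses are made (Syn0),
   and the crosses are random-mated NR times (SynNR), with full
   parental-origin tracking of every chromosome segment.
3. **Trait.** 1000 biallelic, purely additive QTL; |effects| ~
   Gamma(shape 1.66, scale 0.4) with random signs; TBV
   g_i = Σ_j (w_ij − 2p_j) a_j with ancestral-frequency centering. The
   error variance is calibrated once so that ancestral heritability
   averages 0.5.
4. **Prediction.** GBLUP, y = μ + g + ε with g ~ N(0, σ²_a K), where K is
   the VanRaden genomic relationship matrix
   k_ij = Σ_k (x_ik − 2p_k)(x_jk − 2p_k) / Σ_k 2p_k(1 − p_k)
   built from SNPs (QTL excluded, ancestral frequencies p_k), or the
   pedigree numerator relationship matrix (pedigree BLUP). Variance
   components by spectral profile REML.
5. **Recurrent selection.** The model is trained once on a phenotyped
   training set (NTS = 250) and reused for 30 cycles: each cycle the 100
   candidates are scored (EBV, TBV, or random), the top 10 are selected
   and random-mated into the next 100 candidates. Reported per cycle:
   prediction accuracy r(g, ĝ), cumulative gain ΣΔG in units of
   σ_A(anc), additive variance σ²_A in units of σ²_A(anc), and
   segment-length statistics.

Four information-source scenarios separate what the markers exploit:
`Re-LDA-SNP` (pedigree + cosegregation + ancestral LD), `Re-LEA-SNP`
(ancestral QTL–SNP LD removed by reshuffling parental QTL/SNP blocks),
`Re-LDA-Ped` (pedigree BLUP), and `Un-LDA-SNP` (training set and
candidates from synthetics with disjoint parents — ancestral LD only).

## Worked example

```python
import numpy as np
from syngs import DeskProfile, ExperimentConfig, prepare_inputs, run_replicate
from syngs.grid import replicate_seed

gmap, pops, calib = prepare_inputs(DeskProfile(), root_seed=1,
                                   include_sr=False)
print(f"ancestral h2 = {calib.h2_anc:.3f}")

cfg = ExperimentConfig(scenario="Re-LDA-SNP", n_parents=4, n_cycles=2)
res = run_replicate(pops["LR"], calib, cfg, seed=replicate_seed(1, 0, 0))
for m in res.metrics:
    print(f"cycle {m.cycle}: r = {m.accuracy:.3f}, "
          f"gain = {m.cum_gain:.2f} sd_A, sigma2_A = {m.sigma2_A:.2f}, "
          f"segments = {m.mean_segment_length:.1f} cM")
```

prints

```
ancestral h2 = 0.497
cycle 0: r = 0.811, gain = 0.00 sd_A, sigma2_A = 0.83, segments = 66.7 cM
cycle 1: r = 0.760, gain = 1.28 sd_A, sigma2_A = 0.73, segments = 44.4 cM
cycle 2: r = 0.505, gain = 2.50 sd_A, sigma2_A = 0.49, segments = 33.7 cM
```

Training-generation accuracy is high (~0.8); a single selection cycle
already erodes it, and the genetic variance of the candidates declines
under truncation selection while mean performance rises by ~1 ancestral
genetic standard deviation per early cycle. Candidate genomes in Syn1
are mosaics of parent-line segments averaging ~66 cM.

Grids over the full factor space (two ancestral populations, four
scenarios, Np = 2…32, three selection regimes, NR, NTS, marker density)
run via the CLI:

```sh
syngs run --config grid.yaml --out results/ --seed 1
syngs simulate-ancestral --scale 0.1 --seed 1 --out anc
syngs aggregate --dir results/
```

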