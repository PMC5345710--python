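"""Additive trait architecture, true breeding values, and phenotypes.

The trait is controlled by ``n_qtl`` biallelic QTL with purely additive
gene action.  Absolute effect sizes are gamma-distributed (scale 0.4,
shape 1.66, hence mean |a| = 0.664) with random signs.  The true breeding
value of individual i is

    g_i = sum_j (w_ij - 2 p_j) a_j,

where w_ij counts copies of the designated minor allele at QTL j and p_j
is that allele's frequency in the ancestral LR population (used for
centering throughout, also for SR-derived material, whose frequencies are
nearly identical).

The environmental error variance is calibrated once per experiment:
sigma2_e is set equal to the mean additive genetic variance of the LR
population over replicated samplings of the QTL set, which makes the
average ancestral heritability 0.5.  It is then held constant for all
replicates of the selection stage.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ancestral import AncestralPopulation, BaseFrequencies
from .genome import GeneticMap, Individual, allele1_dosage, as_rng

__all__ = [
    "TraitArchitecture",
    "TraitCalibration",
    "sample_architecture",
    "tbv",
    "calibrate_error_variance",
    "phenotype",
    "write_architecture",
]

GAMMA_SCALE = 0.4
GAMMA_SHAPE = 1.66


@dataclass(frozen=True)
class TraitArchitecture:
    qtl_loci: np.ndarray        # locus indices into the map
    effects: np.ndarray         # signed effect per QTL

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_loci)


@dataclass(frozen=True)
class TraitCalibration:
    """Error-variance calibration against the ancestral LR population."""

    sigma2_A_anc: float         # mean ancestral additive variance
    sigma2_e: float             # error variance, set equal to sigma2_A_anc
    h2_per_rep: np.ndarray      # per-replicate ancestral heritability

    @property
    def h2_anc(self) -> float:
        return float(self.h2_per_rep.mean())

    @property
    def sigma_A_anc(self) -> float:
        return float(np.sqrt(self.sigma2_A_anc))


def sample_architecture(gmap: GeneticMap, base: BaseFrequencies,
                        n_qtl: int, rng,
                        gamma_scale: float = GAMMA_SCALE,
                        gamma_shape: float = GAMMA_SHAPE) -> TraitArchitecture:
    """Sample ``n_qtl`` causal loci (without replacement) from the
    QTL-pool loci that segregate in the ancestral base, with gamma
    absolute effects and Bernoulli(0.5) signs.

    The gamma parameterization is exposed; swapping scale and shape
    reproduces the alternative convention found in the literature.
    """
    rng = as_rng(rng)
    poly = (base.p > 0) & (base.p < 1)
    candidates = np.flatnonzero(gmap.is_qtl & poly)
    if len(candidates) < n_qtl:
        raise ValueError(
            f"only {len(candidates)} polymorphic QTL-pool loci available, "
            f"need {n_qtl}")
    loci = np.sort(rng.choice(candidates, n_qtl, replace=False))
    magnitude = rng.gamma(shape=gamma_shape, scale=gamma_scale, size=n_qtl)
    signs = rng.integers(0, 2, n_qtl) * 2 - 1
    return TraitArchitecture(loci, magnitude * signs)


def _minor_counts(individuals_or_haps, loci: np.ndarray,
                  base: BaseFrequencies) -> np.ndarray:
    if isinstance(individuals_or_haps, np.ndarray):
        H = individuals_or_haps
        d = (H[0::2][:, loci].astype(np.int16) + H[1::2][:, loci])
    else:
        d = allele1_dosage(individuals_or_haps, loci)
    return np.where(base.minor_is_one[loci], d, 2 - d)


def tbv(individuals, arch: TraitArchitecture,
        base: BaseFrequencies) -> np.ndarray:
    """True breeding values g = (W - 2p) a.

    `individuals` may be a list of Individual or a (2N, L) haplotype
    array (rows 2i, 2i+1 belong to individual i).
    """
    w = _minor_counts(individuals, arch.qtl_loci, base).astype(np.float64)
    w -= 2.0 * base.p[arch.qtl_loci]
    return w @ arch.effects


def calibrate_error_variance(anc_lr: AncestralPopulation, gmap: GeneticMap,
                             n_reps: int, rng,
                             n_qtl: int = 1000) -> TraitCalibration:
    """Set sigma2_e to the mean LR additive variance over ``n_reps``
    independent samplings of the QTL set and its effects."""
    rng = as_rng(rng)
    if n_reps < 2:
        raise ValueError("need at least two calibration replicates")
    variances = np.empty(n_reps)
    for r in range(n_reps):
        arch = sample_architecture(gmap, anc_lr.base, n_qtl, rng)
        g = tbv(anc_lr.haplotypes, arch, anc_lr.base)
        variances[r] = g.var(ddof=1)
    sigma2 = float(variances.mean())
    if sigma2 <= 0:
        raise ValueError("additive variance is zero; QTL are monomorphic")
    h2 = variances / (variances + sigma2)
    return TraitCalibration(sigma2, sigma2, h2)


def phenotype(tbvs: np.ndarray, calib: TraitCalibration, rng) -> np.ndarray:
    """y = g + e with e ~ N(0, sigma2_e) i.i.d."""
    rng = as_rng(rng)
    g = np.asarray(tbvs, dtype=float)
    return g + rng.normal(0.0, np.sqrt(calib.sigma2_e), size=g.shape)


def write_architecture(arch: TraitArchitecture, gmap: GeneticMap, path) -> None:
    """Tab-separated export: chromosome, position_cM, effect."""
    with open(path, "w") as fh:
        for locus, a in zip(arch.qtl_loci, arch.effects):
            fh.write(f"{gmap.chrom[locus]}\t{gmap.pos[locus]:.6f}\t{a:.8g}\n")
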