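"""Wright-Fisher simulation of ancestral populations with controlled LD.

Two ancestral populations are produced from one forward simulation:

* **LR** — extensive long-range LD: random mating at constant size until
  mutation-drift equilibrium, a strong bottleneck followed by further
  random mating (which builds up long-range associations), then expansion.
* **SR** — short-range LD: derived from LR by continued random mating at
  the large expanded size, which breaks down long-range LD while leaving
  allele frequencies nearly unchanged.

Default stage parameters: initial size 1500 mated for 3000 generations at
mutation rate 2.5e-5 per locus per gamete per generation; bottleneck to 30
individuals for 15 generations; expansion to 10,000 with three rounds of
random mating (LR); 100 further generations at 10,000 (SR).

A ``scale_factor`` shrinks population sizes and, proportionally, the long
generation counts (equilibrium and SR phases), preserving the ratio t/N
that governs drift and LD build-up; the bottleneck size is never scaled
below 10.  Haplotypes are dense uint8 arrays and meiosis is executed by a
compiled kernel, so the scaled stage runs in seconds.

Individuals here are the *reference base* of all pedigrees: they are
treated as unrelated and non-inbred even though they share ancestry
within the simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numba
import numpy as np

from .genome import GeneticMap, as_rng

__all__ = [
    "AncestralParams",
    "BaseFrequencies",
    "AncestralPopulation",
    "simulate_ancestral",
    "wf_generation",
    "ld_profile",
    "save_population",
    "load_population",
    "write_vcf",
]


@dataclass(frozen=True)
class AncestralParams:
    """Stage sizes and durations of the ancestral simulation."""

    n_initial: int = 1500
    n_equilibrium_gens: int = 3000
    mutation_rate: float = 2.5e-5     # per locus per gamete per generation
    bottleneck_size: int = 30
    n_bottleneck_gens: int = 15
    expanded_size: int = 10_000
    n_expand_gens: int = 3
    n_sr_extra_gens: int = 100
    scale_factor: float = 1.0

    def __post_init__(self):
        if not (0 < self.scale_factor <= 1):
            raise ValueError("scale_factor must be in (0, 1]")
        for name in ("n_initial", "n_equilibrium_gens", "bottleneck_size",
                     "n_bottleneck_gens", "expanded_size", "n_expand_gens",
                     "n_sr_extra_gens"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def effective(self) -> "AncestralParams":
        """Apply ``scale_factor``: sizes multiplied, long phases shortened.

        Bottleneck size is clamped at >= 10 and its (short) duration kept,
        as are the expansion rounds.
        """
        s = self.scale_factor
        if s == 1.0:
            return self
        return replace(
            self,
            n_initial=max(2, round(self.n_initial * s)),
            n_equilibrium_gens=round(self.n_equilibrium_gens * s),
            bottleneck_size=max(10, min(self.bottleneck_size,
                                        round(self.bottleneck_size * s))),
            expanded_size=max(2, round(self.expanded_size * s)),
            n_sr_extra_gens=round(self.n_sr_extra_gens * s),
            scale_factor=1.0,
        )


@dataclass(frozen=True)
class BaseFrequencies:
    """Ancestral reference allele frequencies (minor allele fixed in LR).

    ``minor_is_one[k]`` says whether allele 1 is the designated minor
    allele at locus k (ties at 0.5 break toward allele 1); ``p[k]`` is the
    LR frequency of that minor allele.  All downstream genotype centering
    uses these frequencies, for LR- and SR-derived material alike.
    """

    p: np.ndarray
    minor_is_one: np.ndarray

    def minor_dosage(self, allele1_dosage: np.ndarray,
                     loci=None) -> np.ndarray:
        """Convert allele-1 dosages {0,1,2} to minor-allele counts.

        `loci` restricts the designation to the locus subset the dosages
        were taken at (columns of `allele1_dosage`).
        """
        d = np.asarray(allele1_dosage)
        flag = self.minor_is_one if loci is None else self.minor_is_one[loci]
        return np.where(flag, d, 2 - d)


@dataclass
class AncestralPopulation:
    """A diploid population stored as a (2N, L) haplotype array.

    Row 2i and 2i+1 are the two haplotypes of individual i.
    """

    label: str                      # "LR" | "SR"
    haplotypes: np.ndarray          # (2N, L) uint8
    gmap: GeneticMap
    base: BaseFrequencies | None = None

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    def allele1_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def polymorphic(self) -> np.ndarray:
        """Boolean mask of loci segregating in this population."""
        p = self.allele1_freq()
        return (p > 0) & (p < 1)


# ---------------------------------------------------------------------------
# compiled meiosis kernel
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _assemble_gametes(H, parent_rows, bp, bp_off, starts,
                      chrom_bounds, chrom_offsets, global_pos, out):
    n_gam = out.shape[0]
    n_chrom = chrom_bounds.shape[0] - 1
    for g in range(n_gam):
        base = parent_rows[g]
        j = bp_off[g]
        jend = bp_off[g + 1]
        for c in range(n_chrom):
            # discard breakpoints left over before this chromosome
            while j < jend and bp[j] < chrom_offsets[c]:
                j += 1
            cur = starts[g, c]
            for l in range(chrom_bounds[c], chrom_bounds[c + 1]):
                while j < jend and bp[j] <= global_pos[l]:
                    cur ^= 1
                    j += 1
                out[g, l] = H[base + cur, l]
    return out


def wf_generation(H: np.ndarray, n_offspring: int, gmap: GeneticMap,
                  rng: np.random.Generator,
                  mutation_rate: float = 0.0) -> np.ndarray:
    """One Wright-Fisher generation: each offspring draws two parents
    uniformly with replacement (selfing possible), one recombinant gamete
    each; recurrent mutation flips alleles at the given rate."""
    n_parents = H.shape[0] // 2
    if n_parents < 2:
        raise ValueError("population size fell below 2")
    n_gam = 2 * n_offspring
    n_chrom = gmap.n_chrom
    parents = rng.integers(0, n_parents, n_gam)
    counts = rng.poisson(gmap.chrom_lengths / 100.0, size=(n_gam, n_chrom))
    flat = counts.ravel()
    total = int(flat.sum())
    rep = np.repeat(np.arange(n_gam * n_chrom), flat)
    gam_idx = rep // n_chrom
    chrom_idx = rep % n_chrom
    pos = (gmap.chrom_offsets[chrom_idx]
           + rng.random(total) * gmap.chrom_lengths[chrom_idx])
    order = np.lexsort((pos, gam_idx))
    bp = np.ascontiguousarray(pos[order])
    bp_off = np.concatenate([[0], np.cumsum(counts.sum(axis=1))]).astype(np.int64)
    starts = rng.integers(0, 2, (n_gam, n_chrom)).astype(np.uint8)
    out = np.empty((n_gam, gmap.n_loci), dtype=np.uint8)
    _assemble_gametes(H, (2 * parents).astype(np.int64), bp, bp_off, starts,
                      gmap.chrom_bounds, gmap.chrom_offsets,
                      gmap.global_pos, out)
    if mutation_rate > 0:
        n_mut = rng.binomial(out.size, mutation_rate)
        if n_mut:
            idx = rng.integers(0, out.size, n_mut)
            out.reshape(-1)[idx] ^= 1
    return out


# ---------------------------------------------------------------------------
# the full ancestral scenario
# ---------------------------------------------------------------------------

def simulate_ancestral(gmap: GeneticMap, params: AncestralParams, seed,
                       include_sr: bool = True,
                       ) -> tuple[AncestralPopulation, AncestralPopulation | None]:
    """Run the staged ancestral scenario; returns (LR, SR).

    Initial alleles are i.i.d. Bernoulli(0.5) per locus per haplotype.
    Deterministic given `seed`.  ``include_sr=False`` skips the SR phase
    and returns (LR, None).
    """
    rng = as_rng(seed)
    eff = params.effective()
    mu = eff.mutation_rate

    H = rng.integers(0, 2, (2 * eff.n_initial, gmap.n_loci), dtype=np.uint8)
    for _ in range(eff.n_equilibrium_gens):
        H = wf_generation(H, eff.n_initial, gmap, rng, mu)

    # bottleneck: arbitrary subset, then random mating at the small size
    if eff.bottleneck_size < 2:
        raise ValueError("bottleneck size below 2")
    keep = rng.choice(eff.n_initial, eff.bottleneck_size, replace=False)
    rows = np.empty(2 * eff.bottleneck_size, dtype=np.int64)
    rows[0::2], rows[1::2] = 2 * keep, 2 * keep + 1
    H = np.ascontiguousarray(H[rows])
    for _ in range(eff.n_bottleneck_gens):
        H = wf_generation(H, eff.bottleneck_size, gmap, rng, mu)

    for _ in range(eff.n_expand_gens):
        H = wf_generation(H, eff.expanded_size, gmap, rng, mu)

    p1 = H.mean(axis=0)
    minor_is_one = p1 <= 0.5
    base = BaseFrequencies(np.where(minor_is_one, p1, 1.0 - p1), minor_is_one)
    lr = AncestralPopulation("LR", H, gmap, base)

    sr = None
    if include_sr:
        Hs = H.copy()
        for _ in range(eff.n_sr_extra_gens):
            Hs = wf_generation(Hs, eff.expanded_size, gmap, rng, mu)
        sr = AncestralPopulation("SR", Hs, gmap, base)
    return lr, sr


# ---------------------------------------------------------------------------
# diagnostics and I/O
# ---------------------------------------------------------------------------

def ld_profile(pop: AncestralPopulation, distance_bins,
               rng=None, n_pairs: int = 100_000):
    """Mean r^2 between syntenic locus pairs, binned by map distance.

    Pairs of polymorphic loci on the same chromosome are sampled at
    random; monomorphic loci are excluded.  Returns a DataFrame with one
    row per bin (``mean_r2`` is NaN where no pair fell in the bin).
    """
    import pandas as pd

    rng = as_rng(rng)
    edges = np.asarray(distance_bins, dtype=float)
    gmap = pop.gmap
    poly = np.flatnonzero(pop.polymorphic())
    if len(poly) < 2:
        raise ValueError("need at least two polymorphic loci")
    # rejection-sample same-chromosome pairs
    take = rng.integers(0, len(poly), (int(n_pairs * 3), 2))
    li, lj = poly[take[:, 0]], poly[take[:, 1]]
    ok = (gmap.chrom[li] == gmap.chrom[lj]) & (li != lj)
    li, lj = li[ok][:n_pairs], lj[ok][:n_pairs]
    d = np.abs(gmap.pos[li] - gmap.pos[lj])

    Hf = pop.haplotypes
    r2 = np.empty(len(li))
    chunk = 4096
    for k in range(0, len(li), chunk):
        a = Hf[:, li[k:k + chunk]].astype(np.float64)
        b = Hf[:, lj[k:k + chunk]].astype(np.float64)
        pa, pb = a.mean(0), b.mean(0)
        pab = (a * b).mean(0)
        denom = pa * (1 - pa) * pb * (1 - pb)
        r2[k:k + chunk] = (pab - pa * pb) ** 2 / denom
    which = np.digitize(d, edges) - 1
    ok = (which >= 0) & (which < len(edges) - 1)
    which, r2 = which[ok], r2[ok]
    n = np.bincount(which, minlength=len(edges) - 1)
    s = np.bincount(which, weights=r2, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                         "mean_r2": mean, "n_pairs": n})


def save_population(pop: AncestralPopulation, path) -> None:
    np.savez_compressed(
        path, label=pop.label, haplotypes=pop.haplotypes,
        chrom_lengths=pop.gmap.chrom_lengths, chrom=pop.gmap.chrom,
        pos=pop.gmap.pos, is_qtl=pop.gmap.is_qtl,
        base_p=pop.base.p, base_minor_is_one=pop.base.minor_is_one)


def load_population(path) -> AncestralPopulation:
    z = np.load(path, allow_pickle=False)
    gmap = GeneticMap(z["chrom_lengths"], z["chrom"], z["pos"], z["is_qtl"])
    base = BaseFrequencies(z["base_p"], z["base_minor_is_one"])
    return AncestralPopulation(str(z["label"]), z["haplotypes"], gmap, base)


def write_vcf(pop: AncestralPopulation, path) -> None:
    """Minimal diploid VCF export (GT field; genetic position as INFO cM)."""
    gmap = pop.gmap
    H = pop.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description='
                 '"Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"ind{i}" for i in range(pop.n_individuals))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + samples + "\n")
        for k in range(gmap.n_loci):
            gts = "\t".join(f"{H[2 * i, k]}|{H[2 * i + 1, k]}"
                            for i in range(pop.n_individuals))
            fh.write(f"{gmap.chrom[k] + 1}\t{int(gmap.pos[k] * 1e4) + 1}\t"
                     f"locus{k}\tA\tT\t.\tPASS\tCM={gmap.pos[k]:.4f}\tGT\t"
                     + gts + "\n")
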