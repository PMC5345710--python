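"""Construction of synthetic populations from a handful of parent lines.

A synthetic is built by (i) drawing ``Np`` parental gametes from the
ancestral population and doubling them in silico into fully homozygous
parent lines, (ii) intermating the lines to obtain all Np(Np-1)/2 single
crosses (generation Syn0), and (iii) random-mating the crosses for ``NR``
rounds (selfing allowed) to obtain SynNR.  For Np=2 this reduces to an F1
(Syn0) and an F2 family (Syn1).

The training set (TS) and the initial recurrent-selection candidates
(RSC) are sampled disjointly from SynNR(1); in the unrelated design the
candidates come from a second synthetic SynNR(2) whose parents are
distinct.  The linkage-equilibrium reshuffle permutes the per-chromosome
QTL and SNP genotype blocks independently among the parents, which
destroys ancestral QTL-SNP associations while conserving allele
frequencies and within-block LD.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ancestral import AncestralPopulation
from .genome import (GeneticMap, Haplotype, Individual, PedigreeBook,
                     as_rng, crossover_plan, double_haploid, gamete_alleles,
                     mate)

__all__ = [
    "SyntheticConfig",
    "SyntheticPopulation",
    "sample_parents",
    "make_syn0",
    "random_mate",
    "reshuffle_lea",
    "build_synthetic",
    "sample_ts_rsc",
]

NP_LEVELS = (2, 3, 4, 6, 8, 12, 16, 32)
NR_LEVELS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class SyntheticConfig:
    n_parents: int = 4
    n_recomb_gens: int = 1
    related: bool = True               # TS and RSC share parents
    pop_size_per_gen: int | None = None

    def __post_init__(self):
        if self.n_parents < 2:
            raise ValueError("need at least two parents")
        if self.n_recomb_gens < 1:
            raise ValueError("need at least one recombination generation")

    def generation_size(self, n_ts: int = 250, n_rsc: int = 100) -> int:
        """Default per-generation size: large enough to draw TS and RSC."""
        if self.pop_size_per_gen is not None:
            return self.pop_size_per_gen
        return max(n_ts + n_rsc + 50, 400)


@dataclass
class SyntheticPopulation:
    generation: int                    # 0 for Syn0, r for SynR
    individuals: list[Individual]
    parent_labels: frozenset[int]      # founder (DH line) pedigree ids

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def label(self) -> str:
        return f"Syn{self.generation}"


def sample_parents(anc: AncestralPopulation, n_parents: int,
                   book: PedigreeBook, rng) -> list[Individual]:
    """Draw ``n_parents`` gametes from distinct random ancestral
    individuals and double each into a homozygous DH parent line.

    The ancestral donors are registered as (unrelated) pedigree base
    individuals; each DH line is linked to its donor.
    """
    rng = as_rng(rng)
    if n_parents > anc.n_individuals:
        raise ValueError("more parents requested than ancestral individuals")
    donors = rng.choice(anc.n_individuals, n_parents, replace=False)
    parents = []
    for d in donors:
        base_id = book.add_base()
        plan = crossover_plan(anc.gmap, rng)
        alleles = gamete_alleles(plan, anc.haplotypes[2 * d],
                                 anc.haplotypes[2 * d + 1], anc.gmap)
        parents.append(double_haploid(Haplotype(alleles, []), anc.gmap,
                                      book, base_id))
    return parents


def reshuffle_lea(parents: list[Individual], gmap: GeneticMap,
                  book: PedigreeBook, rng) -> list[Individual]:
    """Permute per-chromosome QTL and SNP genotype blocks among parents.

    For each chromosome, the QTL multi-locus genotypes and the SNP
    multi-locus genotypes are treated as separate units and independently
    permuted among the Np parents.  Allele frequencies across the parent
    set and LD within each block are conserved exactly; associations
    *between* QTL and SNPs inherited from the ancestral population are
    randomized.  Returns new DH lines (fresh founder labels).
    """
    rng = as_rng(rng)
    if not all(p.is_homozygous for p in parents):
        raise ValueError("reshuffle requires fully homozygous parents")
    n = len(parents)
    geno = np.stack([p.haplotypes[0].alleles for p in parents])  # (Np, L)
    shuffled = geno.copy()
    for c in range(gmap.n_chrom):
        sl = gmap.chrom_slice(c)
        in_chrom = np.zeros(gmap.n_loci, dtype=bool)
        in_chrom[sl] = True
        for block in (in_chrom & gmap.is_qtl, in_chrom & ~gmap.is_qtl):
            if block.any():
                perm = rng.permutation(n)
                shuffled[:, block] = geno[perm][:, block]
    out = []
    for i, p in enumerate(parents):
        new_id = book.add(p.sire_id, p.dam_id, dh=True)
        h0 = Haplotype.founder(shuffled[i], gmap, new_id)
        h1 = Haplotype.founder(shuffled[i], gmap, new_id)
        out.append(Individual(new_id, (h0, h1), p.sire_id, p.dam_id))
    return out


def make_syn0(parents: list[Individual], gmap: GeneticMap,
              book: PedigreeBook, rng,
              n_per_cross: int = 1) -> SyntheticPopulation:
    """All Np(Np-1)/2 single crosses of the parent lines (generation Syn0)."""
    rng = as_rng(rng)
    if len(parents) < 2:
        raise ValueError("need at least two parents")
    offspring = []
    for i in range(len(parents)):
        for j in range(i + 1, len(parents)):
            for _ in range(n_per_cross):
                offspring.append(mate(parents[i], parents[j], gmap, book, rng))
    return SyntheticPopulation(0, offspring,
                               frozenset(p.id for p in parents))


def random_mate(pop: SyntheticPopulation, n_offspring: int,
                gmap: GeneticMap, book: PedigreeBook,
                rng) -> SyntheticPopulation:
    """One round of random mating: each offspring draws two parents
    uniformly with replacement (selfing allowed)."""
    rng = as_rng(rng)
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    if not pop.individuals:
        raise ValueError("cannot mate an empty population")
    n = len(pop.individuals)
    sires = rng.integers(0, n, n_offspring)
    dams = rng.integers(0, n, n_offspring)
    offspring = [mate(pop.individuals[s], pop.individuals[d], gmap, book, rng)
                 for s, d in zip(sires, dams)]
    return SyntheticPopulation(pop.generation + 1, offspring,
                               pop.parent_labels)


def build_synthetic(parents: list[Individual], n_recomb_gens: int,
                    generation_size: int, gmap: GeneticMap,
                    book: PedigreeBook, rng) -> SyntheticPopulation:
    """Syn0 from all single crosses, then ``n_recomb_gens`` rounds of
    random mating at ``generation_size``."""
    pop = make_syn0(parents, gmap, book, rng)
    for _ in range(n_recomb_gens):
        pop = random_mate(pop, generation_size, gmap, book, rng)
    return pop


def sample_ts_rsc(syn1: SyntheticPopulation,
                  syn2: SyntheticPopulation | None,
                  n_ts: int, n_rsc: int, related: bool,
                  rng) -> tuple[list[Individual], list[Individual]]:
    """Sample the training set and the initial selection candidates.

    If ``related``, both come (disjointly, without replacement) from
    ``syn1``; otherwise the candidates come from ``syn2``, a synthetic
    with distinct parents.
    """
    rng = as_rng(rng)
    if related:
        if len(syn1) < n_ts + n_rsc:
            raise ValueError("synthetic too small for disjoint TS and RSC")
        perm = rng.permutation(len(syn1))
        ts = [syn1.individuals[i] for i in perm[:n_ts]]
        rsc = [syn1.individuals[i] for i in perm[n_ts:n_ts + n_rsc]]
    else:
        if syn2 is None:
            raise ValueError("unrelated design requires a second synthetic")
        if len(syn1) < n_ts or len(syn2) < n_rsc:
            raise ValueError("synthetics too small for TS / RSC")
        if syn1.parent_labels & syn2.parent_labels:
            raise ValueError("unrelated design requires disjoint parent sets")
        ts_idx = rng.choice(len(syn1), n_ts, replace=False)
        rsc_idx = rng.choice(len(syn2), n_rsc, replace=False)
        ts = [syn1.individuals[i] for i in ts_idx]
        rsc = [syn2.individuals[i] for i in rsc_idx]
    return ts, rsc
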