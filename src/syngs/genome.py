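"""Genetic maps, meiosis, and haplotype algebra with parental-origin tracking.

All positions are genetic positions in centimorgan (cM).  Within a
chromosome, intervals are half-open ``[start, end)``; a locus lying exactly
on a crossover breakpoint belongs to the segment on its right.

Recombination follows the Haldane model: the number of crossovers per
chromosome and meiosis is Poisson with mean ``length_cM / 100`` and
breakpoint positions are uniform on the chromosome, with no interference
and no obligate chiasma.

Every haplotype carries, next to its 0/1 allele vector, a list of
*origin segments*: for each chromosome, which founder (a doubled-haploid
parent line, identified by its pedigree id) contributed each stretch of
the genome.  Segments partition each chromosome exactly and adjacent
segments from the same founder are merged on creation, so segment-length
statistics can be read off directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GeneticMap",
    "Haplotype",
    "Individual",
    "PedigreeBook",
    "build_map",
    "meiosis",
    "double_haploid",
    "mate",
    "allele1_dosage",
    "write_map",
    "read_map",
    "as_rng",
]


def as_rng(seed) -> np.random.Generator:
    """Return `seed` itself if it is already a Generator, else a fresh one."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticMap:
    """A multi-chromosome genetic map with QTL/SNP role flags.

    Loci are stored sorted by (chromosome, position).  ``is_qtl`` marks the
    QTL *pool*: loci eligible to act as causal loci of the trait; all other
    loci are markers (SNPs).

    Attributes
    ----------
    chrom_lengths : ndarray, shape (n_chrom,)
        Chromosome lengths in cM.
    chrom : ndarray, shape (n_loci,)
        Chromosome index of each locus.
    pos : ndarray, shape (n_loci,)
        Position of each locus within its chromosome, in cM.
    is_qtl : ndarray of bool, shape (n_loci,)
        Role flag: True for QTL-pool loci, False for SNP markers.
    """

    chrom_lengths: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    is_qtl: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "chrom_lengths",
                           np.asarray(self.chrom_lengths, dtype=float))
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=np.int32))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=float))
        object.__setattr__(self, "is_qtl", np.asarray(self.is_qtl, dtype=bool))
        n_chrom = len(self.chrom_lengths)
        if np.any(self.chrom_lengths < 0):
            raise ValueError("chromosome lengths must be non-negative")
        counts = np.bincount(self.chrom, minlength=n_chrom)
        if np.any(counts == 0):
            raise ValueError("every chromosome must carry at least one locus")
        if np.any(np.diff(self.chrom) < 0):
            raise ValueError("loci must be grouped by ascending chromosome")
        bounds = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        for c in range(n_chrom):
            p = self.pos[bounds[c]:bounds[c + 1]]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on chromosome {c}")
            if p[0] < 0 or p[-1] > self.chrom_lengths[c]:
                raise ValueError(f"position outside chromosome {c}")
        offsets = np.concatenate([[0.0], np.cumsum(self.chrom_lengths)])
        object.__setattr__(self, "chrom_bounds", bounds)
        object.__setattr__(self, "chrom_offsets", offsets)
        object.__setattr__(self, "global_pos", offsets[self.chrom] + self.pos)

    # -- basic properties ---------------------------------------------------
    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths)

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    @property
    def total_length(self) -> float:
        return float(self.chrom_lengths.sum())

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @property
    def snp_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    def chrom_slice(self, c: int) -> slice:
        return slice(int(self.chrom_bounds[c]), int(self.chrom_bounds[c + 1]))


def build_map(n_chrom: int, total_length: float, n_loci: int,
              n_qtl: int = 0, seed=None,
              chrom_lengths: Sequence[float] | None = None) -> GeneticMap:
    """Build a map with loci placed uniformly at random.

    By default chromosomes have equal length ``total_length / n_chrom``;
    per-chromosome lengths may be supplied instead.  ``n_qtl`` loci are
    flagged at random as the QTL pool.  Deterministic given `seed`.
    """
    rng = as_rng(seed)
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    if n_loci < n_chrom:
        raise ValueError("need at least one locus per chromosome")
    if chrom_lengths is None:
        lengths = np.full(n_chrom, total_length / n_chrom)
    else:
        lengths = np.asarray(chrom_lengths, dtype=float)
        if len(lengths) != n_chrom or not np.isclose(lengths.sum(), total_length):
            raise ValueError("chrom_lengths inconsistent with n_chrom/total_length")
    # place loci uniformly over the whole map, then sort
    chrom = rng.choice(n_chrom, size=n_loci, p=lengths / lengths.sum())
    pos = rng.random(n_loci) * lengths[chrom]
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    if len(np.unique(chrom)) < n_chrom:
        raise ValueError("random placement left a chromosome without loci; "
                         "increase n_loci")
    is_qtl = np.zeros(n_loci, dtype=bool)
    if n_qtl:
        is_qtl[rng.choice(n_loci, size=n_qtl, replace=False)] = True
    return GeneticMap(lengths, chrom, pos, is_qtl)


def write_map(gmap: GeneticMap, path) -> None:
    """Export as tab-separated text: chromosome, position_cM, role."""
    with open(path, "w") as fh:
        for c, p, q in zip(gmap.chrom, gmap.pos, gmap.is_qtl):
            fh.write(f"{c}\t{p:.6f}\t{'QTL' if q else 'SNP'}\n")


def read_map(path, chrom_lengths: Sequence[float]) -> GeneticMap:
    chrom, pos, qtl = [], [], []
    with open(path) as fh:
        for line in fh:
            c, p, role = line.rstrip("\n").split("\t")
            chrom.append(int(c))
            pos.append(float(p))
            qtl.append(role == "QTL")
    return GeneticMap(np.asarray(chrom_lengths, float), chrom, pos, qtl)


# ---------------------------------------------------------------------------
# haplotypes, individuals, pedigree
# ---------------------------------------------------------------------------

#: per-chromosome origin segments: (founder labels, right edges in cM).
#: labels[i] covers [edges[i-1] (or 0), edges[i]); edges[-1] == chromosome
#: length, so the segments partition the chromosome exactly.
Segments = list[tuple[np.ndarray, np.ndarray]]


@dataclass
class Haplotype:
    """One gametic genome: allele vector plus founder-origin segments."""

    alleles: np.ndarray          # uint8, length n_loci
    segments: Segments

    @classmethod
    def founder(cls, alleles: np.ndarray, gmap: GeneticMap, label: int) -> "Haplotype":
        segs = [(np.array([label], dtype=np.int64),
                 np.array([gmap.chrom_lengths[c]], dtype=float))
                for c in range(gmap.n_chrom)]
        return cls(np.asarray(alleles, dtype=np.uint8).copy(), segs)

    def segment_lengths(self) -> np.ndarray:
        out = []
        for labels, ends in self.segments:
            out.append(np.diff(ends, prepend=0.0))
        return np.concatenate(out)

    def founder_at(self, gmap: GeneticMap) -> np.ndarray:
        """Founder label covering each locus (for consistency checks)."""
        out = np.empty(gmap.n_loci, dtype=np.int64)
        for c in range(gmap.n_chrom):
            sl = gmap.chrom_slice(c)
            labels, ends = self.segments[c]
            idx = np.searchsorted(ends, gmap.pos[sl], side="right")
            idx = np.minimum(idx, len(labels) - 1)  # pos == chrom length
            out[sl] = labels[idx]
        return out


@dataclass
class Individual:
    id: int
    haplotypes: tuple[Haplotype, Haplotype]
    sire_id: int | None = None
    dam_id: int | None = None

    def dosage(self, loci=None) -> np.ndarray:
        """Allele-1 dosage in {0,1,2} at `loci` (all loci if None)."""
        a0, a1 = self.haplotypes[0].alleles, self.haplotypes[1].alleles
        if loci is None:
            return a0.astype(np.int16) + a1
        return a0[loci].astype(np.int16) + a1[loci]

    @property
    def is_homozygous(self) -> bool:
        return bool(np.array_equal(self.haplotypes[0].alleles,
                                   self.haplotypes[1].alleles))


class PedigreeBook:
    """Append-only pedigree registry; ids are dense integer indices.

    Base individuals (the ancestral reference base, treated as unrelated
    and non-inbred) have sire = dam = -1.  Doubled haploids are recorded
    with sire = dam = source individual and a DH flag, which the
    numerator-relationship recursion uses to set their inbreeding to 1.
    Insertion order is topological by construction.
    """

    def __init__(self):
        self.sire: list[int] = []
        self.dam: list[int] = []
        self.is_dh: list[bool] = []

    def __len__(self) -> int:
        return len(self.sire)

    @property
    def n(self) -> int:
        return len(self.sire)

    def add(self, sire: int | None = None, dam: int | None = None,
            dh: bool = False) -> int:
        s = -1 if sire is None else int(sire)
        d = -1 if dam is None else int(dam)
        new_id = len(self.sire)
        if s >= new_id or d >= new_id:
            raise ValueError("parents must be registered before offspring")
        if (s == -1) != (d == -1):
            raise ValueError("either both or neither parent must be known")
        self.sire.append(s)
        self.dam.append(d)
        self.is_dh.append(bool(dh))
        return new_id

    def add_base(self) -> int:
        return self.add(None, None)

    def arrays(self):
        return (np.asarray(self.sire, dtype=np.int64),
                np.asarray(self.dam, dtype=np.int64),
                np.asarray(self.is_dh, dtype=bool))

    def write(self, path) -> None:
        """Three-column pedigree text (id, sire, dam); 0 denotes base."""
        with open(path, "w") as fh:
            for i, (s, d) in enumerate(zip(self.sire, self.dam)):
                fh.write(f"{i + 1}\t{s + 1}\t{d + 1}\n")


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def crossover_plan(gmap: GeneticMap, rng: np.random.Generator):
    """Sample one meiosis: per chromosome, sorted breakpoints and the
    starting parental strand (0 or 1)."""
    plans = []
    for c in range(gmap.n_chrom):
        length = gmap.chrom_lengths[c]
        k = rng.poisson(length / 100.0)
        bp = np.sort(rng.random(k) * length)
        plans.append((bp, int(rng.integers(2))))
    return plans


def gamete_alleles(plan, alleles0: np.ndarray, alleles1: np.ndarray,
                   gmap: GeneticMap) -> np.ndarray:
    out = np.empty(gmap.n_loci, dtype=np.uint8)
    for c, (bp, start) in enumerate(plan):
        sl = gmap.chrom_slice(c)
        src = (start + np.searchsorted(bp, gmap.pos[sl], side="right")) % 2
        out[sl] = np.where(src == 0, alleles0[sl], alleles1[sl])
    return out


def _slice_segments(labels: np.ndarray, ends: np.ndarray,
                    a: float, b: float):
    """Sub-segments of one chromosome's segment list restricted to [a, b)."""
    if b <= a:
        return (np.empty(0, np.int64), np.empty(0, float))
    i0 = int(np.searchsorted(ends, a, side="right"))
    i1 = int(np.searchsorted(ends, b, side="left"))
    i1 = min(i1, len(labels) - 1)
    lab = labels[i0:i1 + 1].copy()
    end = ends[i0:i1 + 1].copy()
    end[-1] = b
    return lab, end


def _merge_segments(labels: np.ndarray, ends: np.ndarray):
    """Drop zero-length segments and merge adjacent same-founder runs."""
    starts = np.concatenate([[0.0], ends[:-1]])
    keep = ends > starts
    labels, ends = labels[keep], ends[keep]
    if len(labels) > 1:
        last = np.append(labels[1:] != labels[:-1], True)
        labels, ends = labels[last], ends[last]
    return labels, ends


def gamete_segments(plan, segs0: Segments, segs1: Segments,
                    gmap: GeneticMap) -> Segments:
    out: Segments = []
    parents = (segs0, segs1)
    for c, (bp, start) in enumerate(plan):
        length = gmap.chrom_lengths[c]
        cuts = np.concatenate([[0.0], bp, [length]])
        labs, ends = [], []
        for j in range(len(cuts) - 1):
            src = parents[(start + j) % 2][c]
            lab, end = _slice_segments(src[0], src[1], cuts[j], cuts[j + 1])
            labs.append(lab)
            ends.append(end)
        labels = np.concatenate(labs)
        edges = np.concatenate(ends)
        out.append(_merge_segments(labels, edges))
    return out


def meiosis(parent: Individual, gmap: GeneticMap, rng) -> Haplotype:
    """Simulate one meiosis of `parent`, returning a recombinant gamete
    with merged origin segments."""
    rng = as_rng(rng)
    plan = crossover_plan(gmap, rng)
    h0, h1 = parent.haplotypes
    alleles = gamete_alleles(plan, h0.alleles, h1.alleles, gmap)
    segments = gamete_segments(plan, h0.segments, h1.segments, gmap)
    return Haplotype(alleles, segments)


def double_haploid(gamete: Haplotype, gmap: GeneticMap, book: PedigreeBook,
                   source_id: int) -> Individual:
    """Double a gamete in silico into a fully homozygous founder line.

    The new line gets a fresh pedigree id (flagged DH, inbreeding 1) which
    also serves as its founder label for origin tracking.
    """
    new_id = book.add(source_id, source_id, dh=True)
    h0 = Haplotype.founder(gamete.alleles, gmap, new_id)
    h1 = Haplotype.founder(gamete.alleles, gmap, new_id)
    return Individual(new_id, (h0, h1), source_id, source_id)


def mate(sire: Individual, dam: Individual, gmap: GeneticMap,
         book: PedigreeBook, rng) -> Individual:
    rng = as_rng(rng)
    new_id = book.add(sire.id, dam.id)
    return Individual(new_id, (meiosis(sire, gmap, rng),
                               meiosis(dam, gmap, rng)),
                      sire.id, dam.id)


def allele1_dosage(individuals: Iterable[Individual],
                   loci=None) -> np.ndarray:
    """Stack allele-1 dosages of `individuals` into an (n, m) array."""
    return np.stack([ind.dosage(loci) for ind in individuals])
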