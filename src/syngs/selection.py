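"""The recurrent genomic selection engine.

One replicate executes the full breeding scheme: sample parents from the
ancestral population, build the synthetic(s), draw and phenotype the
training set, fit the prediction model once, then run ``n_cycles`` of
truncation selection without retraining.  In each cycle the 100
candidates are scored (EBV from the frozen cycle-0 equation, TBV, or
random scores), metrics are recorded *before* selection, the top Ns = 10
are selected and random-mated to create the next 100 candidates.

Four information-source scenarios are supported:

* ``Re-LDA-SNP`` — TS and candidates share parents; genomic kernel.
* ``Re-LEA-SNP`` — as above, but parental QTL and SNP blocks are
  reshuffled before intermating, removing ancestral QTL-SNP LD.
* ``Re-LDA-Ped`` — shared parents; pedigree numerator kernel.
* ``Un-LDA-SNP`` — TS and candidates from synthetics with disjoint
  parents; genomic kernel (ancestral LD is the only information source).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestral import AncestralPopulation
from .genome import Individual, PedigreeBook, as_rng, mate
from .metrics import (additive_variance, cumulative_gain,
                      inbreeding_and_relationship_stats, prediction_accuracy,
                      segment_length_stats)
from .prediction import (MixedModelFit, RelationshipMatrix, extend_pedigree_A,
                         fit_mixed_model, pedigree_A, predict, thin_snps,
                         vanraden_G, vanraden_cross)
from .synthetic import (build_synthetic, reshuffle_lea, sample_parents,
                        sample_ts_rsc)
from .trait import TraitCalibration, phenotype, sample_architecture, tbv

__all__ = ["ExperimentConfig", "CycleMetrics", "RepResult",
           "select", "advance_cycle", "run_replicate", "SCENARIOS", "REGIMES"]

log = logging.getLogger(__name__)

SCENARIOS = ("Re-LDA-SNP", "Re-LDA-Ped", "Re-LEA-SNP", "Un-LDA-SNP")
REGIMES = ("EBV", "TBV", "RBV")


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the simulation factor grid."""

    scenario: str = "Re-LDA-SNP"
    regime: str = "EBV"
    ancestral: str = "LR"
    n_parents: int = 4
    n_recomb_gens: int = 1
    n_ts: int = 250
    snp_density: float = 2.5           # SNPs per cM
    n_cycles: int = 30
    n_selected: int = 10
    n_candidates: int = 100
    n_qtl: int = 1000
    syn_size: int | None = None        # per-generation synthetic size
    track_pedigree_stats: bool = False

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.ancestral not in ("LR", "SR"):
            raise ValueError("ancestral must be 'LR' or 'SR'")
        if self.n_selected >= self.n_candidates:
            raise ValueError("n_selected must be below n_candidates")

    @property
    def generation_size(self) -> int:
        if self.syn_size is not None:
            return self.syn_size
        return max(self.n_ts + self.n_candidates + 50, 400)

    @property
    def uses_pedigree_kernel(self) -> bool:
        return self.scenario == "Re-LDA-Ped"

    @property
    def related(self) -> bool:
        return self.scenario != "Un-LDA-SNP"


@dataclass
class CycleMetrics:
    cycle: int
    accuracy: float                  # NaN when undefined
    cum_gain: float                  # units of sigma_A(anc)
    sigma2_A: float                  # units of sigma2_A(anc)
    mean_segment_length: float       # cM
    mean_inbreeding: float = float("nan")
    var_ts_relationship: float = float("nan")


@dataclass
class RepResult:
    config: ExperimentConfig
    seed: int
    metrics: list[CycleMetrics]
    fit: MixedModelFit

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(m) for m in self.metrics])
        df.insert(0, "seed", self.seed)
        return df


# ---------------------------------------------------------------------------
# selection primitives
# ---------------------------------------------------------------------------

def select(candidates: list[Individual], scores: np.ndarray, n_selected: int,
           rng) -> list[Individual]:
    """Truncation selection of the ``n_selected`` highest scores, ties
    broken at random.  All-equal scores (undefined ranking) degrade to
    random selection, which is logged."""
    rng = as_rng(rng)
    scores = np.asarray(scores, float)
    if len(candidates) < n_selected:
        raise ValueError("fewer candidates than selections requested")
    if len(scores) != len(candidates):
        raise ValueError("one score per candidate required")
    if np.all(scores == scores[0]):
        log.info("all scores equal; selecting at random among ties")
    tie_break = rng.permutation(len(scores))
    order = np.lexsort((tie_break, -scores))
    return [candidates[i] for i in order[:n_selected]]


def advance_cycle(selected: list[Individual], gmap, book: PedigreeBook,
                  n_offspring: int, rng) -> list[Individual]:
    """Random-mate the selected individuals (uniform pairs with
    replacement, selfing allowed) into the next candidate generation."""
    rng = as_rng(rng)
    if not selected:
        raise ValueError("no selected individuals")
    n = len(selected)
    sires = rng.integers(0, n, n_offspring)
    dams = rng.integers(0, n, n_offspring)
    return [mate(selected[s], selected[d], gmap, book, rng)
            for s, d in zip(sires, dams)]


# ---------------------------------------------------------------------------
# one full replicate
# ---------------------------------------------------------------------------

def _stage_rngs(seed: int, names: tuple[str, ...]) -> dict:
    """Independent per-stage generators derived from one root seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss)
            for name, ss in zip(names, children)}


def run_replicate(anc: AncestralPopulation, calib: TraitCalibration,
                  config: ExperimentConfig, seed: int) -> RepResult:
    """Execute one simulation replicate of the breeding scheme.

    ``anc`` must match ``config.ancestral``; its ``base`` frequencies
    (fixed from LR) drive all genotype centering.  Deterministic given
    `seed`; stage generators are split from it so stages are independent.
    """
    if anc.label != config.ancestral:
        raise ValueError(f"ancestral population is {anc.label}, "
                         f"config wants {config.ancestral}")
    rngs = _stage_rngs(seed, ("trait", "markers", "parents", "synthetic",
                              "sampling", "phenotype", "cycles"))
    gmap, base = anc.gmap, anc.base
    book = PedigreeBook()

    arch = sample_architecture(gmap, base, config.n_qtl, rngs["trait"])
    kernel_genomic = not config.uses_pedigree_kernel
    snps = (thin_snps(gmap, config.snp_density, base, rngs["markers"])
            if kernel_genomic else None)

    # --- parents and synthetics ------------------------------------------
    parents = sample_parents(anc, config.n_parents
                             * (1 if config.related else 2),
                             book, rngs["parents"])
    if config.related:
        parents1, parents2 = parents, None
    else:
        parents1, parents2 = (parents[:config.n_parents],
                              parents[config.n_parents:])
    if config.scenario == "Re-LEA-SNP":
        parents1 = reshuffle_lea(parents1, gmap, book, rngs["parents"])

    size = config.generation_size
    syn1 = build_synthetic(parents1, config.n_recomb_gens, size, gmap, book,
                           rngs["synthetic"])
    syn2 = None
    if not config.related:
        syn2 = build_synthetic(parents2, config.n_recomb_gens, size, gmap,
                               book, rngs["synthetic"])
    ts, rsc = sample_ts_rsc(syn1, syn2, config.n_ts, config.n_candidates,
                            config.related, rngs["sampling"])

    # --- model training (once) -------------------------------------------
    y_ts = phenotype(tbv(ts, arch, base), calib, rngs["phenotype"])
    n_ts = config.n_ts
    if kernel_genomic:
        X_ts = base.minor_dosage(np.stack([i.dosage(snps) for i in ts]), snps)
        X_rsc = base.minor_dosage(np.stack([i.dosage(snps) for i in rsc]), snps)
        K = vanraden_G(np.vstack([X_ts, X_rsc]), base.p[snps])
        A_full = None
    else:
        A_full = pedigree_A(book)
        idx = np.array([i.id for i in ts] + [i.id for i in rsc])
        K = RelationshipMatrix(A_full[np.ix_(idx, idx)], "pedigree")
    fit = fit_mixed_model(y_ts, K, np.arange(n_ts))

    ts_ids = np.array([i.id for i in ts])
    track = config.track_pedigree_stats
    rng_c = rngs["cycles"]
    sigma_A = calib.sigma_A_anc
    # spread below float noise of the BLUP system counts as "constant"
    acc_atol = 1e-8 * max(1.0, np.sqrt(fit.sigma2_a))

    candidates = rsc
    ebv = fit.ebv_candidates
    baseline = None
    out: list[CycleMetrics] = []
    for cycle in range(config.n_cycles + 1):
        g = tbv(candidates, arch, base)
        if baseline is None:
            baseline = float(g.mean())
        f_mean = var_rel = float("nan")
        if track or config.uses_pedigree_kernel:
            if A_full is not None and A_full.shape[0] < book.n:
                A_full = extend_pedigree_A(A_full, book)
            elif A_full is None:
                A_full = pedigree_A(book)
            if track:
                cand_ids = np.array([i.id for i in candidates])
                f_mean, var_rel = inbreeding_and_relationship_stats(
                    A_full, ts_ids, cand_ids)
        out.append(CycleMetrics(
            cycle=cycle,
            accuracy=prediction_accuracy(g, ebv, atol=acc_atol),
            cum_gain=cumulative_gain(g, baseline, sigma_A),
            sigma2_A=additive_variance(g, calib.sigma2_A_anc),
            mean_segment_length=segment_length_stats(candidates),
            mean_inbreeding=f_mean,
            var_ts_relationship=var_rel,
        ))
        if cycle == config.n_cycles:
            break

        if config.regime == "EBV":
            scores = ebv
        elif config.regime == "TBV":
            scores = g
        else:                                   # RBV
            scores = rng_c.random(len(candidates))
        chosen = select(candidates, scores, config.n_selected, rng_c)
        candidates = advance_cycle(chosen, gmap, book,
                                   config.n_candidates, rng_c)

        # score the new candidates with the frozen training equation
        if kernel_genomic:
            X_new = base.minor_dosage(
                np.stack([i.dosage(snps) for i in candidates]), snps)
            K_new_ts = vanraden_cross(X_new, X_ts, base.p[snps])
        else:
            A_full = extend_pedigree_A(A_full, book)
            cand_ids = np.array([i.id for i in candidates])
            K_new_ts = A_full[np.ix_(cand_ids, ts_ids)]
        ebv = predict(fit, K_new_ts)

    return RepResult(config, seed, out, fit)
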