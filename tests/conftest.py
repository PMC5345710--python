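"""Shared fixtures: a small map, a tiny end-to-end world for fast
pipeline tests, and the desk-scale world used by the acceptance suite.

Everything is generated programmatically; nothing is read from disk.
"""
import numpy as np
import pytest

from syngs.ancestral import AncestralParams, simulate_ancestral
from syngs.genome import Haplotype, Individual, PedigreeBook, build_map
from syngs.grid import DeskProfile, prepare_inputs
from syngs.trait import calibrate_error_variance


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_map():
    return build_map(3, 300.0, 600, n_qtl=120, seed=11)


def make_founders(gmap, n, book, rng, label_base=None):
    """Homozygous founder individuals with random alleles (test helper)."""
    out = []
    for _ in range(n):
        alleles = rng.integers(0, 2, gmap.n_loci, dtype=np.uint8)
        fid = book.add(None, None, dh=True) if label_base is None else None
        h0 = Haplotype.founder(alleles, gmap, fid)
        h1 = Haplotype.founder(alleles, gmap, fid)
        out.append(Individual(fid, (h0, h1), None, None))
    return out


TINY_PARAMS = AncestralParams(
    n_initial=60, n_equilibrium_gens=30, bottleneck_size=12,
    n_bottleneck_gens=5, expanded_size=120, n_expand_gens=2,
    n_sr_extra_gens=10)


@pytest.fixture(scope="session")
def tiny_world():
    """Very small ancestral LR + calibration for fast pipeline tests."""
    gmap = build_map(5, 500.0, 1500, n_qtl=400, seed=3)
    lr, _ = simulate_ancestral(gmap, TINY_PARAMS, seed=5, include_sr=False)
    calib = calibrate_error_variance(lr, gmap, n_reps=10,
                                     rng=np.random.default_rng(17),
                                     n_qtl=100)
    return gmap, lr, calib


@pytest.fixture(scope="session")
def desk_world():
    """Desk-scale study conditions (full 10 x 191.3 cM map, scaled
    ancestral stage) shared by the acceptance checks."""
    gmap, pops, calib = prepare_inputs(DeskProfile(), root_seed=101,
                                       include_sr=False)
    return gmap, pops["LR"], calib
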