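"""Relationship kernels and the GBLUP / pedigree-BLUP mixed model.

The prediction model is

    y_i = mu + g_i + eps_i,   (g_i) ~ MVN(0, sigma2_a K),
                              (eps_i) ~ MVN(0, sigma2_eps I),

fitted on the phenotyped training set only.  K is either the VanRaden
genomic relationship matrix built from SNP markers (QTL excluded) centered
with *ancestral* allele frequencies,

    k_ij = sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / sum_k 2 p_k (1 - p_k),

or the pedigree numerator relationship matrix computed by the tabular
method over all recorded ancestors back to the (unrelated, non-inbred)
ancestral base.

Variance components are estimated by REML using a spectral decomposition
of the training-set block of K and a one-dimensional profile likelihood
over the ratio delta = sigma2_eps / sigma2_a; breeding values of
unphenotyped candidates are obtained by covariance projection,
g_hat = K[cand, TS] alpha with alpha = (K_TT + delta I)^-1 (y - mu).
Because alpha, mu and delta are frozen at training, the same equation can
score candidates of any later selection cycle without retraining.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .ancestral import BaseFrequencies
from .genome import GeneticMap, PedigreeBook, as_rng

__all__ = [
    "RelationshipMatrix",
    "MixedModelFit",
    "vanraden_G",
    "vanraden_cross",
    "pedigree_A",
    "extend_pedigree_A",
    "fit_mixed_model",
    "predict",
    "thin_snps",
    "write_kernel",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelationshipMatrix:
    """A symmetric relationship kernel over TS followed by candidates."""

    values: np.ndarray
    kind: str                   # "genomic" | "pedigree"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def _center(X: np.ndarray, p: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) - 2.0 * np.asarray(p, dtype=float)


def _vanraden_denominator(p: np.ndarray) -> float:
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic in the base population")
    return denom


def vanraden_G(genotypes: np.ndarray, p: np.ndarray) -> RelationshipMatrix:
    """VanRaden genomic relationships from minor-allele counts.

    Parameters
    ----------
    genotypes : (n, m) array of minor-allele counts in {0, 1, 2}
    p : (m,) ancestral (base) minor-allele frequencies used for centering
        and for the denominator 2 sum p_k (1 - p_k).
    """
    Z = _center(genotypes, p)
    G = (Z @ Z.T) / _vanraden_denominator(np.asarray(p, float))
    return RelationshipMatrix((G + G.T) / 2.0, "genomic")


def vanraden_cross(genotypes_new: np.ndarray, genotypes_ref: np.ndarray,
                   p: np.ndarray) -> np.ndarray:
    """Cross-block k_ij between new individuals (rows) and reference
    individuals (columns), with the same centering and denominator as
    :func:`vanraden_G`."""
    p = np.asarray(p, float)
    return (_center(genotypes_new, p) @ _center(genotypes_ref, p).T
            ) / _vanraden_denominator(p)


def pedigree_A(book: PedigreeBook) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    Base individuals are unrelated and non-inbred (a_ii = 1); doubled
    haploids are fully inbred (a_ii = 2) and relate to others exactly as
    their gamete-source individual does.
    """
    sire, dam, is_dh = book.arrays()
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0:                          # base
            A[i, i] = 1.0
            continue
        row = 0.5 * (A[s, :i] + A[d, :i])
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 2.0 if is_dh[i] else 1.0 + 0.5 * A[s, d]
    return A


def extend_pedigree_A(A: np.ndarray, book: PedigreeBook) -> np.ndarray:
    """Grow a previously computed numerator matrix to cover newly
    registered individuals (tabular recursion on the new rows only)."""
    sire, dam, is_dh = book.arrays()
    n_old, n = A.shape[0], len(sire)
    if n == n_old:
        return A
    out = np.zeros((n, n))
    out[:n_old, :n_old] = A
    for i in range(n_old, n):
        s, d = sire[i], dam[i]
        if s < 0:
            out[i, i] = 1.0
            continue
        row = 0.5 * (out[s, :i] + out[d, :i])
        out[i, :i] = row
        out[:i, i] = row
        out[i, i] = 2.0 if is_dh[i] else 1.0 + 0.5 * out[s, d]
    return out


def thin_snps(gmap: GeneticMap, density: float, base: BaseFrequencies,
              rng, mode: str = "random") -> np.ndarray:
    """Sample a marker panel of ``round(density * total_length)`` SNPs.

    Candidates are non-QTL-pool loci polymorphic in the ancestral base;
    QTL never enter the panel.  ``mode='random'`` samples uniformly (the
    default); ``mode='equidistant'`` takes evenly spaced candidates for
    sensitivity checks.
    """
    rng = as_rng(rng)
    # round half up, so density 2.5 on 1913 cM gives 4783 markers
    n_target = int(np.floor(density * gmap.total_length + 0.5))
    poly = (base.p > 0) & (base.p < 1)
    pool = np.flatnonzero(~gmap.is_qtl & poly)
    if len(pool) < n_target:
        raise ValueError(f"only {len(pool)} polymorphic SNPs available, "
                         f"need {n_target}")
    if mode == "random":
        return np.sort(rng.choice(pool, n_target, replace=False))
    if mode == "equidistant":
        take = np.linspace(0, len(pool) - 1, n_target).round().astype(int)
        return pool[take]
    raise ValueError(f"unknown thinning mode {mode!r}")


def write_kernel(K: RelationshipMatrix, ids, path) -> None:
    """Whitespace-delimited square text with an id header row/column."""
    ids = list(ids)
    with open(path, "w") as fh:
        fh.write("id " + " ".join(str(i) for i in ids) + "\n")
        for i, row in zip(ids, K.values):
            fh.write(str(i) + " " + " ".join(f"{v:.10g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    """A fitted GBLUP / pedigree-BLUP equation, reusable across cycles."""

    mu: float
    sigma2_a: float
    sigma2_eps: float
    delta: float                    # sigma2_eps / sigma2_a
    alpha: np.ndarray               # (n_ts,) solution (K_TT + delta I)^-1 (y - mu)
    ebv: np.ndarray                 # breeding values for all rows of K
    n_ts: int
    reml_neg2loglik: float

    @property
    def ebv_ts(self) -> np.ndarray:
        return self.ebv[:self.n_ts]

    @property
    def ebv_candidates(self) -> np.ndarray:
        return self.ebv[self.n_ts:]


_DELTA_LOG_BOUNDS = (np.log(1e-9), np.log(1e9))


def _spectral_reml(y: np.ndarray, s: np.ndarray, U: np.ndarray):
    """Profile REML over log(delta) for y = 1 mu + g + eps on the
    eigendecomposition K_TT = U diag(s) U'."""
    n = len(y)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg2reml(log_delta: float) -> float:
        d = s + np.exp(log_delta)
        xvx = np.sum(xt * xt / d)
        beta = np.sum(xt * yt / d) / xvx
        resid2 = np.sum((yt - xt * beta) ** 2 / d)
        return ((n - 1) * np.log(resid2) + np.sum(np.log(d)) + np.log(xvx))

    res = minimize_scalar(neg2reml, bounds=_DELTA_LOG_BOUNDS,
                          method="bounded",
                          options={"xatol": 1e-10, "maxiter": 500})
    if not res.success:
        raise RuntimeError(f"REML did not converge: {res.message}")
    delta = float(np.exp(res.x))
    d = s + delta
    xvx = np.sum(xt * xt / d)
    beta = float(np.sum(xt * yt / d) / xvx)
    resid_t = yt - xt * beta
    sigma2_a = float(np.sum(resid_t ** 2 / d) / (n - 1))
    alpha = U @ (resid_t / d)
    return beta, sigma2_a, delta, alpha, float(res.fun)


def fit_mixed_model(y_ts: np.ndarray, K: RelationshipMatrix,
                    ts_index=None) -> MixedModelFit:
    """Fit the mixed model on the phenotyped training set and predict
    breeding values for every individual covered by ``K``.

    ``ts_index`` gives the rows of K corresponding to the training set
    (default: the first ``len(y_ts)`` rows).  Candidate phenotypes are
    never used.
    """
    y = np.asarray(y_ts, dtype=float)
    n = len(y)
    if ts_index is None:
        ts_index = np.arange(n)
    ts_index = np.asarray(ts_index)
    if len(ts_index) != n:
        raise ValueError("ts_index length must match y_ts")
    Kfull = K.values
    Ktt = Kfull[np.ix_(ts_index, ts_index)]

    s, U = np.linalg.eigh(Ktt)
    tol = 1e-8 * max(np.trace(Ktt) / n, 1.0)
    if s.min() < -tol:
        # one round of numerical PSD repair
        jitter = 1e-8 * np.trace(Ktt) / n
        log.warning("kernel not PSD (min eig %.3g); adding jitter %.3g",
                    s.min(), jitter)
        s = s + jitter
        if s.min() < -tol:
            raise ValueError("kernel not positive semi-definite after jitter")
    s = np.clip(s, 0.0, None)

    mu, sigma2_a, delta, alpha, crit = _spectral_reml(y, s, U)
    ebv = Kfull[:, ts_index] @ alpha
    return MixedModelFit(mu, sigma2_a, sigma2_a * delta, delta, alpha,
                         ebv, n, crit)


def predict(fit: MixedModelFit, K_new_ts: np.ndarray) -> np.ndarray:
    """Score new candidates with the frozen training-generation equation:
    g_hat = K[new, TS] alpha."""
    return np.asarray(K_new_ts, dtype=float) @ fit.alpha
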