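"""Per-cycle metrics and across-replicate summaries.

Prediction accuracy is the Pearson correlation between true and predicted
breeding values of the selection candidates; it is undefined (NaN, never
zero) when either vector is constant.  Cumulative gain is the shift of
the mean candidate TBV relative to cycle 0 in units of the ancestral
additive standard deviation; the additive variance is the sample variance
of candidate TBVs in units of the ancestral additive variance.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import Individual

__all__ = [
    "prediction_accuracy",
    "cumulative_gain",
    "additive_variance",
    "segment_length_stats",
    "inbreeding_and_relationship_stats",
    "summarize_replicates",
]


def prediction_accuracy(tbv: np.ndarray, ebv: np.ndarray,
                        atol: float = 0.0) -> float:
    """Pearson r between TBV and EBV; NaN when undefined.

    With fewer than three candidates a correlation is meaningless and an
    error is raised.  A constant vector (e.g. identical pedigree EBVs of
    all full sibs) yields NaN, which aggregation treats as missing.
    ``atol`` declares a vector constant when its standard deviation does
    not exceed it: EBVs that are equal in exact arithmetic (identical
    kernel rows) still carry float-level noise, and a correlation of that
    noise would be spurious.
    """
    g = np.asarray(tbv, float)
    e = np.asarray(ebv, float)
    if g.shape != e.shape:
        raise ValueError("TBV and EBV must have equal length")
    if len(g) < 3:
        raise ValueError("need at least three candidates")
    if g.std() <= atol or e.std() <= atol:
        return float("nan")
    return float(np.corrcoef(g, e)[0, 1])


def cumulative_gain(tbv_c: np.ndarray, baseline_mean: float,
                    sigma_A_anc: float) -> float:
    """(mean TBV at cycle C - mean at cycle 0) / sigma_A(anc)."""
    if sigma_A_anc <= 0:
        raise ValueError("sigma_A_anc must be positive")
    return float((np.mean(tbv_c) - baseline_mean) / sigma_A_anc)


def additive_variance(tbv_c: np.ndarray, sigma2_A_anc: float) -> float:
    """Sample (n-1) variance of candidate TBVs / sigma2_A(anc)."""
    if sigma2_A_anc <= 0:
        raise ValueError("sigma2_A_anc must be positive")
    tbv_c = np.asarray(tbv_c, float)
    if len(tbv_c) < 2:
        raise ValueError("need at least two candidates")
    return float(tbv_c.var(ddof=1) / sigma2_A_anc)


def segment_length_stats(individuals: list[Individual]) -> float:
    """Mean cM length of chromosomal segments of unique parental origin.

    Adjacent same-founder segments are merged at gamete creation, so this
    is the plain mean over all segments of all haplotypes.
    """
    lengths = [h.segment_lengths()
               for ind in individuals for h in ind.haplotypes]
    return float(np.concatenate(lengths).mean())


def inbreeding_and_relationship_stats(A: np.ndarray, ts_idx, rsc_idx
                                      ) -> tuple[float, float]:
    """(mean inbreeding of candidates, variance of TS-candidate
    relationships) from a numerator relationship matrix."""
    ts_idx = np.asarray(ts_idx)
    rsc_idx = np.asarray(rsc_idx)
    f_mean = float(np.mean(np.diag(A)[rsc_idx] - 1.0))
    cross = A[np.ix_(ts_idx, rsc_idx)]
    return f_mean, float(cross.var(ddof=1))


def summarize_replicates(df: pd.DataFrame,
                         group_cols=("cycle",),
                         value_cols=("accuracy", "cum_gain", "sigma2_A"),
                         ) -> pd.DataFrame:
    """Across-replicate mean, MC standard error and defined-value count
    per cycle (NaN values, e.g. undefined accuracies, are excluded from
    means and counted separately)."""
    group_cols = list(group_cols)
    rows = []
    for key, sub in df.groupby(group_cols):
        key = key if isinstance(key, tuple) else (key,)
        for col in value_cols:
            v = sub[col].to_numpy(float)
            defined = v[~np.isnan(v)]
            n = len(defined)
            rows.append(dict(zip(group_cols, key)) | {
                "metric": col,
                "mean": defined.mean() if n else np.nan,
                "se": defined.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n_defined": n,
                "n_undefined": int(len(v) - n),
            })
    return pd.DataFrame(rows)
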