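"""Cross-class Pearson co-expression screening with exact t-based p-values.

Pairs are screened between RNA classes (miRNA-mRNA, miRNA-circRNA,
circRNA-mRNA) across all samples pooled; with the 3 + 3 two-breed design
this gives n = 6 and t-tests on 4 degrees of freedom.  The sponge premise
fixes the expected signs: miRNA-target pairs are kept when strongly
negative, circRNA-mRNA (the ceRNA pair) when strongly positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

PAIR_KINDS = ("miRNA_mRNA", "miRNA_circRNA", "circRNA_mRNA")


@dataclass
class CorrelatedPair:
    id_a: str
    id_b: str
    pair_kind: str
    r: float
    n: int
    p: float


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length sample vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt((xd * xd).sum())
    sy = np.sqrt((yd * yd).sum())
    if sx == 0 or sy == 0:
        raise ZeroDivisionError("constant vector: correlation undefined")
    return float((xd * yd).sum() / (sx * sy))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a sample correlation: t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"invalid correlation {r}")
    if abs(r) == 1.0:
        return 0.0  # degenerate: perfectly collinear
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


def correlate_pairs(
    mat_a: ExpressionMatrix,
    mat_b: ExpressionMatrix,
    pair_kind: str,
    sign: str,
    r_min: float = 0.8,
    p_max: float = 0.05,
    features_a: list[str] | None = None,
    features_b: list[str] | None = None,
) -> list[CorrelatedPair]:
    """All cross-class pairs with the requested sign, |r| >= r_min and p < p_max.

    Matrices are aligned by sample id (mismatched sample sets are an error).
    Zero-variance features are excluded from screening and counted in the log.
    Output order: p ascending, then |r| descending, then ids.
    """
    if pair_kind not in PAIR_KINDS:
        raise ValueError(f"unknown pair kind {pair_kind!r}")
    if sign not in ("negative", "positive"):
        raise ValueError(f"sign must be negative or positive, got {sign!r}")
    if set(mat_a.sample_ids) != set(mat_b.sample_ids):
        raise ValueError("sample sets differ between matrices")
    samples = mat_a.sample_ids
    va = mat_a.values.loc[features_a if features_a is not None else mat_a.feature_ids, samples]
    vb = mat_b.values.loc[features_b if features_b is not None else mat_b.feature_ids, samples]

    n = len(samples)
    a = va.to_numpy(dtype=float)
    b = vb.to_numpy(dtype=float)
    a_sd = a.std(axis=1)
    b_sd = b.std(axis=1)
    skip_a, skip_b = int((a_sd == 0).sum()), int((b_sd == 0).sum())
    if skip_a or skip_b:
        logger.info("excluded zero-variance features: %d (A), %d (B)", skip_a, skip_b)
    a = a[a_sd > 0]
    ids_a = list(va.index[a_sd > 0])
    b = b[b_sd > 0]
    ids_b = list(vb.index[b_sd > 0])
    if not len(a) or not len(b):
        return []

    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    rmat = np.clip(az @ bz.T / n, -1.0, 1.0)

    pairs = []
    for i, ia in enumerate(ids_a):
        for j, ib in enumerate(ids_b):
            r = float(rmat[i, j])
            if sign == "negative" and r > -r_min:
                continue
            if sign == "positive" and r < r_min:
                continue
            p = correlation_pvalue(r, n)
            if p < p_max:
                pairs.append(CorrelatedPair(ia, ib, pair_kind, r, n, p))
    pairs.sort(key=lambda q: (q.p, -abs(q.r), q.id_a, q.id_b))
    return pairs


def write_pairs_tsv(pairs: list[CorrelatedPair], path: str) -> None:
    df = pd.DataFrame(
        [
            {"kind": q.pair_kind, "id_a": q.id_a, "id_b": q.id_b,
             "r": q.r, "n": q.n, "p": q.p}
            for q in pairs
        ],
        columns=["kind", "id_a", "id_b", "r", "n", "p"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
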