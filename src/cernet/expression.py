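"""Count normalization and differential-expression filtering.

Counts are library-size normalized (RPM/CPM for junction or small-RNA
counts, FPKM when feature lengths are known).  The DE statistic is Welch's
t on log2(normalized + pseudocount); this is deliberately simple — it is the
threshold logic (|log2FC| and p cutoffs, BH adjustment) that downstream
stages consume, and the module boundary allows swapping in an exact
negative-binomial test without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Features x samples values plus the sample -> group design."""

    values: pd.DataFrame  # rows: feature ids, columns: sample ids
    design: dict[str, str]  # sample id -> group label
    feature_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate feature or sample labels")
        missing = set(self.values.columns) - set(self.design)
        if missing:
            raise ValueError(f"design missing samples: {sorted(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            g = self.design[s]
            if g not in seen:
                seen.append(g)
        return seen

    @classmethod
    def from_tsv(cls, counts_path: str, design_path: str,
                 feature_lengths: dict[str, int] | None = None) -> "ExpressionMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        design_df = pd.read_csv(design_path, sep="\t")
        design = dict(zip(design_df["sample"], design_df["group"]))
        return cls(values, design, feature_lengths)

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class DEResult:
    feature_id: str
    log2fc: float
    p: float
    padj: float
    direction: str  # up / down / ns


def normalize(matrix: ExpressionMatrix, method: str = "CPM") -> ExpressionMatrix:
    """RPM/CPM: count * 1e6 / library size; FPKM additionally / (length/1e3)."""
    method = method.upper()
    if method not in ("RPM", "CPM", "FPKM"):
        raise ValueError(f"unknown normalization method {method!r}")
    libsize = matrix.values.sum(axis=0)
    if (libsize == 0).any():
        bad = list(libsize.index[libsize == 0])
        raise ValueError(f"zero library size for samples {bad}")
    scaled = matrix.values * 1e6 / libsize
    if method == "FPKM":
        if not matrix.feature_lengths:
            raise ValueError("FPKM requires feature_lengths")
        lens = pd.Series(
            {f: matrix.feature_lengths[f] for f in matrix.feature_ids}, dtype=float
        )
        if (lens <= 0).any():
            raise ValueError("FPKM requires positive feature lengths")
        scaled = scaled.mul(1e3 / lens, axis=0)
    return replace(matrix, values=scaled)


def de_test(
    matrix: ExpressionMatrix,
    pseudocount: float = 1.0,
    lfc_min: float = 1.0,
    p_max: float = 0.05,
    use_padj: bool = False,
    groups: tuple[str, str] | None = None,
) -> list[DEResult]:
    """Welch t on log2(value + pseudocount), group1 vs group2, BH-adjusted.

    log2fc is the mean difference of the transformed values (group1 − group2);
    reversing the contrast order negates every log2fc and leaves p unchanged.
    Features with no variation in either group get p = 1 when the means agree.
    """
    groups = list(groups) if groups is not None else matrix.groups()
    if len(groups) != 2 or set(groups) != set(matrix.design.values()):
        raise ValueError(f"need exactly the 2 design groups, got {groups}")
    g1 = [s for s in matrix.sample_ids if matrix.design[s] == groups[0]]
    g2 = [s for s in matrix.sample_ids if matrix.design[s] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 samples")

    log_vals = np.log2(matrix.values.to_numpy(dtype=float) + pseudocount)
    i1 = [matrix.sample_ids.index(s) for s in g1]
    i2 = [matrix.sample_ids.index(s) for s in g2]
    a, b = log_vals[:, i1], log_vals[:, i2]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), np.where(np.isclose(lfc, 0.0), 1.0, 0.0), p)
    padj = multipletests(p, method="fdr_bh")[1]

    results = []
    for fid, l, pv, pa in zip(matrix.feature_ids, lfc, p, padj):
        crit = pa if use_padj else pv
        if abs(l) >= lfc_min and crit < p_max:
            direction = "up" if l > 0 else "down"
        else:
            direction = "ns"
        results.append(DEResult(fid, float(l), float(pv), float(pa), direction))
    return results


def filter_de(
    results: list[DEResult],
    lfc_min: float = 1.0,
    p_max: float = 0.05,
    use_padj: bool = False,
) -> dict[str, str]:
    """Features passing |log2fc| >= lfc_min and (p or padj) < p_max, with direction."""
    out: dict[str, str] = {}
    for r in results:
        crit = r.padj if use_padj else r.p
        if abs(r.log2fc) >= lfc_min and crit < p_max:
            out[r.feature_id] = "up" if r.log2fc > 0 else "down"
    return out


def write_de_tsv(results: list[DEResult], path: str) -> None:
    df = pd.DataFrame([r.__dict__ for r in results])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def directions_from_results(results: list[DEResult]) -> Mapping[str, str]:
    return {r.feature_id: r.direction for r in results}
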