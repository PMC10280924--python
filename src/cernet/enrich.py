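"""Over-representation analysis of a feature set against term annotations.

One-sided Fisher exact test (equivalently the hypergeometric upper tail) on
the 2x2 table of query/background membership per term, BH-adjusted across
tested terms.  Annotations are plain feature -> term mappings (GO or
pathway style); no DAG propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cerna import hypergeom_tail

NAMESPACES = ("BP", "CC", "MF", "pathway")


@dataclass
class TermAnnotation:
    term_id: str
    term_name: str
    namespace: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.term_id}: empty member set")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"{self.term_id}: unknown namespace {self.namespace!r}")


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    k: int  # hits in query
    n: int  # query size
    K: int  # term size within background
    N: int  # background size
    p: float
    fdr: float


def bh_adjust(pvalues: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving with input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_terms(
    query: set[str] | frozenset[str],
    background: set[str] | frozenset[str],
    annotations: list[TermAnnotation],
) -> list[EnrichmentResult]:
    """One result per term with >= 1 query hit, Fisher p ascending.

    Term memberships are restricted to the background before testing; the
    query must be a subset of the background.
    """
    query = frozenset(query)
    background = frozenset(background)
    if not query <= background:
        raise ValueError(f"query not subset of background: {sorted(query - background)[:5]}")
    N, n = len(background), len(query)
    tested = []
    for term in annotations:
        members = term.members & background
        k = len(members & query)
        if k == 0 or not members:
            continue
        p = hypergeom_tail(N, len(members), n, k)
        tested.append((term, k, len(members), p))
    fdr = bh_adjust([t[3] for t in tested])
    results = [
        EnrichmentResult(term.term_id, term.term_name, term.namespace,
                         k, n, K, N, p, float(q))
        for (term, k, K, p), q in zip(tested, fdr)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def read_annotations(mapping_path: str, terms_path: str | None = None) -> list[TermAnnotation]:
    """Read a (feature, term) mapping TSV plus an optional term-description TSV
    with columns term_id, term_name, namespace."""
    mapping = pd.read_csv(mapping_path, sep="\t", names=["feature", "term"],
                          header=0 if _has_header(mapping_path) else None)
    meta: dict[str, tuple[str, str]] = {}
    if terms_path:
        tdf = pd.read_csv(terms_path, sep="\t")
        meta = {r.term_id: (r.term_name, r.namespace) for r in tdf.itertuples(index=False)}
    out = []
    for term_id, grp in mapping.groupby("term"):
        name, ns = meta.get(term_id, (str(term_id), "pathway"))
        out.append(TermAnnotation(str(term_id), name, ns, frozenset(grp["feature"])))
    out.sort(key=lambda t: t.term_id)
    return out


def _has_header(path: str) -> bool:
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    return first[:2] == ["feature", "term"]


def write_enrichment_tsv(results: list[EnrichmentResult], path: str) -> None:
    pd.DataFrame([r.__dict__ for r in results],
                 columns=["term_id", "term_name", "namespace",
                          "k", "n", "K", "N", "p", "fdr"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
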