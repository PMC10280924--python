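"""End-to-end orchestration: classify, normalize/DE, correlate, bind, score,
intersect, assemble and (optionally) enrich.

Mirrors the evidence funnel of a sponge screen: differential expression
first restricts each RNA class, correlation screens fix the expected signs,
sequence-level MRE prediction validates each correlated miRNA-target pair,
the hypergeometric shared-miRNA score ranks circRNA-mRNA pairs, and
positive co-expression intersects that ranking before direction-coherent
triplets are assembled.  Every stage logs before/after counts into the run
manifest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Any

from . import annotation as ann
from . import binding, cerna, correlation, enrich, expression
from .simulate import FixtureBundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineThresholds:
    """All filter settings applied between stages; serialized into manifests."""

    r_min: float = 0.8
    corr_p_max: float = 0.05
    de_lfc_min: float = 1.0      # mRNA: |log2FC| >= 1
    de_fc_min: float = 2.0       # circRNA / miRNA: fold change > 2
    de_p_max: float = 0.05
    de_use_padj: bool = False
    pseudocount: float = 1.0
    cerna_alpha: float = 1.0     # 1.0 scores every shared pair (no cutoff)
    top_k: int = 50
    top_coexpr_export: int = 200
    normalization: str = "CPM"
    corr_log2: bool = True       # correlate log2(normalized + 1), not raw values

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= 1:
            raise ValueError("r_min must lie in (0, 1]")
        for name in ("corr_p_max", "de_p_max", "cerna_alpha"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.de_fc_min < 1 or self.de_lfc_min < 0:
            raise ValueError("fold-change thresholds out of range")


@dataclass
class PipelineResult:
    classified: list[ann.CircRNARecord]
    de_results: dict[str, list[expression.DEResult]]
    de_features: dict[str, dict[str, str]]  # class -> feature -> direction
    mirna_mrna_pairs: list[correlation.CorrelatedPair]
    mirna_circ_pairs: list[correlation.CorrelatedPair]
    circ_mrna_pairs: list[correlation.CorrelatedPair]
    mirna_mrna_bound: list[binding.BindingSummary]
    mirna_circ_bound: list[binding.BindingSummary]
    score_pairs: list[cerna.CeRNAPair]
    final_pairs: list[cerna.CeRNAPair]
    network: cerna.CeRNANetwork
    enrichment: list[enrich.EnrichmentResult] = field(default_factory=list)
    funnel: dict[str, Any] = field(default_factory=dict)


def run_pipeline(
    bundle: FixtureBundle,
    thresholds: PipelineThresholds | None = None,
) -> PipelineResult:
    """Run every stage on an in-memory bundle and return all intermediates."""
    th = thresholds or PipelineThresholds()
    funnel: dict[str, Any] = {"thresholds": asdict(th)}

    classified = ann.classify_all(bundle.circrnas, bundle.annotation)
    funnel["circrnas_classified"] = len(classified)

    lfc_small = math.log2(th.de_fc_min)
    de_results: dict[str, list[expression.DEResult]] = {}
    de_features: dict[str, dict[str, str]] = {}
    norm: dict[str, expression.ExpressionMatrix] = {}
    for cls, mat, lfc_min in (
        ("mRNA", bundle.mrna_counts, th.de_lfc_min),
        ("miRNA", bundle.mirna_counts, lfc_small),
        ("circRNA", bundle.circ_counts, lfc_small),
    ):
        nm = expression.normalize(mat, th.normalization)
        norm[cls] = nm
        res = expression.de_test(nm, th.pseudocount, lfc_min, th.de_p_max, th.de_use_padj)
        de_results[cls] = res
        de_features[cls] = expression.filter_de(res, lfc_min, th.de_p_max, th.de_use_padj)
        funnel[f"de_{cls}"] = len(de_features[cls])
        logger.info("DE %s: %d / %d", cls, len(de_features[cls]), len(res))

    de_mirnas = sorted(de_features["miRNA"])
    de_mrnas = sorted(de_features["mRNA"])
    de_circs = sorted(de_features["circRNA"])

    if th.corr_log2:
        import numpy as np
        from dataclasses import replace

        corr_mats = {
            cls: replace(m, values=np.log2(m.values + 1.0)) for cls, m in norm.items()
        }
    else:
        corr_mats = norm
    mm = correlation.correlate_pairs(
        corr_mats["miRNA"], corr_mats["mRNA"], "miRNA_mRNA", "negative",
        th.r_min, th.corr_p_max, de_mirnas, de_mrnas,
    )
    mc = correlation.correlate_pairs(
        corr_mats["miRNA"], corr_mats["circRNA"], "miRNA_circRNA", "negative",
        th.r_min, th.corr_p_max, de_mirnas, de_circs,
    )
    cg = correlation.correlate_pairs(
        corr_mats["circRNA"], corr_mats["mRNA"], "circRNA_mRNA", "positive",
        th.r_min, th.corr_p_max, de_circs, de_mrnas,
    )
    funnel["corr_miRNA_mRNA"] = len(mm)
    funnel["corr_miRNA_circRNA"] = len(mc)
    funnel["corr_circRNA_mRNA"] = len(cg)

    mm_bound = binding.scan_pairs(
        bundle.mirna_seqs, bundle.target_seqs, [(q.id_a, q.id_b) for q in mm]
    )
    mc_bound = binding.scan_pairs(
        bundle.mirna_seqs, bundle.target_seqs, [(q.id_a, q.id_b) for q in mc]
    )
    funnel["bound_miRNA_mRNA"] = len(mm_bound)
    funnel["bound_miRNA_circRNA"] = len(mc_bound)
    logger.info("binding: miRNA-mRNA %d -> %d, miRNA-circRNA %d -> %d",
                len(mm), len(mm_bound), len(mc), len(mc_bound))

    circ_targets: dict[str, set[str]] = {}
    for s in mc_bound:
        circ_targets.setdefault(s.target_id, set()).add(s.mirna_id)
    mrna_targets: dict[str, set[str]] = {}
    for s in mm_bound:
        mrna_targets.setdefault(s.target_id, set()).add(s.mirna_id)
    universe = set(de_mirnas)

    score_pairs = cerna.cerna_score(circ_targets, mrna_targets, universe, th.cerna_alpha)
    funnel["cerna_scored"] = len(score_pairs)

    coexpr = {(q.id_a, q.id_b): (q.r, q.p) for q in cg}
    final_pairs = cerna.intersect_evidence(score_pairs, coexpr, th.top_k)
    funnel["cerna_final"] = len(final_pairs)

    directions: dict[str, str] = {}
    for cls in de_results:
        directions.update(expression.directions_from_results(de_results[cls]))
    network = cerna.build_cernet(
        final_pairs,
        {(s.mirna_id, s.target_id) for s in mc_bound},
        {(s.mirna_id, s.target_id) for s in mm_bound},
        directions,
    )
    funnel["triplets"] = len(network.triplets)
    funnel["network_nodes"] = network.graph.number_of_nodes()
    funnel["network_edges"] = network.graph.number_of_edges()
    logger.info("network: %d triplets, %d nodes, %d edges",
                len(network.triplets), network.graph.number_of_nodes(),
                network.graph.number_of_edges())

    enrichment: list[enrich.EnrichmentResult] = []
    if bundle.term_mapping:
        net_mrnas = {
            n for n in network.graph.nodes
            if network.graph.nodes[n]["node_type"] == "mRNA"
        }
        if net_mrnas:
            terms: dict[str, set[str]] = {}
            for feat, term in bundle.term_mapping:
                terms.setdefault(term, set()).add(feat)
            anns = [
                enrich.TermAnnotation(t, t, t.split(":")[1] if ":" in t else "pathway",
                                      frozenset(members))
                for t, members in sorted(terms.items())
            ]
            background = frozenset(bundle.mrna_counts.feature_ids)
            enrichment = enrich.enrich_terms(net_mrnas & background, background, anns)
    funnel["enriched_terms"] = len(enrichment)

    return PipelineResult(
        classified, de_results, de_features, mm, mc, cg, mm_bound, mc_bound,
        score_pairs, final_pairs, network, enrichment, funnel,
    )


def triplet_recovery(
    result: PipelineResult, truth_triplets: list[tuple[str, str, str]]
) -> tuple[float, float]:
    """(recall, precision) of recovered triplets against the planted truth."""
    found = set(result.network.triplets)
    truth = set(tuple(t) for t in truth_triplets)
    if not truth:
        return float("nan"), float("nan")
    tp = len(found & truth)
    recall = tp / len(truth)
    precision = tp / len(found) if found else 1.0
    return recall, precision
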