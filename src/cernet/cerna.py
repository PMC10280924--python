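"""Shared-miRNA ceRNA scoring, evidence intersection and network assembly.

Two transcripts compete for a miRNA pool when the overlap of their
targeting-miRNA sets is larger than chance.  For a circRNA targeted by K of
the N candidate miRNAs and an mRNA targeted by M of them, sharing x, the
ceRNA score is the hypergeometric upper tail

    p = sum_{i=x}^{min(K,M)} C(K, i) C(N-K, M-i) / C(N, M),

inclusive of the observed overlap; smaller p means a less likely shared
miRNA repertoire under random targeting.  Scored pairs are intersected with
positively co-expressed circRNA-mRNA pairs, and triplets (circRNA, miRNA,
mRNA) are assembled when all three supporting edges exist and the miRNA's
differential-expression direction opposes both partners' (the sponge
direction-coherence rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats


@dataclass
class CeRNAPair:
    circ_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    universe_size: int       # N
    circ_targeting_count: int  # K
    mrna_targeting_count: int  # M
    shared_count: int          # x
    score_p: float
    significant: bool = False
    coexpr_r: float | None = None
    coexpr_p: float | None = None


@dataclass
class CeRNANetwork:
    graph: nx.Graph = field(default_factory=nx.Graph)
    triplets: list[tuple[str, str, str]] = field(default_factory=list)  # (circ, miR, mRNA)


def hypergeom_tail(N: int, K: int, M: int, x: int) -> float:
    """Upper-tail P(X >= x) for X ~ Hypergeom(N, K, M), inclusive of x."""
    if not (0 <= K <= N and 0 <= M <= N):
        raise ValueError(f"inconsistent arguments N={N}, K={K}, M={M}")
    if not 0 <= x <= min(K, M):
        raise ValueError(f"x={x} outside [0, min(K, M)={min(K, M)}]")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, M))


def cerna_score(
    circ_targets: Mapping[str, set[str] | frozenset[str]],
    mrna_targets: Mapping[str, set[str] | frozenset[str]],
    universe: set[str] | frozenset[str],
    alpha: float = 1.0,
) -> list[CeRNAPair]:
    """One scored pair per (circRNA, mRNA) sharing at least one targeting miRNA.

    ``universe`` is the candidate miRNA set the targeting maps were drawn
    from (by default the screened miRNAs entering pair prediction).  Pairs
    with score_p < alpha are flagged significant; alpha = 1 disables the
    cutoff.  Output order: score_p ascending, then ids.
    """
    universe = frozenset(universe)
    for name, targets in (("circ", circ_targets), ("mrna", mrna_targets)):
        for tid, mirnas in targets.items():
            extra = set(mirnas) - universe
            if extra:
                raise ValueError(f"{name} {tid}: miRNAs outside universe: {sorted(extra)}")
    N = len(universe)
    pairs = []
    for circ_id in sorted(circ_targets):
        cm = frozenset(circ_targets[circ_id])
        for mrna_id in sorted(mrna_targets):
            gm = frozenset(mrna_targets[mrna_id])
            shared = cm & gm
            if not shared:
                continue
            p = hypergeom_tail(N, len(cm), len(gm), len(shared))
            pairs.append(
                CeRNAPair(
                    circ_id, mrna_id, shared, N, len(cm), len(gm), len(shared),
                    p, significant=p < alpha,
                )
            )
    pairs.sort(key=lambda q: (q.score_p, q.circ_id, q.mrna_id))
    return pairs


def intersect_evidence(
    score_pairs: Sequence[CeRNAPair],
    positive_coexpr_pairs: Mapping[tuple[str, str], tuple[float, float]],
    top_k: int | None = 50,
) -> list[CeRNAPair]:
    """Keep scored pairs that are also positively co-expressed; rank and truncate.

    ``positive_coexpr_pairs`` maps (circ_id, mrna_id) -> (r, p) from the
    positive circRNA-mRNA correlation screen.  Survivors are ranked by
    score_p ascending (ties by ids) and truncated to the top_k strongest.
    """
    merged = []
    for q in score_pairs:
        key = (q.circ_id, q.mrna_id)
        if key in positive_coexpr_pairs:
            r, p = positive_coexpr_pairs[key]
            merged.append(
                CeRNAPair(
                    q.circ_id, q.mrna_id, q.shared_mirnas, q.universe_size,
                    q.circ_targeting_count, q.mrna_targeting_count, q.shared_count,
                    q.score_p, q.significant, coexpr_r=r, coexpr_p=p,
                )
            )
    merged.sort(key=lambda q: (q.score_p, q.circ_id, q.mrna_id))
    return merged if top_k is None else merged[:top_k]


def build_cernet(
    final_pairs: Sequence[CeRNAPair],
    mirna_circ_pairs: set[tuple[str, str]],
    mirna_mrna_pairs: set[tuple[str, str]],
    de_directions: Mapping[str, str],
) -> CeRNANetwork:
    """Assemble direction-coherent (circRNA, miRNA, mRNA) triplets.

    A triplet is included iff its circRNA-mRNA pair survived the evidence
    intersection, the miRNA supports both partners ((miR, circ) and
    (miR, mRNA) screened pairs), and the miRNA's DE direction is opposite to
    both partners' (up vs down).
    """
    _OPP = {"up": "down", "down": "up"}
    net = CeRNANetwork()
    for q in final_pairs:
        for mid in sorted(q.shared_mirnas):
            if (mid, q.circ_id) not in mirna_circ_pairs:
                continue
            if (mid, q.mrna_id) not in mirna_mrna_pairs:
                continue
            for fid in (q.circ_id, mid, q.mrna_id):
                if fid not in de_directions:
                    raise ValueError(f"missing DE direction for {fid}")
            dm = de_directions[mid]
            dc = de_directions[q.circ_id]
            dg = de_directions[q.mrna_id]
            if dm not in _OPP or dc != _OPP[dm] or dg != _OPP[dm]:
                continue
            net.graph.add_node(q.circ_id, node_type="circRNA", direction=dc)
            net.graph.add_node(mid, node_type="miRNA", direction=dm)
            net.graph.add_node(q.mrna_id, node_type="mRNA", direction=dg)
            net.graph.add_edge(q.circ_id, mid, relation="sponges")
            net.graph.add_edge(mid, q.mrna_id, relation="targets")
            net.graph.add_edge(q.circ_id, q.mrna_id, relation="cerna")
            triplet = (q.circ_id, mid, q.mrna_id)
            if triplet not in net.triplets:
                net.triplets.append(triplet)
    net.triplets.sort()
    return net


def export_network(network: CeRNANetwork, out_prefix: str) -> dict[str, str]:
    """Write the network as SIF plus node/edge TSVs with deterministic ordering."""
    g = network.graph
    sif_path = f"{out_prefix}.sif"
    edge_path = f"{out_prefix}_edges.tsv"
    node_path = f"{out_prefix}_nodes.tsv"

    edges = sorted(
        (min(u, v), g.edges[u, v]["relation"], max(u, v)) for u, v in g.edges
    )
    with open(sif_path, "w") as fh:
        for u, rel, v in edges:
            fh.write(f"{u} {rel} {v}\n")
    pd.DataFrame(edges, columns=["source", "relation", "target"]).to_csv(
        edge_path, sep="\t", index=False
    )
    nodes = sorted(
        ({"id": n, "type": g.nodes[n]["node_type"], "direction": g.nodes[n]["direction"]}
         for n in g.nodes),
        key=lambda d: d["id"],
    )
    pd.DataFrame(nodes, columns=["id", "type", "direction"]).to_csv(
        node_path, sep="\t", index=False
    )
    return {"sif": sif_path, "edges": edge_path, "nodes": node_path}


def read_edge_tsv(path: str) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df[["source", "relation", "target"]].itertuples(index=False)]


def write_cerna_pairs_tsv(pairs: Sequence[CeRNAPair], path: str) -> None:
    rows = [
        {
            "circ_id": q.circ_id, "mrna_id": q.mrna_id,
            "shared_mirnas": ";".join(sorted(q.shared_mirnas)),
            "x": q.shared_count, "K": q.circ_targeting_count,
            "M": q.mrna_targeting_count, "N": q.universe_size,
            "score_p": q.score_p, "coexpr_r": q.coexpr_r, "coexpr_p": q.coexpr_p,
        }
        for q in pairs
    ]
    pd.DataFrame(
        rows,
        columns=["circ_id", "mrna_id", "shared_mirnas", "x", "K", "M", "N",
                 "score_p", "coexpr_r", "coexpr_p"],
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")
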