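"""miRNA response element (MRE) prediction with a deterministic seed-and-extend scorer.

A site requires a perfect Watson-Crick match between the miRNA seed
(positions 2-8, 1-based from the 5' end) and the target.  From the seed the
duplex is extended along the miRNA 3' region — which runs 5'-ward on the
target, since the strands pair antiparallel — scoring +5 per Watson-Crick
pair and +2 per G:U wobble; the first non-pairing position terminates the
extension (no gaps or internal loops are modeled).  The energy field is a
monotone proxy in kcal/mol-like units, not a nearest-neighbor free energy:
energy = -(7.0 + 0.45 * WC + 0.2 * GU) over the extension.

The reported site position is the 0-based offset of the 5'-most paired
target base (the base pairing the deepest matched miRNA 3' position);
position + 7 + extension ends at the seed match.  Externally produced pair
tables in the same per-pair summary schema (total/max score and energy,
target length, site positions, MRE count) can be read in place of the
scanner's output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass
class ScanParams:
    base_score: float = 40.0
    wc_bonus: float = 5.0
    gu_bonus: float = 2.0
    energy_base: float = 7.0
    energy_wc: float = 0.45
    energy_gu: float = 0.2


@dataclass
class BindingSite:
    mirna_id: str
    target_id: str
    position: int  # 0-based start of the paired region on the target
    score: float
    energy: float
    seed_start: int = 0  # 0-based offset of the seed match on the target


@dataclass
class BindingSummary:
    mirna_id: str
    target_id: str
    target_length: int
    positions: list[int] = field(default_factory=list)
    mre_count: int = 0
    total_score: float | None = None
    total_energy: float | None = None
    max_score: float | None = None
    max_energy: float | None = None


def _normalize(seq: str, label: str) -> str:
    s = seq.upper().replace("T", "U")
    for ch in s:
        if ch not in "ACGU":
            raise ValueError(f"invalid symbol {ch!r} in {label}")
    return s


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def _is_wc(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def scan_targets(
    mirna_seq: str,
    target_seq: str,
    params: ScanParams | None = None,
    mirna_id: str = "miRNA",
    target_id: str = "target",
) -> list[BindingSite]:
    """All non-overlapping MREs of one miRNA on one target, ordered by position.

    Overlap conflicts between candidate sites are resolved greedily by score
    descending, then position ascending.
    """
    params = params or ScanParams()
    mi = _normalize(mirna_seq, "miRNA")
    tg = _normalize(target_seq, "target")
    if len(mi) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    seed = mi[1:8]
    seed_rc = reverse_complement(seed)

    candidates = []
    start = 0
    while True:
        q = tg.find(seed_rc, start)
        if q < 0:
            break
        start = q + 1
        score = params.base_score
        wc = gu = 0
        # miRNA position 9, 10, ... (0-based 8+) pairs target q-1, q-2, ...
        for k in range(8, len(mi)):
            tpos = q - 1 - (k - 8)
            if tpos < 0:
                break
            a, b = mi[k], tg[tpos]
            if _is_wc(a, b):
                wc += 1
            elif (a, b) in _WOBBLE:
                gu += 1
            else:
                break
        ext = wc + gu
        score += params.wc_bonus * wc + params.gu_bonus * gu
        energy = -(params.energy_base + params.energy_wc * wc + params.energy_gu * gu)
        candidates.append(
            BindingSite(mirna_id, target_id, q - ext, score, energy, seed_start=q)
        )

    # greedy non-overlap on the full paired region [position, seed_start + 7)
    chosen: list[BindingSite] = []
    for site in sorted(candidates, key=lambda s: (-s.score, s.position)):
        if all(
            site.seed_start + 7 <= o.position or o.seed_start + 7 <= site.position
            for o in chosen
        ):
            chosen.append(site)
    chosen.sort(key=lambda s: s.position)
    return chosen


def aggregate_pair(sites: list[BindingSite], target_length: int) -> BindingSummary:
    """Per-pair summary: totals are sums over sites, maxima follow the best-scoring
    site (max_energy is the energy of the site attaining max_score)."""
    if not sites:
        raise ValueError("aggregate_pair needs at least one site; use an empty summary")
    ids = {(s.mirna_id, s.target_id) for s in sites}
    if len(ids) > 1:
        raise ValueError(f"mixed pair ids: {sorted(ids)}")
    mirna_id, target_id = next(iter(ids))
    best = max(sites, key=lambda s: (s.score, -s.position))
    return BindingSummary(
        mirna_id=mirna_id,
        target_id=target_id,
        target_length=target_length,
        positions=[s.position for s in sites],
        mre_count=len(sites),
        total_score=sum(s.score for s in sites),
        total_energy=sum(s.energy for s in sites),
        max_score=best.score,
        max_energy=best.energy,
    )


PAIR_TABLE_COLUMNS = [
    "mirna_id", "target_id", "total_score", "total_energy",
    "max_score", "max_energy", "target_length", "positions", "mre_count",
]


def read_pair_table(path: str) -> list[BindingSummary]:
    """Read a per-pair MRE summary TSV (scanner output or an external predictor's).

    Rows violating the summary invariants (MRE count vs positions, totals vs
    maxima, positive energies) are skipped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in PAIR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out: list[BindingSummary] = []
    skipped = 0
    for ln, row in enumerate(df.itertuples(index=False), 2):
        try:
            positions = [int(x.replace(",", "")) for x in str(row.positions).split()]
            s = BindingSummary(
                mirna_id=row.mirna_id,
                target_id=row.target_id,
                target_length=int(str(row.target_length).replace(",", "")),
                positions=positions,
                mre_count=int(row.mre_count),
                total_score=float(row.total_score),
                total_energy=float(row.total_energy),
                max_score=float(row.max_score),
                max_energy=float(row.max_energy),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {ln}: {exc}") from exc
        if (
            s.mre_count != len(s.positions)
            or (s.mre_count >= 1 and s.total_score < s.max_score)
            or s.total_energy > 0
            or s.max_energy > 0
        ):
            logger.warning("%s: line %d violates summary invariants; skipped", path, ln)
            skipped += 1
            continue
        out.append(s)
    if skipped:
        logger.warning("%s: skipped %d invalid rows", path, skipped)
    return out


def write_pair_table(summaries: list[BindingSummary], path: str) -> None:
    rows = []
    for s in summaries:
        rows.append(
            {
                "mirna_id": s.mirna_id,
                "target_id": s.target_id,
                "total_score": s.total_score,
                "total_energy": s.total_energy,
                "max_score": s.max_score,
                "max_energy": s.max_energy,
                "target_length": s.target_length,
                "positions": " ".join(str(p) for p in s.positions),
                "mre_count": s.mre_count,
            }
        )
    pd.DataFrame(rows, columns=PAIR_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def scan_pairs(
    mirna_seqs: dict[str, str],
    target_seqs: dict[str, str],
    pairs: list[tuple[str, str]],
    params: ScanParams | None = None,
) -> list[BindingSummary]:
    """Scan a list of (miRNA id, target id) pairs; pairs without sites are dropped."""
    out = []
    for mid, tid in pairs:
        sites = scan_targets(
            mirna_seqs[mid], target_seqs[tid], params, mirna_id=mid, target_id=tid
        )
        if sites:
            out.append(aggregate_pair(sites, len(target_seqs[tid])))
    return out
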