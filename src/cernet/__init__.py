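"""cernet: competing-endogenous-RNA (circRNA-miRNA-mRNA) network inference.

Stages: circRNA genomic classification, expression normalization and
differential-expression filtering, signed Pearson co-expression screening,
miRNA response-element prediction, hypergeometric shared-miRNA ceRNA
scoring, evidence intersection and direction-coherent network assembly —
plus a synthetic-data generator with planted ground truth for validating
the whole funnel.
"""

from importlib import resources

__version__ = "0.1.0"

from .annotation import (  # noqa: F401
    CircRNARecord,
    GenomeAnnotation,
    classify_circrna,
    category_proportions,
    summarize_lengths,
)
from .binding import scan_targets, aggregate_pair, read_pair_table  # noqa: F401
from .cerna import hypergeom_tail, cerna_score, intersect_evidence, build_cernet  # noqa: F401
from .correlation import pearson_r, correlation_pvalue, correlate_pairs  # noqa: F401
from .enrich import enrich_terms, bh_adjust  # noqa: F401
from .expression import ExpressionMatrix, normalize, de_test, filter_de  # noqa: F401
from .pipeline import PipelineThresholds, run_pipeline  # noqa: F401
from .simulate import SimulationConfig, simulate_bundle, write_fixture_bundle  # noqa: F401


def reference_data_path(name: str):
    """Path to a packaged reference data file (published summary tables)."""
    return resources.files("cernet").joinpath("data", name)
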