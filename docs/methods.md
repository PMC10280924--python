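# Methods

This note documents the models, the numerical choices, and the design
decisions behind `cernet`, including what the synthetic-data generator does
and does not emulate.

## The inference funnel

The pipeline operationalizes the ceRNA (miRNA-sponge) hypothesis as a
conjunction of independent evidence types, applied in sequence. Each stage
is a filter with its own thresholds; the run manifest records every
threshold applied and the before/after counts, so a run is auditable as a
funnel.

1. **Classification** of back-splice junctions into five genomic-origin
   categories (see below).
2. **Differential expression** per RNA class at |log2FC| ≥ 1 (mRNA) or fold
   change > 2 (circRNA/miRNA) and p < 0.05.
3. **Signed Pearson screens** between DE sets: miRNA–mRNA and miRNA–circRNA
   negative, circRNA–mRNA positive; |r| ≥ 0.8 and p < 0.05.
4. **MRE prediction** on every surviving miRNA–target pair; pairs without
   sites are dropped.
5. **Hypergeometric shared-miRNA scoring** of circRNA–mRNA pairs,
   intersected with the positive co-expression set and truncated to the
   top 50 by score.
6. **Direction-coherent triplet assembly**: (circ, miR, mRNA) is kept only
   if the miRNA's DE direction opposes both partners'.
7. **Term over-representation** of the network's mRNAs (Fisher exact, BH).

## circRNA classification

Annotation names the five categories but no universal rule book exists, so
the definitions here are explicit and evaluated in precedence order:
exonic → intronic → sense-overlapping → antisense → intergenic. The
precedence resolves double-qualifying records deterministically: a circle
whose ends hit exon boundaries also overlaps its host gene, and same-strand
evidence always wins over opposite-strand evidence. Boundary coincidence is
exact by default (`boundary_slack = 0`); a slack in nt is exposed for
annotations with fuzzy exon ends. A record's `exon_count` is the number of
exons of the largest-overlap same-strand transcript that the span touches,
0 for antisense/intergenic.

circRNA *length* is the genomic span `end − start`, not the spliced
length — the catalogs this mirrors report spans up to ~10⁵ nt, only
consistent with genomic length. N50 is computed by descending-length
accumulation: the record length at which the cumulative sum first reaches
half the total.

## Differential expression

The DE statistic is Welch's *t* on log2(normalized + pseudocount), with a
default pseudocount of 1.0 and BH-adjusted p-values reported alongside raw
ones (raw p drives the default filter). This is deliberately not a
negative-binomial exact test: the screening thresholds, not the test's
small-sample power, are what downstream stages consume, and the module
boundary (a `DEResult` list) allows substituting an exact NB test without
touching callers. Degenerate features (no variation in either group) get
p = 1 when group means agree. The contrast order is explicit
(`groups=(g1, g2)`); reversing it negates every log2FC and leaves p
unchanged.

## Correlation screening

With three replicates per group all n = 6 samples are pooled, so
correlation tests run on 4 degrees of freedom; the exact two-sided p comes
from t = r·sqrt((n−2)/(1−r²)). This transform at n = 6 reproduces each of
the 12 printed (r, p) rows of the reference pair table shipped in
`src/cernet/data/` to at least 6 significant figures, which is what pins
down both the sample count and the formula. Thresholding uses |r| ≥ r_min
inclusively; note that p < 0.05 at n = 6 by itself already implies
|r| > 0.811, so the p-criterion is the binding one at the default
r_min = 0.8. Screens are computed on log2(normalized + 1) values by default
(`corr_log2`), the usual co-expression scale; raw normalized values are a
flag away. Zero-variance features are excluded and counted in the log
rather than raised, since an all-zero row is an expected data artifact.

## MRE scoring

The scanner is a deterministic stand-in for thermodynamic tools, designed
so that site presence/absence and positions are exactly testable: perfect
WC seed match (miRNA positions 2–8) anchors a site; the 3′ extension walks
the miRNA from position 9 and the target 5′-ward (antiparallel pairing),
+5 per WC pair, +2 per G:U, terminating at the first non-pairing position;
no gaps or loops. Score = 40 + 5·WC + 2·GU; energy = −(7.0 + 0.45·WC +
0.2·GU) kcal/mol-like. The reported position is the 5′-most paired target
base. Overlapping candidates are resolved greedily by score then position.
`max_energy` in a pair summary is the energy of the max-score site (for
single-site pairs the conventions coincide, as in every printed single-MRE
row of the reference table). The scanner makes no claim of thermodynamic
accuracy — externally produced pair tables in the same schema are
first-class inputs via `read_pair_table`.

## ceRNA scoring and network assembly

The shared-miRNA score is the hypergeometric upper tail, inclusive of the
observed overlap; pairs sharing zero miRNAs are never scored. The miRNA
universe N defaults to the candidate set entering pair prediction (the
screened DE miRNAs), configurable to all quantified miRNAs. No
multiple-testing correction is applied to score p-values by default
(`cerna_alpha = 1` scores all pairs; BH is available). Intersection with
positive co-expression ranks by score_p ascending with lexicographic
tie-breaks and truncates to `top_k = 50`. Triplet assembly requires all
three edges plus direction coherence; `ns` features never form triplets.
Enrichment reuses the same hypergeometric kernel as the ceRNA score (the
one-sided Fisher exact p for a 2×2 table), cross-checked in tests against
an independent implementation.

## The synthetic-data generator

The generator emulates the statistical structure of a two-breed ovary
RNA-seq contrast: 3 + 3 samples, negative-binomial counts
(var = μ + φμ², gamma-Poisson, φ = 0.05 by default), library sizes varying
±20%, and a genome of non-overlapping single-transcript genes with 1–18
exons on both strands. circRNAs are planted per category at configurable
proportions (default: the five-way mix of a published ovary catalog,
dominated by sense-overlapping records) and constructed to satisfy the
classification definitions exactly, so classifier-vs-truth agreement is a
sharp test.

**Sponge model.** For each planted triplet, per-sample miRNA activity a_s
is the standardized *latent* log-mean of the miRNA (the biological signal
its counts are drawn around). The circRNA attenuates activity
multiplicatively, a′_s = a_s · 2^(−sponge·c_s), with c_s the standardized
realized circRNA level, and the mRNA mean is multiplied by 2^(−β·a′_s).
The miRNA and circRNA carry direct group effects of ±de_lfc/2 per group in
opposite directions; the mRNA's group effect arises entirely through the
repression chain. Two deliberate choices here: (i) using the latent rather
than realized miRNA signal avoids double-counting miRNA measurement noise
in the target, and (ii) giving triplet mRNAs no *additional* direct shift
avoids compounding two large effects into fold changes that drive counts to
zero. Together these make the three correlation signs
(miRNA–mRNA < 0, miRNA–circRNA < 0, circRNA–mRNA > 0) hold in expectation
with magnitudes that the n = 6 screens can detect.

**Defaults.** β = 1.5, sponge = 0.5, de_lfc = 3 (8-fold), base means
2⁶–2¹¹, dispersion 0.05, 20 planted triplets with distinct members, 4 decoy
DE features per class, 2 MREs per planted pair on ~600-nt targets with half
the 3′ extension complementary. These constitute the strong-effect regime
under which the plant-and-recover contract (triplet recall ≥ 0.9,
precision ≥ 0.8) holds for an arbitrary seed; with all effects zeroed the
pipeline returns an empty network in ≥ 95% of runs. The decoys matter: they
pass the DE and correlation screens (any two strongly DE features correlate
across a pooled two-group design) and are removed only by the sequence
evidence, which is what makes precision a meaningful measurement.

**Sequences.** miRNA sequences are rejection-sampled so that seeds are
mutually distinct and no miRNA's seed occurs inside another's 5′ pairing
region (which would plant a foreign site); targets are rejection-sampled so
that no miRNA seed complement occurs anywhere except at recorded planted
positions, and the base 5′ of each planted site is forced non-pairing so
the scanner's extension stops exactly at the planted boundary. This makes
site recovery exact — positions, counts and scores — not merely likely.

**What is not emulated**: read-level noise (FASTQ, mapping ambiguity),
isoform structure and spliced circRNA sequence, dispersion trends across
the mean, batch effects, correlated co-regulation outside planted triplets,
and realistic miRNA/target sequence composition. Passing plant-and-recover
tests therefore demonstrates the correctness of the inference logic under
the generative model's assumptions, not performance on real libraries.

**Determinism.** One root seed; per-stage child streams with fixed labels.
An identical config reproduces a byte-identical bundle (checksummed
manifest), and `run-all` reproduces identical output checksums.

## Problem sizes

Default bundles use 60 genes, 40 miRNAs, 80 circRNAs — small enough that a
full simulate-plus-pipeline run takes well under a second, so Monte-Carlo
sweeps (200-seed null calibration, 100-run null control) and the
10,000-record classification catalog run in seconds. All sizes are
config fields, not constants.

## Known limitations

* The Welch-t DE screen is underpowered at n = 3 + 3 relative to NB exact
  tests; planted effects are sized to be detectable, but real data at this
  depth would warrant a shrinkage estimator.
* The MRE scorer models no thermodynamics and no gaps; it is a
  position-faithful oracle target, not a miranda replacement.
* The hypergeometric score assumes exchangeable miRNA targeting; shared
  targeting driven by sequence composition biases would inflate
  significance on real data.
* With n = 6 the null expectation of |r| is already 3/8, so the r ≥ 0.8
  screen retains an appreciable false-positive rate among DE features;
  downstream sequence evidence, not the correlation screen, carries the
  specificity.
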