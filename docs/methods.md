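# Methods

## Scope and model

`regdiscover` implements a regulator-discovery computation over
developmental expression data: an organ-wise enrichment atlas, a temporal
candidate screen, outgroup-based evolutionary classification, term
over-representation, ChIP peak co-occupancy with E-box scanning, and
cross-species expression-window comparison. All stages are deterministic
functions of their inputs; the only stochastic component is the
synthetic-data generator, which is a pure function of (seed, config).

## Organ enrichment

A gene's organ profile is the arithmetic mean RPKM per organ over the
stages with available measurements; unavailable entries are first-class
(they are skipped, never imputed as zero — the atlas format distinguishes
"unavailable" from "not expressed"). The enrichment rule is
parameterized rather than fixed: with top mean m\*, runner-up m₂ and
pseudocount c,

    score = (m* + c) / (m₂ + c);  enriched iff m* ≥ expr_floor and score ≥ fold_min.

Defaults: `expr_floor` 1 RPKM (below this, fold ratios are dominated by
noise), `fold_min` 2 (a conventional specificity margin), `pseudocount`
0.1 RPKM (caps the score at ~(m\*+0.1)/0.1 when the runner-up is silent and
removes the division-by-zero case). The one-organ-per-gene structure is
enforced by construction (argmax); whether a more permissive multi-organ
rule is preferable is an open design question we resolved in favor of the
partition, because the downstream screen and atlas table assume it. Brain
and cerebellum are independent organ axes.

Ties in the argmax are broken by declared organ order, and output rows are
ordered (organ, descending top mean, gene id) so tables are reproducible.

## Temporal screen

`screen_candidates` applies two strict predicates per gene within one
organ: mean RPKM > `min_mean_rpkm` (default 1) and
(P0 + ε)/(P63 + ε) > `min_ratio` (default 8), ε = 0.01 RPKM. Decisions
documented here because the source criteria leave them open:

* **Averaging window.** "Average RPKM" is taken over *all* available
  stages of the screened organ, the least-assumption reading; a
  `mean_stages` subset (e.g. perinatal-only) is exposed for alternatives.
* **Pseudocount.** ε = 0.01 handles zero adult expression without
  discarding genes; a gene with P0 = 1, P63 = 0 gets ratio 101.
* **Strictness.** Both inequalities are strict, matching the ">" wording
  of the criteria; a gene at mean exactly 1.0 fails.
* **Missing boundary stages.** Genes lacking the P0 or P63 measurement are
  emitted with `passes = False` and a named reason, never silently dropped.

## Evolutionary classification

The mapping is fixed: ortholog → conserved, related non-ortholog → type I,
absent → type II, no record → unclassified. Orthology inference itself
(similarity search, tree reconciliation) is an input, not a computation:
the module consumes a declared evidence table so any upstream method can
be plugged in. The `conserved` and `unclassified` categories exist because
type I + type II need not exhaust a candidate list.

## Term enrichment

The upper-tail hypergeometric probability is summed in log space
(log-gamma binomial coefficients + logsumexp), giving ≤ 1e-12 relative
error against exact enumeration for universes up to ~10⁴ (verified in
tests against `math.comb` enumeration and `scipy.stats.hypergeom.sf`).
BH q-values are the standard step-up, capped at 1, order-preserved;
statsmodels is an independent oracle in tests, never the implementation.
The background universe is a required argument: published analyses rarely
state their background, so defaulting one silently would bake in an
unauditable choice. Ties in p are broken lexicographically by term id so
"top N" lists are deterministic.

## Co-occupancy and motifs

Coordinates are 0-based half-open (BED convention) throughout. The
proximity rule flags an A interval when some same-chromosome B interval
has gap(a,b) = max(0, b.start − a.end, a.start − b.end) ≤ window; "near"
has no canonical threshold, so the window is a required, echoed parameter
(suggested 1,000 bases). The sweep sorts B per chromosome and binary
searches with a running-maximum-of-ends array; tests compare it against
the all-pairs oracle.

Nearest-gene assignment minimizes |anchor − midpoint| with
midpoint = ⌊(start+end)/2⌋ and lexicographic tie-break. The anchor table
abstracts the anchor convention (translation start vs transcription
start): callers supply whichever coordinate they mean.

Motif scanning matches IUPAC patterns (default `CANNTG`, the canonical
bHLH E-box — note it is its own reverse complement) position by position;
minus-strand hits are reported at plus-strand coordinates with the matched
string as read on the minus strand. `N` in the *sequence* matches only
fully ambiguous pattern positions.

## Expression windows

"Expressing" means raw count > 0; dot plots report percent-expressing
without a stated threshold, so the zero/nonzero reading is the default and
the only one implemented at the counting level. Window semantics are
*envelope*: first to last qualifying stage, with interior dips below the
threshold counted and reported (`dip_count`) rather than splitting the
window — cross-species stage sampling is too sparse for strict contiguity
to be meaningful. Default `min_fraction` 0.2; 0.4 is the natural setting
for a stricter "over 40%" framing. Durations convert stage labels to
absolute ages via a species timeline (embryonic stage → days post
conception; postnatal stage → gestation + days) and divide by lifespan;
timelines are user-supplied inputs with no baked-in constants, since
lifespan and stage-age mappings are study-specific choices.

## Synthetic data generator

The generator emulates the *structure* of the real resources, not their
gene-level distributions:

* **Atlas.** 2,000 genes × 7 organs (brain, cerebellum, heart, kidney,
  liver, ovary, testis) × 14 stages (E10.5–E17.5, P0–P63), 50 planted
  enriched genes per organ at fold 8 over a 5-RPKM baseline,
  multiplicative log-normal noise with CV 0.2 (unit mean, so CV 0
  reproduces planted means exactly), 2% missing entries. A fraction
  (default 0.1, mirroring a ~10% candidate yield per organ) of each
  organ's enriched genes carry a perinatal profile: embryonic ramp, P0
  peak, geometric decay to P63 with planted P0/P63 mean ratio 32.
* **Margins.** Planted effects sit at 4× their decision thresholds (fold
  8 vs 2; ratio 32 vs 8). The ratio margin is the binding one: the screen
  ratio compares two single-stage values, so its log has standard
  deviation ≈ CV·√2 ≈ 0.28 at CV 0.2, and a 4× margin puts a flipped
  verdict ~5 standard deviations out (~10⁻⁶ per gene); organ means
  average 14 stages and are far safer. Masking never removes P0/P63 of
  planted temporal genes in their target organ — otherwise the planted
  truth would be unrecoverable by construction, which is a property of the
  generator, not of the method under test.
* **Peaks.** B peaks on a fixed-pitch grid; exactly round(co_fraction·n_A)
  A peaks placed with gap ≤ window of a distinct B peak, the rest beyond
  2·window of every B peak, so the planted fraction is exact, not
  approximate. Pitch 6·window + 4·peak_len guarantees both constraints;
  infeasible packings raise.
* **Single-cell counts.** Within a gene's planted stage window each cell
  expresses with probability p_in (count 1 + Poisson(2)), outside with
  p_out; defaults p_in 0.5, p_out 0.02, 500 cells per stage.
* **Fixture bundle.** `write_fixture` emits every input format (atlas and
  catalog TSV, evidence TSV, GMT, BED pair, anchor TSV, enhancer FASTA
  with the E-box ablated in the outgroup species, MTX bundle, timeline
  TSVs) plus `truth.json`. Timeline values (mouse gestation 19 d, lifespan
  730 d, etc.) are fixture conventions, not biological claims.

What passing the planted-recovery tests shows: the decision rules
implement their definitions exactly and are robust at the stated
noise/margin combination. What it does not show: performance on real
atlases, where effect sizes hug the thresholds, noise is not log-normal,
organs share correlated programs and the enrichment criterion of any
particular published list may differ from the parameterized rule here.

## Numerical and determinism choices

* Hypergeometric tails in log space; comparisons at 1e-12 relative
  tolerance in tests.
* RPKM values are rounded to 6 decimals at generation time so TSV
  round-trips are exact; all report floats printed with %.6g.
* All RNG through `numpy.random.default_rng(seed)`; file outputs are
  timestamp-free, and pipeline runs write to temporary names with an
  atomic rename on success, so a failed run leaves no partial report.
* Problem sizes in the test and acceptance runs (2,000-gene atlas,
  1,000-interval oracle comparisons, 1,000 null replicates, 100 window
  replicates) were chosen as the smallest sizes at which the planted
  margins and calibration checks are statistically sharp.

## Known limitations

* The enrichment criterion is a parameterized stand-in exposed through
  `EnrichmentConfig`; published organ-enrichment lists derived from other
  criteria will not be reproduced exactly.
* No GO graph propagation: annotations must arrive pre-propagated.
* The motif scanner is exact-match IUPAC, not a PWM; degenerate motifs
  with position-specific weights are out of scope.
* Orthology, peak calling, clustering and pseudotime are upstream inputs
  by design.
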