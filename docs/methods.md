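# Methods

## Aggregation-propensity consensus

An Int^N precursor's tendency to form splicing-inactive, β-sheet-based
aggregates is predicted from sequence alone. Four per-residue predictors are
computed and combined by majority vote; all four are local re-implementations
of published scale- or pattern-based algorithms, so the package never calls
an external service.

1. **AGGRESCAN-style scale track.** The a3v aggregation-propensity scale
   (Conchillo-Solé et al. 2007, BMC Bioinformatics 8:65) is averaged over a
   centered window (default 5 residues, odd). Hot spots are proline-free runs
   of ≥ 5 residues with windowed value above −0.02 (the published hot-spot
   threshold). Prolines are β-breakers and terminate runs by construction.
2. **Amyloidogenic hexapeptide pattern.** The six-position residue-class
   pattern for de novo amyloid hexapeptides (López de la Paz & Serrano 2004,
   PNAS 101:87): {not P}{not P,K,R,H,W}[VLSCWFNQE][ILTYWFNE][FIY]{not
   P,K,R,H}. Every matching window (canonical positive: STVIIE) marks all six
   residues.
3. **Mean packing density.** Windowed mean of the expected contact-number
   scale (contacts within 8 Å by residue type; Galzitskaya, Garbuzynskiy &
   Lobanov 2006, PLoS Comput Biol 2:e177), hot spots above the published
   threshold 21.4 over runs of ≥ 5. The shipped table was transcribed from
   the publication line; for the rank- and classification-level uses in this
   package only the (robust) ordering of the scale matters — aliphatic and
   aromatic residues above the threshold, charged and small residues below.
4. **β-sheet propensity.** Windowed mean of Chou–Fasman P_β (1978), hot
   spots above 1.0 over runs of ≥ 5. The threshold is the scale's own
   normalisation point (P_β = 1 is the database average, > 1 marks β
   formers); no published hot-spot threshold exists for this scale, so the
   natural unity cutoff was adopted.

Window means are truncated at the termini (mean over the residues available
in the centered window), keeping track length equal to sequence length. A
residue is a **consensus hit** when at least ⌈M/2⌉ of the M methods flag it
(majority; M = 4 by default, threshold and method set configurable).

Absolute consensus values are *not* comparable with those of web consensus
servers built from larger and partly machine-learned method panels.
Downstream analyses therefore use rank order, score ratios, and
classification rather than raw score equality — the classification cutoff
(N2/N1 = 1) is scale-free.

## N1/N2 partitioning and the ratio classifier

The lobe boundary of a candidate Int^N is transferred from a
boundary-annotated reference by global pairwise alignment (BLOSUM62, affine
gaps, open −10 / extend −0.5). The candidate position aligned with the
reference boundary becomes the candidate boundary; if that reference column
is deleted in the candidate, the boundary maps to the *next* aligned
candidate residue, preserving the semantics "N2 begins at the first residue
of the transferred region". Ties among co-optimal tracebacks are broken
deterministically (match preferred over insertion over deletion). Transfers
below 15% identity (identical pairs / longer sequence length) are refused;
the caller must then supply an explicit boundary. The reference record is
data, not code: a JSON document with the sequence and its 0-based boundary
index. The shipped reference (`data/synthetic_reference_intein.json`) is a
synthetic stand-in for demonstration and testing; real analyses should use a
reference intein with a structurally assigned N1/N2 border.

Lobe scores are per-residue normalised. Default `hit_fraction` mode: the
fraction of lobe residues inside consensus hits; alternative `mean_count`
mode: the mean of count/M over the lobe. Per-residue normalisation makes the
full-fragment score the exact length-weighted mean of the lobe scores,
s_total = (b·s_N1 + (L−b)·s_N2)/L, which holds to machine precision and is
property-tested. The ratio r = s_N2/s_N1 is undefined when s_N1 = 0
(classification: indeterminate); r < 1 predicts efficient splicing, r > 1
aggregation-prone behaviour. The "aggregation score" itself has no single
published numerical definition; both normalisations are provided and both
are reported because the classification is invariant when lobes scale
proportionally.

## Panel statistics

Spearman ρ uses mid-ranks for ties. p-values: two-sided t-approximation by
default (appropriate for the n ≈ 13 panels this targets), or permutation —
exhaustive over all n! orderings for n ≤ 8, seeded Monte-Carlo (with add-one
smoothing) above. Regression lines are ordinary least squares. The panel
report computes N2-vs-total and N2-vs-N1 correlations and fits, plus
prediction-vs-label confusion counts when efficiency labels are available; a
constant score vector leaves that pair's correlation undefined and it is
reported as missing rather than failing the panel.

## Kinetics

Splice-product formation under pseudo-first-order conditions (Int^C in 3:1
excess over the limiting Int^N precursor) follows SP(t) = SP_max(1 −
e^(−kt)). The fit is nonlinear least squares with the analytic Jacobian,
initialised at SP_max = max(sp) and k = ln 2 / t(half-max); tolerances are
1e−10 on parameters with at most 10⁴ evaluations, and an unconverged fit
raises instead of returning. No offset term is fitted by default — SP(0) = 0
is forced, which matches traces normalised to zero initial product; an
optional offset handles baselined data. Data whose signal does not increase
with time are rejected (they imply k ≤ 0). Standard errors come from the
asymptotic covariance; over seeded noise replicates (σ = 0.02, n = 12) the
±2·stderr interval covers the true rate in roughly 9 out of 10 fits, the
usual mild undercoverage of asymptotic intervals at small n. Derived
quantities: t_1/2 = ln 2/k (an exact identity of the fit object) and
efficiency SP_max/P_N0, warned above 1 and clipped at 1.2.

SEC calibration is OLS of log10(MW) (default) or MW against retention time;
predictions invert the fit. Retention at or before the void time is outside
the column's separating range, so such predictions are returned as flagged
lower bounds evaluated at the void time.

## Synthetic fixtures

Generators are pure functions of parameters + seed (numpy `default_rng`).

* `make_intein` emulates the lobe composition contrast: N1 from an
  order-promoting pool diluted 4:1 with small/polar neutrals
  (`AAGGTTSSQQNNVLF` — chosen so the baseline N1 score is moderate and
  responsive to inserts rather than saturated), N2 from charged (D/E/K/R,
  default fraction 0.5, the disorder proxy) plus disorder-promoting neutrals
  including proline. Amyloid load is injected by overwriting non-overlapping
  6-mers with STVIIE at seeded positions, which preserves lobe lengths and
  makes the true boundary exact. Position 1 is fixed to Ser and Int^C ends
  in the conserved Asn, so records are valid cysteine-less candidates.
* `make_timecourse` places n points log-spaced over (t_max/100, t_max]
  (front-loaded, because a fast reaction with t_1/2 ≈ 36 s is over within
  minutes) on the one-phase curve plus Gaussian noise clipped at 0.
* `make_panel` draws each intein's N2 insert count uniformly from {0..6} and
  sets the N1 count to its complement with probability |anticorrelation|
  (independent otherwise), producing panels whose lobe scores are negatively
  coupled at roughly the requested strength; n = 13 mirrors the small-panel
  regime the statistics target.

What the fixtures do **not** emulate: real intein sequence conservation
(block motifs are not planted), genuine disorder (composition is a proxy),
structure, or inter-method disagreement patterns of real sequences. Passing
tests on fixtures demonstrate that the pipeline's arithmetic, orderings and
invariances are correct — not that the consensus reproduces any particular
experimental aggregation measurement.

## Numerical and design choices

* 0-based half-open coordinates everywhere; 1-based numbering only inside
  human-facing mutation labels (C24S).
* Motif patterns for the conserved blocks are config data with deliberately
  loose shipped defaults (no authoritative numerical block boundaries
  exist); annotation is advisory and never filters candidates. Matching is
  binary per window, so "best match" reduces to leftmost-first
  non-overlapping selection, which is deterministic.
* Catalytic +1 residue is stored on the record, not inferred: Int^C FASTA
  files usually exclude extein context.
* Acceptance-style study sizes: 200 replicates for estimator calibration,
  100 seeds × 13 inteins for panel sign consistency — sizes at which the
  Monte-Carlo error of the reported rates is well under the decision
  margins.

## Known limitations

* The 4-method consensus is a proxy for larger consensus servers; absolute
  scores differ and only rank/classification-level agreement should be
  expected.
* Boundary transfer assumes homology detectable at ≥ 15% identity with a
  reliable reference boundary; it cannot place a boundary ab initio.
* The kinetics model is a single rising exponential: no association-limited
  phase, no bi-exponential behaviour, and C-cleavage is reported as a signal
  column, not modelled.
* Packing-density scale values are a transcription (see above); replace
  `data/packing_density.tsv` to pin exact published digits if required.
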