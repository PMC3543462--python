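# Methods

## Scope and model

The package quantifies acantharian protists in two independent data
streams. The amplicon branch treats taxonomic assignment as a
nearest-neighbor problem under exact global alignment: every read is
compared end-to-end against every reference, so identity values are
reproducible and comparable across reads, at the cost of O(n·m) work per
pair. The geochemistry branch treats a sediment-trap bottle series as a
Gaussian Sr background with sparse additive pulses; inference is a simple
threshold rule rather than a fitted mixture, matching how trap chemistry
is screened in practice.

## Amplicon quality control

* **Primer rule.** Exact match of the forward primer at position 0 and of
  the reverse-complemented reverse primer at the 3′ end. IUPAC degeneracy
  is honored in the primer only; an `N` in the read matches nothing. This
  is deliberately conservative: an uncalled base inside a primer span says
  the primer region was not sequenced cleanly.
* **Window rule.** Per-base error probabilities `p_i = 10^(−Q_i/10)`
  averaged over every 50-bp window at step 1; a read is discarded iff some
  window mean is strictly greater than 1%. Reads shorter than 50 bp form a
  single full-length window. The expected-error reading (mean `p_i`, not a
  count of low-Q bases) is the standard quality-aware interpretation of a
  per-section error budget.
* **Numerics.** Window means are computed by cumulative sum; the discard
  comparison carries a 1e-12 absolute guard so a window whose true mean
  equals the limit is kept under the strict rule despite floating-point
  rounding (thirty Q20 bases otherwise average one ulp above 0.01).
* **Chimera hook.** `run_qc` accepts a pass-through hook that may only
  remove reads; no chimera detector is bundled.

## Alignment and assignment

* **Scoring.** Affine gaps with defaults +5 match, −4 mismatch, −12 open,
  −2 extend — common DNA global-search values; all four are configurable.
  A gap of length L costs `open + (L−1)·extend`. `N` and other ambiguity
  codes score as mismatches against everything, including themselves.
* **Determinism.** Traceback prefers diagonal over up over left at equal
  score, and the match state over the two gap states at entry, so the
  reported alignment is byte-reproducible. The DP inner loop is
  numba-compiled; a linear-memory score-only variant exists for screening.
* **Identity.** `matches / all alignment columns` (gap and ambiguity
  columns count in the denominator only), kept as `fractions.Fraction`.
  Exact rationals make tie detection robust: two references at 125/130
  compare equal, where floats could split them. Thresholds given as
  decimal strings or floats are normalized through their decimal
  representation (0.85 ⇒ 17/20 exactly).
* **Nearest neighbor and ties.** The neighbor is ranked by identity (the
  retention criterion is an identity threshold, so ranking by raw score
  could retain a read via one reference while reporting the identity of
  another). Tied lineages collapse to their longest shared root-first
  prefix; fully disjoint ties fall back to a designated root label. Both
  the 85% assignment threshold and the 97% cyst-similarity screen are
  strict inequalities.

## Community summaries

Depth zones are half-open bins [0,100), [100,1000) and [1000,3000] m
(deeper water is its own zone); the closed top keeps a 3000-m trap inside
the deep zone. Composition fractions are computed per sample over assigned
reads only — unassigned reads are reported separately, never silently mixed
into a denominator. Clades under a 1% display floor are masked for display
but retained in the data.

## Trap flux analysis

* **Background.** Mean and sample SD (n−1) over bottles strictly below the
  9 µg mL⁻¹ cutoff, per trap. Fewer than two qualifying bottles is an
  error. A zero SD degenerates the significance rule to `> mean` and logs
  a warning.
* **Significance.** `conc > mean + 2·SD`, strict. Bottles between the
  cutoff and this threshold are simply non-significant.
* **Flux and uncertainty.** Excess concentration × volume / 1000 /
  (area × duration). The uncertainty combines 1% analytical error on the
  measured concentration with the background SD in quadrature and scales
  like the flux. The background's own SD (not SD/√n) is used — the
  conservative choice, since consecutive bottles share slowly varying
  preservative chemistry and are not exchangeable replicates.
* **Carbon.** C:Sr = 0.120 ± 0.022 mg/mg; relative errors in quadrature.
  Reported values keep full precision; a reporting helper truncates toward
  zero (2 decimals for Sr flux, 3 for C flux).
* **Carbonate bound.** The ~1 mg Sr g⁻¹ carbonate ratio is applied per
  gram of measured Ca elevation; the basis is an explicit parameter.

## Synthetic data

* **References.** One random root sequence; clade ancestors diverge from
  it at the between-clade rate (default 0.20 substitutions/site), members
  from their ancestor at the within-clade rate (default 0.02). Defaults:
  4 clades × 5 references × 130 bp, matching the short-hypervariable-region
  setting. Lineages are two-rank (`Acantharea;Clade<k>`).
* **Reads.** Forward primer + mutated reference + reverse-complemented
  reverse primer; degenerate primer positions are concretized (a real
  amplicon carries actual bases). Substitution-only errors at 1% per base
  by default (an optional indel rate exists but defaults to 0 — the QC
  filters are quality-based and substitutions dominate the realistic
  failure modes). Qualities follow the error state: Q40 for correct bases,
  Q20 for substituted ones, so the emitted FASTQ is informative but —
  by construction — never breaches the 1% window budget; window-filter
  failures are exercised with hand-built fixtures instead. Truth lives in
  a sidecar TSV, keeping the FASTQ standard-clean.
* **Trap series.** Nine 500-mL bottles at 28 days each on a 0.66 m² trap;
  background 8.0 ± 0.2 µg mL⁻¹ (negative draws are resampled, keeping the
  background approximately Gaussian); two spikes of 4 and 8 mg Sr
  (bottles 4 and 8), i.e. fluxes of 0.216 and 0.433 mg Sr m⁻² d⁻¹ —
  inside the observed episodic range. The bottle count is deliberately
  modest: with the significance threshold estimated from the same bottles,
  the internal studentized residual is bounded by (n−1)/√n, so small
  background sets keep the family-wise false-positive rate of the 2·SD
  rule low (≈3% of series at 7 background bottles), while for n ≳ 10 it
  rises above 10% no matter how quiet the background is. A long deployment
  should be analyzed as consecutive shorter series if false positives
  matter.

## What the synthetic tests do and do not show

Recovery tests demonstrate that the implementation inverts its own
generative model: clade recovery ≥99% at 1% read error and 20%/2%
between/within divergence, spike detection and 2-SD flux coverage ≥95%
over seeded replicates. Real data differ in ways the generator does not
emulate: chimeras, indel-rich errors, primer-site mutations, uneven clade
abundances, reference databases that do not span field diversity, and
trap backgrounds with drift or autocorrelation. Passing tests therefore
validate the algorithms and their wiring, not field performance.

## Problem sizes

Default verification runs use 2000 reads against 20 references for
assignment recovery, 500 random pairs (length ≤6) for the brute-force
alignment oracle, and 200 simulated trap series; these sizes give stable
percentages while keeping a full run of the suite and the acceptance
script to a few minutes on one core.

## Known limitations

No heuristic pre-filter: assignment is all-vs-all exact alignment, fine
for thousands of reads × tens of references, slow beyond that. No
read-pair merging, no chimera detector, no E-value model. The flux model
assumes the preservative is well mixed and dissolution complete within a
collection period. Carbon conversion inherits whatever bias the fixed
C:Sr ratio carries between regions and seasons.
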