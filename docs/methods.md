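# Methods

This note documents the models, parameter choices and numerical decisions
behind `mirconsensus`, and what the synthetic fixtures do and do not show
about real data.

## 3′-UTR sequence space

One UTR record per transcript isoform, for every biotype. Internally all
coordinates are 0-based half-open (GTF converted on read; BED output keeps
the internal convention) and all sequences are RNA (ACGU), 5′→3′ in
transcription direction.

- An **annotated** UTR is the spliced exonic sequence 3′ of the stop-codon
  boundary (`cds_end`). It is used when its length is at least
  `min_utr_length` (default 50 nt).
- Otherwise a **proxy** UTR is used: the `proxy_length` (default 130 nt)
  genomic bases immediately downstream of the last exon, unspliced, in
  transcription direction. 130 nt is the rounded cross-species mode of
  known 3′-UTR lengths (per-species modes 142/131/122 average to ~131.7;
  we follow the conventional rounded value and expose the parameter). A
  proxy replaces — does not supplement — a short annotated UTR, and the
  proxy window starts at the last exon end (not the stop codon) in that
  case; both points are genuinely open conventions and were fixed once
  here. Windows running off the contig are truncated with a warning.
- Non-coding transcripts and pseudogenes have no stop codon and therefore
  always use the proxy rule.
- The mode-length statistic is computed over annotated UTRs only, with
  ties broken toward the smaller length (deterministic).

## Engines

All engines emit `TargetSite` records with local (UTR) and genomic seed
coordinates; overlapping same-engine sites for one miRNA–UTR pair are
reduced to the best-scoring site per overlap cluster, so one binding
position yields one event. Engine keep-thresholds are configuration with
the defaults below.

### seedscan (seed matching)

Finds every exact match of the reverse complement of miRNA positions 2–7
and classifies it: 8mer (m8 match + A opposite position 1), 7mer-m8,
7mer-A1, 6mer. The raw score is

    type_score + AU_context + position_score

with type scores 3.0 / 2.0 / 1.5 / 1.0 (this package's own values — they
encode the standard efficacy ordering, not any published coefficient
set), `AU_context` the A/U fraction of the 30 nt flanking the seed match,
and `position_score` up to 0.5 at the UTR center, 0 at the edges
(functional sites are depleted near long-UTR edges). Conservation, when a
per-base bedGraph track is supplied, is averaged over the seed interval
and carried as metadata; it is consumed, never computed, and
conservation-based filtering is disabled without a track.

### dpalign (complementarity alignment)

Local Smith–Waterman with affine gaps of the reversed miRNA against the
UTR, scoring complementarity: Watson–Crick +5, G·U wobble +2, mismatch
−3, gap open 8, gap extend 2 (a gap of length L costs `open+(L−1)·ext`),
with pair scores at miRNA positions 2–8 multiplied by 4. Keep threshold:
alignment score ≥ 140 (the conventional threshold for this score family;
a perfect 22-nt duplex scores ≈ 215, a perfect seed alone 140). The fill
is a vectorized 3-state DP; reported sites are traced back from every
endpoint reaching the threshold and de-duplicated per overlap cluster.

### duplexfold (duplex MFE) and the ΔΔG adjustment

Minimum-free-energy intermolecular duplex between the miRNA and sliding
UTR windows (window 26 nt, step 13), intramolecular pairs forbidden. A
structure is a monotone (antiparallel, non-crossing) set of canonical
pairs scored as

    E = initiation + Σ (stack | loop)

- Stacks: a 36-entry nearest-neighbor table (packaged TSV,
  `engines/data/stack_energies.tsv`) covering all Watson–Crick and wobble
  pair combinations, kcal/mol at 37 °C. Watson–Crick entries follow
  standard published values; the two symmetric double-wobble stacks,
  positive in published tables, are clamped to small negative values so
  that every complementary stack stabilizes the duplex (a model
  invariant here).
- Loops/bulges: affine cost `2.0 + 0.5·(unpaired nt)` rather than full
  tabulated loop energies — desk-scale fidelity, not a re-implementation
  of a complete folding package. Loops longer than `max_loop = 6`
  unpaired nt per strand are forbidden (a Vienna-style cap, part of the
  model definition; the test oracles apply the same rule).
- Duplex initiation: +4.09 kcal/mol.

Sites are kept when E < 0 kcal/mol and stored with `raw_score = −E`.
The optional accessibility adjustment approximates the cost of opening
the unbound site as the stability of the best duplex between the target
region and either 20-nt flank: `ΔΔG = E + max(0, −E_competing)`. The
penalty is never negative. This is a deliberate simplification of full
unbound-ensemble opening energies.

## Validated pairs and tiers

Source tables are normalized (case-folded gene symbols; miRNA ids
lower-cased with an organism prefix ensured, e.g. `mir-21` →
`hsa-mir-21`) and deduplicated on (miRNA, gene): sources merge into a
set, the best supporting tier wins (monotone — adding evidence never
lowers a tier). Default tier map: oncomirdb → high (manual curation),
mirecords → medium (partial curation), tarbase/mirtarbase → low (text
mining). Prediction↔validation matching is at gene-symbol level because
the source databases rarely record isoforms; whether "unique" pairs
should be keyed by transcript instead is unknowable from the sources, so
gene-level was fixed once. Predictions absent from every source are
treated as presumed negatives for calibration and ROC — a known bias:
undiscovered true targets deflate measured precision and AUC.

## Standardization, calibration, CWS

- Z-scores are per engine over the engine's full prediction set, using
  the population (n) standard deviation, oriented so larger is better
  (energies are sign-flipped). Standardization is global per run, not per
  organism; stratified runs achieve the latter.
- The weight curve W(s) is the empirical precision of predictions scoring
  ≥ s (complementary cumulative distribution against validated pairs).
  The raw curve is non-monotone on finite data, so it is isotonized by
  weighted pool-adjacent-violators regression (weights = count of
  predictions above each knot; implemented via scikit-learn's
  `IsotonicRegression`) — the published construction does not mention
  smoothing, but a probability interpretation requires monotonicity.
  Weights are floored at ε = 1e-6 (configurable) so the CWS denominator
  can never vanish. W is evaluated *at each prediction's own score*, not
  as one constant per tool. Lookup between knots takes the next knot
  above (the ≥-s set is the same); above the top knot the last weight
  applies.
- Groups merge predictions of one (miRNA, transcript, strand) whose
  genomic seed intervals overlap by ≥ 1 nt (transitive closure), keeping
  the best member per engine. Exact coincidence of site type and seed
  coordinates across ≥ 2 engines is flagged separately
  (`agreement_exact`), distinguishing "same genomic position" (grouping)
  from strong agreement. CWS = Σ ZᵢWᵢ / Σ Wᵢ, a convex combination of
  member Z-scores. Ranking is by CWS descending with deterministic
  tie-breaks (agreement, ids, position).

## Evaluation

ROC by threshold sweep with trapezoid AUC (equal to the concordance
statistic with ties counted ½; scikit-learn's implementation behind the
module surface, cross-checked in tests by brute-force pair counting).
The universe is predicted pairs, each contributing its best score per
method; engines missing a pair contribute their observed floor (their
minimum Z). A per-site mode is exposed. Tier-stratified evaluation uses
one tier's pairs as positives and never-validated pairs as negatives,
excluding pairs validated at other tiers.

## Synthetic fixtures: what they emulate, and what they do not

`generate_fixture` builds a toy genome (single contig, a few kb) whose
transcripts carry annotated, short (<50 nt) and absent UTRs at stated
proportions (defaults 0.75/0.10/0.15, 24 transcripts, 6 miRNAs), plants
seed sites of chosen type for chosen miRNA–transcript pairs (flanking
bases that decide the site class are part of the planted string, so
classification is pinned), adds decoy sites excluded from the validated
tables, and writes validated tables with tier-dependent corruption
(defaults: high 0 %, medium 10 %, low 30 % — chosen to reproduce the
reliability ordering that curated-versus-text-mined sources exhibit, not
any measured rates). `generate_score_benchmark`
draws a latent quality q ~ N(0,1) per pair, engine scores `a·q + noise`
(default a = 1.0/0.8/0.6, unit noise) and labels Bernoulli(σ(2q)).

Passing tests on these fixtures certify the machinery — coordinate
arithmetic, strand handling, score fusion, calibration recovery, the
direction of ensemble and tier effects — under a generative model where
the assumptions hold exactly. They do not certify biological accuracy on
real genomes: real UTRs have composition bias, repeats, alternative
polyadenylation and conservation structure that the uniform-random toy
genome lacks, and real validated databases have correlated, biased
coverage rather than independent per-tier corruption.

## Numerical choices and degenerate inputs

- Ties in the mode statistic → smallest length; ties in ranking → fixed
  lexicographic order; grouping is independent of input order.
- Zero score variance or a single prediction per engine is an error
  naming the engine (standardization undefined).
- Engines with zero predictions are skipped in calibration with a
  warning; group members from uncalibrated engines fall back to ε.
- ROC requires both classes; single-class input is an error.
- Problem sizes in tests and the acceptance script (24-transcript
  fixtures, 2 000–10 000-pair benchmarks, 400 000-sample Monte-Carlo
  truth curves) were chosen so the statistical checks have comfortable
  margins while the whole suite runs in well under a minute; they are
  package defaults, not tuned quantities.

## Known limitations

- No bit-compatibility with any published predictor; the engines
  implement the mechanism families, with their own documented parameters.
- No intramolecular target-structure prediction; accessibility is the
  flank-duplex approximation above.
- No multi-site cooperativity scoring.
- Conservation is an optional precomputed input only.
- Single pooled calibration per run; no per-organism stratification.
- Presumed-negative labeling biases absolute precision/AUC downward;
  comparisons between methods on the same universe remain meaningful.
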