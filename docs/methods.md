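# Methods

## Analysis model

The pipeline treats a comparative profiling experiment as a fixed design:
cell types (tissue origins) × functional states × biological replicates,
each sample fractionated into cytoplasm, secretome and nuclear extract.  Its
input is a table of scored peptide-spectrum matches (PSMs), not spectra; the
search engine that produced the scores is outside the model.

**PSM acceptance.**  A PSM is accepted when score > 13, or when
9 ≤ score ≤ 13 and all three reference-match flags (precursor *m/z*,
retention time, MS2 pattern) are set.  "Above 13" is read strictly, and the
rescue window as a closed interval, so a score of exactly 13.0 passes only
through the rescue tier; both cut points are configurable
(`FilterThresholds`).  Decoy PSMs — from full sequence reversal, one decoy
per target — pass through the same rule, and FDR is estimated as accepted
decoys / accepted targets (D/T).  The alternative 2D/(T+D) estimator is
available but not the default; with the default score models the two are
indistinguishable at the reported precision.

**Protein inference.**  Accepted peptides are mapped to every database
protein whose in-silico tryptic digest contains them (exact peptide match,
not substring search, so a non-tryptic fragment never maps).  Peptides
matching no protein go to an orphan list and are excluded, never silently
dropped.  Inference is the minimal-explanation set cover, computed *per
sample*, by greedy selection with ties broken toward the lexicographically
smaller accession — deterministic and reproducible.  An exhaustive solver
(`infer_proteins_exact`, feasible to ~20 candidate proteins) certifies
minimality and serves as the oracle in tests; greedy matched the certified
minimum on ≥ 90% of random benchmark instances and is guaranteed to cover.

**Evidence rules.**  After inference, a protein is retained in a sample when
it has ≥ 2 distinct peptides there, or exactly 1 while reaching ≥ 2 in at
least one *other* sample of the whole experiment (any sample, not only other
cell types — the more permissive reading of an ambiguous rule).  Proteins
never reaching 2 peptides anywhere are removed everywhere.

**Quantitation.**  Distinct-peptide counts collapse spectral and charge
multiplicity.  The digestion rule is cleave C-terminal of K/R unless
followed by P, 0 missed cleavages for observability counting (configurable
up to any value for sensitivity analysis); peptide masses are monoisotopic
with fixed carbamidomethyl-C (+57.02146 Da), and the observable window
[500, 4500] Da is closed at both ends.  emPAI is computed per fraction and
per replicate, then averaged over replicates ("average emPAI"); the
averaging order is a convention fixed here, since only the average is ever
reported.  Per-fraction profile counts are unions over replicates; the total
is the union across fractions (never the sum).  Replicate aggregation
includes zeros in means; detection in every replicate is "robust", in some
but not all "ambiguous", rendered `(+)` in reports.  The count bins overlap
in their verbal definition ("≥ 6" vs "≥ 15"); they are resolved as the only
disjoint reading: 6–14 → `+++`, ≥ 15 → `++++`.  emPAI-to-color intensity is
the linear map min(emPAI / scale_max, 1).

**Signatures.**  Detection for signature purposes is total count ≥ 1 in any
state of a tissue; an ambiguous `(+)` still counts as detected, but the flag
travels into the report.  Exclusive (one tissue) and shared-pair (two
tissues, absent third) classes are reported separately and never forced into
a partition; all states — control, activated and tumor-associated — enter
symmetrically.

**Differential calls.**  Direction comes from comparing the fraction's count
bins (`-` < `+` < `++` < `+++` < `++++`); proteins undetected on both sides
are omitted.  Significance uses a 1-df goodness-of-fit chi-squared on the
two unrounded replicate-mean counts with equal expected counts
((c + t)/2 per cell) and no continuity correction — the minimal test
applicable when the only inputs are two mean spectral counts.  No
multiple-testing correction is applied by default (per-protein p < 0.05 is
the reporting convention); the calls table carries raw p-values, so any
correction can be applied downstream.  Cross-tissue patterns: any up + any
down → oppositional; uniform → common-up/-down; a proper subset regulated →
tissue-restricted (subset listed).

## Synthetic-data generator

The generator emulates the *statistical* structure of the experiment, at the
PSM/score level — no spectra, peaks or retention times are simulated.

* Database: 400 random proteins of 150–400 residues over the 20 standard
  amino acids, K+R enriched to 12% combined so realistic tryptic peptides
  always exist; the scale is roughly a quarter of a typical single-cell-type
  profile (~1500 proteins), keeping full runs in seconds while preserving
  all the planted structure.
* Planted truth: 20 tissue-exclusive proteins per tissue, 10 per tissue
  pair, 30 core proteins (all samples), 10 inflammation-induced secretome
  proteins per tissue (expressed only in the IL-1β state; expectation 0 in
  control supernatants), 5 tumor markers (expectation 2 in control/activated
  vs 8 in tumor states), 100 background proteins (all samples, expectation
  2–8).  All sets are pairwise disjoint by construction.
* Abundance: per sample, the number of distinct peptides for an expressed
  protein is Poisson around its planted expectation, truncated at the
  protein's observable-peptide total, drawn without replacement from its
  in-window tryptic peptides.  Poisson is a stand-in — replicate variance of
  real spectral counts is not modelled after data.  Planted expectations are
  8 for exclusive/shared/induced proteins (the `+++`-level, ≥ 6-peptide
  detections typical of robustly identified marker proteins) and 6 for core.
* Scores: targets ~ Normal(20, 3), decoys ~ Normal(5, 2), clipped at 0 and
  rounded to 4 decimals (so PSM tables round-trip bit-exactly).  The three
  reference-match booleans are one joint Bernoulli event (probability 0.8
  for targets, 0.01 for decoys) drawn only for scores inside the rescue
  window — real matching tolerances are not published, so the three criteria
  collapse to a single flag.  Decoys are drawn uniformly from the decoy
  digest peptide pool, 60 PSMs per sample.
* Every random draw flows from one integer seed through per-stage
  `numpy.random.default_rng` streams; identical parameters give
  byte-identical outputs at every operation.

What passing tests on this generator show: the pipeline's logic (filtering,
FDR accounting, inference, counting, signature and differential calling)
recovers known truth under a clean generative model.  What they do not show:
robustness to correlated peptide detectability, shared peptides between
homologous real proteins, chimeric spectra, retention-time drift, or
abundance-dependent score distributions — none of which the generator
emulates.

## Numerical and engineering choices

* Peptide monoisotopic masses come from `pyteomics`; the digestion itself is
  implemented in-package because an *ordered* digest with a concatenation
  identity is part of the contract, and is cross-checked against the
  pyteomics cleavage rule in tests.
* Chi-squared p-values use `scipy.stats.chi2.sf`; (c, t) = (0, 0) is an
  error, not a p of 1.
* Tie-breaks (greedy inference, sorting of all outputs) are lexicographic by
  accession, making every artifact deterministic; the pipeline manifest
  content-hashes each file, and a rerun of the same config (output location
  excluded from the hash) reproduces every byte.
* Profile TSVs mirror published supplementary protein lists (accession,
  name, peptides) plus per-fraction columns; an XLSX import shim accepts the
  same layout and refuses — with a log of the observed header — to guess at
  unrecognized columns.
* When analysing an external PSM table, the replicate list per cell state is
  inferred from the table's labels; a replicate contributing zero accepted
  PSMs therefore drops out of mean/robustness denominators.  With a
  simulation block the design's replicate list is authoritative.
* Test and benchmark problem sizes (400-protein database, 27 samples,
  500 parsimony instances of ≤ 15 proteins) were chosen so a full suite run
  completes in well under a minute while exercising every planted structure.

## Known limitations

* No probabilistic protein grouping (EM-style posteriors): inference is the
  minimal-set principle only, so degenerate proteins with identical peptide
  sets collapse to one representative (lexicographic).
* emPAI uses 0-missed-cleavage, charge-state-free observable counts; other
  conventions shift absolute emPAI values (relative comparisons are stable).
* The chi-squared test on two mean counts is a convention, not an exact
  count model; for replicate-level inference a count regression would be
  more powerful, but requires inputs the profile tables do not carry.
* Presence/absence signatures are sensitive to single spurious detections in
  the "absent" tissue; the evidence rules mitigate but cannot eliminate this.
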