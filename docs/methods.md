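# Methods

## The assay being modelled

A host specimen (egg or larva of a lepidopteran crop pest) is extracted
whole; any parasitoid developing inside contributes a small fraction of
the total DNA. A 133 bp COI mini-barcode is co-amplified from host and
parasitoid templates with a degenerate primer pair (forward
`ATTCHACDAAYCAYAARGAYATYGG`, reverse `ACTATAAAARAAAYTATDAYAAADGCRTG`),
sequenced on a multiplexed short-read run, and each specimen is assayed
in 3 independent PCR replicates. Detection of a parasitoid is then a
read-count question complicated by PCR competition (host template in
vast excess), primer–template mismatches, cross-contamination, and
index hopping between multiplexed samples.

## Read processing

* **Primer trimming.** A merged read is accepted when its 5′ end
  matches the forward primer and its 3′ end matches the reverse
  complement of the reverse primer, each with ≤ 2 IUPAC mismatches
  (`PrimerPair.max_mismatch`, configurable; amplicon trimming tools do
  not agree on a canonical tolerance, 2 on a 25–29 nt primer ≈ the
  usual 10% error rate). A mismatch is a template base outside the
  degeneracy set of the primer code at that position.
* **Mismatch geometry.** Mismatch positions are reported from the
  primer 3′ end because extension failure is what kills amplification:
  any mismatch within the 3′-proximal 10 bases sets the simulated
  amplification efficiency to 0; each mismatch outside that window
  multiplies efficiency by 0.9. These two constants are deliberately
  coarse — the modelled phenomenon is the dichotomy "amplifies roughly
  normally vs effectively not at all", which is what a single
  3′-critical mismatch produces in practice.
* **Length filter.** Inclusive bounds, 133 ± 10 → [123, 143].
* **Chimeras.** A dereplicated sequence is flagged when it equals a
  prefix of one ≥ 2×-more-abundant sequence and a suffix of another,
  with both segments ≥ 20 bases exact. This is a deliberate
  simplification of breakpoint-scoring chimera detectors: it captures
  the abundance logic and the two-parent recombination geometry without
  reimplementing a full scoring model.
* **Clustering.** OTUs are grown from unassigned amplicons in
  decreasing abundance order, attaching every amplicon within
  Levenshtein distance d (default 1) of the current frontier. For any
  d this equals the connected components of the distance-≤ d graph; the
  abundance-ordered growth fixes representatives and ids
  deterministically (most abundant member; ties broken by sequence).
  Distances come from edlib.
* **Taxonomy.** The representative is aligned semi-globally (infix)
  within each ~658 bp reference; identity = 1 − edit distance / query
  length. This equals matches/aligned-columns for substitution-only
  alignments and penalises indels conservatively. Best identity ≥ 0.99
  → that species; exact ties → `ambiguous:<species list>`; below
  threshold → `unidentified`.

## False-positive filtering and consensus

`T_CC[o]` is the maximum count of OTU *o* across negative controls;
`T_FA[o] = ceil(r_fa · N_o)` with `N_o` the OTU's run total and
`r_fa = 0.002`. A cell is zeroed when ≤ max(T_CC, T_FA); the "≤"
(rather than "<") guarantees that negative-control columns are
identically zero after filtering, which is tested as an invariant. OTU
rows are pooled by assigned species before the presence test (two
haplotypes of one species support each other), and a specimen is
positive for a species when ≥ 2 of 3 replicates carry pooled reads.

**Known limitation (by construction of T_FA):** the threshold scales
with an OTU's run total, so the more prevalent and abundant a
parasitoid is across the run, the higher the count a single specimen
must exceed. At ~8,000 reads/sample, detection of tissue fractions near
0.001 (≈ 8 reads) is reliable while the OTU's run total stays below
~4,000 reads (T_FA ≤ 8); surveys where one species dominates the run
will lose sensitivity exactly at the smallest fractions. The
parameter-recovery test therefore uses moderate per-species prevalences
(0.10 at n = 400), a regime where the filter's guarantees and its
sensitivity coexist.

## Calibration

Expected read proportion for mass *m* in host mass *M* is *m/(m+M)* (a
proportion must lie in [0, 1]); the conventional relative DNA abundance
*m/M* is reported alongside (0.07 ng in 56 ng → 0.00125, i.e. ~0.001 at
one significant figure). The detection threshold of a species is the
smallest mass of the largest all-positive suffix of its mass-sorted
consensus calls; a stray positive below a negative (never observed in
practice) warns and is ignored, so adding a positive at a larger mass
can never raise the threshold.

## Synthetic-data generator

The generator is the package's test bed and defines the study
conditions; it emulates the statistical structure of the assay, not its
chemistry.

* **Reference set.** One host + N parasitoids, 658 bp each: random
  flanks around a concrete expansion of the forward primer, a 133 bp
  insert, and a concrete expansion of the reverse-complemented reverse
  primer. Species inserts differ from a common ancestral insert at
  pairwise-disjoint position sets of size `max(2, round(divergence·133))`
  (default divergence 0.05), guaranteeing < 99% pairwise identity,
  hence separability at the validity threshold; a divergence below
  2/133 is rejected. An optional cryptic pair differs at exactly 2
  insert positions; an optional primer-mismatch species carries a
  documented voucher binding region whose critical mismatch sits 10
  bases from the reverse primer's 3′ end (efficiency 0).
* **Mock runs.** Per (species, mass, replicate): depth ~
  Poisson(8,000); reads split multinomially between parasitoid
  (weight mass × efficiency) and host (56 ng × efficiency). 10 negative
  controls carry zero template.
* **Field runs.** 4 fields × 100 specimens across 2 sites; stage mix
  0.3575/0.32125/0.32125 (egg/early/late — 143 eggs and 257 larvae per
  400); per-(species, stage, site) Bernoulli parasitism; tissue
  fractions log-normal(μ = −5.267, σ = 0.55), mean 0.006, bulk range
  ~0.001–0.01, truncated to (0, 0.5); with probability 0.05 a
  parasitised specimen gains a second species (multiparasitism).
  Rearing outcome: dead with stage mortality (0.315 eggs, 0.563
  larvae), else the largest-fraction parasitoid emerges (rearing never
  reveals multiparasitism), else the host emerges.
* **Error processes.** Cross-contamination adds
  Poisson(rate × run-mean depth × OTU relative abundance) stray reads
  to every column; index hopping removes Binomial(N_o, rate) reads per
  OTU without replacement (multivariate hypergeometric across source
  columns) and reassigns them uniformly, conserving per-OTU totals
  exactly.
* **What it does not emulate.** Sequencing quality scores, paired-end
  structure, PCR competition beyond fixed efficiencies, chimera
  formation, tag-jump mechanisms beyond the uniform reassignment, or
  between-replicate pipetting variance. Passing tests therefore show
  that the *inference* machinery is correct under the stated error
  model, not that any particular wet-lab run meets the model.

## Problem sizes and determinism

Simulated runs use the design scales throughout: 4 masses × 3
replicates (+10 controls) for dilutions, 400 specimens × 3 replicates
for field runs, ~8,000 reads per replicate. The headline calibration is
repeated over 21 seeds and summarised by the modal threshold; every
random draw flows from a single `numpy.random.default_rng(seed)`, so
identical seeds give byte-identical artifacts.

## Design choices on genuinely open points

* The mortality conventions are exposed as two explicit denominator
  modes reported with numerators and denominators, rather than as
  opaque labels, because "including mortality in the calculation" is
  ambiguous between conventions; nothing downstream depends on the
  label.
* Proportion comparisons default to the Welch unequal-variance t-test
  (fractional degrees of freedom), with a paired Wilcoxon rank test
  available; per-field rates are the ANOVA unit.
* T_CC uses the maximum (not a quantile) of negative-control counts:
  conservative and guarantees clean controls.
* Count-level simulation is the default test path; read-level emission
  (`emit_reads`) exists to exercise the full read pipeline and is
  exact (optional uniform substitution errors).
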