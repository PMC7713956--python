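# Methods

## Model of chromosomal drive in ZW meiosis

Female birds (ZW) produce one oocyte and three polar bodies per
meiosis, so a centromere variant can bias its own retention.  The
simulator models each chromosome as a four-chromatid bundle:

* **Meiosis I (centromeric drive).**  The homolog whose centromere is
  of the focal (Australian) origin is retained with probability `d`
  (`0.5` = fair).  In males all four products become sperm; `d` is
  forced to 0.5 and a configured male drive raises an error — male
  biases would be post-meiotic (sperm competition, fertilisation) and
  are outside the model.
* **Crossovers.**  The default model places one obligate crossover per
  bivalent, uniform on the arm, between one randomly chosen chromatid
  of each homolog.  With arm length `L = max(50, distal cM)` this makes
  the recombination fraction of a marker at `m` cM equal `m/(2L)`, so a
  50-cM distal marker has r = 0.5 exactly — the property the marker
  panel is designed around.  The alternative `poisson` model draws
  crossover counts at bundle rate `L/50` with random chromatid pairs,
  which reproduces Haldane's map function
  `r = (1 − e^(−2m/100))/2`; the cytological interference regime of the
  real map is unknown, so both models are declared assumptions.
* **Meiosis II (distal/neocentromere drive).**  After MI the retained
  dyad consists of one plain and one exchange chromatid.  Only when a
  crossover between centromere and distal locus has made the dyad
  heterozygous there (probability `m/L` under the obligate model) does
  MII drive act: the chromatid with the focal origin is retained with
  probability `d`; otherwise segregation is fair.  This mirrors the
  neocentromere mechanism, which requires exactly such a crossover.
* **Sex.**  The maternal Z/W segregation (fair by default,
  configurable) fixes each offspring's sex; daughters are hemizygous at
  Z-linked markers and their W slot is written explicitly (−1).

Closed forms used as test oracles follow directly: a centromeric-drive
signal at a marker `m` cM away is diluted to `d(1−r) + (1−d)r`, and an
MII-only drive gives `(m/L)·d + (1−m/L)·0.5` at the distal locus while
leaving the centromere at 0.5.

## What the synthetic cross emulates

Defaults reproduce the study design: 2 contributing Timor founders
(one of each sex, one of them carrying heterozygous Australian
segments over 4.78 % of the diploid genome), a pool of 100 Australian
founders, 11 F1 (7 m / 4 f), ~443 BC1-generation egg samples with 51
adults (26 m / 25 f) of which 41 (18 m / 23 f) breed, ~905
BC2-generation samples, and 56 markers on 29 chromosomes (29
centromeric, ≤ 27 cM, median 0; 27 distal, ≥ 18 cM, median 50;
inter-marker distance ≥ 17 cM; the Z carries both marker types).
Egg counts per pair are scaled by 1/(1 − 0.12) and each egg is
independently infertile with probability 0.12, so realised sample
counts fluctuate around the targets.  Allele pools are 8 Australian
and 3 Timor lengths per locus (the two-founder bottleneck keeps Timor
diversity low), with 10 % of markers sharing one length between pools.

Nuisance processes: allelic dropout (2 % of genotypes become apparent
homozygotes), genotyping failure (1 % of records), chromosomal
abnormalities (~2.9 % of embryos split over triploidy, trisomy,
haploidy, monosomy, tetraploidy with an MI/MII/polyspermy mechanism
mix, matching the observed 39/1,359 rate), and an optional
inbreeding penalty that kills offspring homozygous identical-by-state
for an Australian allele — which biases survivor-only counts below 0.5
without any drive, the confound the male-background design addresses.
Abnormal chromosome sets are constructed from the logged meiosis (an
MI error adds a chromatid of the other homolog, an MII error the
sister chromatid, polyspermy an independent sperm), restricted to
autosomes except haploidy.  Every event lands in the truth log.

What the generator does **not** emulate: genotyping length artefacts
(stutter, size homoplasy beyond the configured overlap), heritable
null-allele lineages (dropout is per-genotype), linkage between
markers on different chromosomes, selection on adult phenotypes, and
post-meiotic male biases.  Passing tests therefore demonstrate that
the inference machinery is correct and calibrated under the declared
generative model, not that real microsatellite data are free of
artefacts the model omits.

## Counting rules

Allele origins come from the founder pools; a length observed in both
pools (or only in descendants) is AMBIG, and transmissions involving
it are excluded and ledgered (`ambiguous_policy="founder_label"`
resolves shared lengths by majority founder pool instead).  A parent is
focal at a marker iff it carries two distinct observable alleles, one
Australian and one Timor; heterozygous-with-null parents are excluded.
A pair is *fully informative* iff every producible offspring genotype
determines the focal transmission uniquely — decided by enumeration,
not by a constellation table.  The single partially informative case
is AB×AB (both parents carry the same two lengths): homozygous
offspring yield one record per hybrid parent, heterozygous offspring
are ambiguous and never counted.  ZW females are hemizygous at
Z-linked markers, so Z-linked transmission is effectively tested in
males only; the W is treated as a null allele.  Offspring with a
chromosomal abnormality are dropped for the affected chromosomes iff
the contributing parent is a hybrid or backcrossed bird.  Dead embryos
and chicks with genotypes count exactly like survivors.  Null alleles
are inferred conservatively from trios: a slot is rewritten to NULL
only when no assignment of observed alleles explains the trio and a
single hidden allele in one specific genotype resolves it; when the
dropout could sit in either of two genotypes no call is made
(precision over recall — verified as precision 1 against the truth
log).

## Statistics

* `k = successes/n` with a Wilson score interval.
* Exact two-sided binomial test against p0 using the central
  (doubled-tail) definition, capped at 1 — it matches the sign symmetry
  of the offset-GLM Wald test; the minimum-likelihood definition is
  available behind a flag.
* Offset GLM: `logit P(AUS) = logit(p0) + β₀`; the MLE is analytic
  (`β₀ = logit(k) − logit(p0)`, `SE = (n·k·(1−k))^(−1/2)`).  At a
  boundary count (0 or n) the report switches to a profile-likelihood
  interval and a likelihood-ratio p-value.
* Binomial GLMM: groups (markers or individuals) carry a Gaussian
  random intercept on the logit scale; the marginal likelihood is
  maximised by adaptive Gauss–Hermite quadrature (20 nodes, Newton
  mode-finding per group, exact σ = 0 limit equal to the offset GLM).
  Rows sharing a group share one intercept, so the eight-level
  generation × position × sex fixed effect (cell-means coding) is
  integrated jointly per marker.  The population-level k is reported at
  the conditional mode (u = 0); marginal and conditional scales differ
  when σ > 0.
* Background rate p0: population-level estimate of the male-parent
  marker-random-intercept model (raw pooled proportion available); it
  is then used as a plug-in offset, mirroring conventional practice —
  its sampling error is not propagated.
* Random-effect LRT: both the nominal χ²₁ p (the convention of the
  GLMM tooling this replaces) and the boundary-corrected
  ½χ²₀ + ½χ²₁ p are reported.
* Level contrast: Wald test of one eight-level coefficient against the
  transmission-weighted mean of the other seven, with the contrast
  vector in the output.  The weighting is a declared choice; the
  fixed-effect covariance comes from finite-difference observed
  information at the optimum with σ held at its estimate.
* Power: `h = 2asin√k − 2asin√0.5`, two-tailed normal power, solved
  for k by bracketing; cross-checked against exact binomial power
  (agreement within 0.003 in k for n ≥ 500).
* Multiplicity: nominal p-values by default; the Bonferroni ledger
  (markers × generations × sexes × analysis variants) is computed on
  demand.
* Sex ratio: FMR = n_F/n_M with a delta-method interval on log FMR and
  an exact binomial p.

## Numerical and design choices

* Seeds: one root seed; the simulator draws per-pair streams from it,
  so a pair's offspring are reproducible given the preceding
  construction order.  All pipeline outputs are byte-identical under a
  fixed seed.
* Anomaly-screen thresholds (≥ 2 chromosomes with 3 distinct alleles ⇒
  triploidy, etc.) are configurable artifact choices; without dosage
  information, isodisomic MII errors in homozygous parents are
  undetectable, so calls carry an informative-marker count.  Mechanism
  classification uses centromere-linked markers (≤ 5 cM) where the
  contributor is heterozygous and shares no length with the partner.
  Dropout can mimic monosomy (two masked genotypes on one chromosome);
  monosomy calls therefore carry a caution note, and the
  zero-false-positive guarantee is stated for dropout-free data.
* Problem sizes in the test suite: Monte-Carlo meiosis checks use
  10⁵ gametes (±3–3.5 SE bands); calibration uses 10,000 markers of
  n = 350; drive recovery uses 100 study-scale replicates; GLMM σ
  recovery uses 20 replicates of 56 × 350.  These sizes make the
  binomial noise floors at least threefold smaller than the effects
  asserted.
* Embryos of unknown sex: the simulator sexes every fertilised egg
  (genetic sexing), leaving only infertile eggs unsexed; at Z-linked
  markers a deduction that would depend on an unknown offspring sex is
  treated as ambiguous.
* Both hybrid parents of an AB×AB homozygote each contribute a record;
  in the emulated design the partner is always a pure Australian bird,
  so the double-hybrid case arises only in constructed data and is
  flagged.

## Known limitations

Origin labels rest on founder genotypes: introgression predating the
cross (emulated at 4.78 %) mislabels a small fraction of alleles, and
the default policy can only exclude lengths seen in both pools, not
detect a truly novel admixed haplotype.  The GLMM assumes a Gaussian
random intercept on the logit scale.  Monosomy/haploidy detection
without dosage is heuristic.  Power formulas treat transmissions as
independent Bernoulli trials, ignoring the pedigree's clustering.
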