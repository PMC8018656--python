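# Methods

`bonecheck` implements the analytical core of a mixed-methods
compliance protocol for an annual export quota of captive-bred lion
skeletons: molecular species verification, STR-based individual
matching between source-farm and port-of-exit samples, and a
skeleton-weight audit. Because the casework genotype and weight data
behind such audits are confidential, the package pairs the analysis
with a synthetic-cohort generator whose defaults encode the audited
quota year's conditions, so every method can be validated against
known ground truth. This note records the models, the parameter
choices and their rationale, the numerical decisions, and what the
synthetic validation does and does not establish.

## Synthetic cohorts

**What is emulated.** One quota year: `quota_size = 800` tagged
skeletons distributed over `n_facilities = 7` farms (farm = trader
here), shipped in consignments of `consignment_size = 50`, with a
`spot_fraction = 12.5%` port spot-check allocated per consignment by
largest remainder with at least one sample per consignment (total =
⌈spot_fraction × quota⌉). Genotypes are drawn under Hardy–Weinberg from
an 18-locus STR panel with 5–11 alleles per locus (allele count uniform
on that range; frequencies Dirichlet(1,…,1)); each sample also carries
calls at three diagnostic mtDNA SNP loci. Planted anomaly classes
mirror those observed in real audits: a non-target species (tiger
genotype and SNP profile under a lion tag), a reassigned tag (port
sample carrying tag *t* but the genotype of a different individual from
the same facility), pooled port samples (genotype of an individual
absent from every farm sample), and duplicate farm tags (two tags, one
genotype). The non-target tag is excluded from the port spot-check set:
in the emulated protocol that skeleton is intercepted before export, and
it is counted as a farm anomaly. A machine-readable truth table records
every planted class.

**Species divergence.** The `divergence` parameter sets the fraction of
each locus's allele universe that is private to one species (split
evenly, disjoint, by masking the other species' frequencies to zero and
renormalizing; `divergence = 0` leaves the two frequency tables
identical). The default is 0.8, calibrated so that 20+20-individual
reference panels drawn from the two species show ≈ 73 % private alleles
— matching the observed composition of real lion/tiger reference
panels at comparable markers, where roughly 72 % of alleles are
species-specific.

**Weights.** Farm weights are truncated normal, mean 16.6 kg, SD
5.5 kg, floor 5 kg (observed skeletons run ≈ 6–38 kg, so a hard
positive floor is required; the true distribution shape is not known —
truncated normal is an assumption). Port nett weight is the farm weight
times a desiccation factor (default 0.88 ± 0.03: skeletons are cleaned
and dry between inspections; reported reductions run ≈ 12–15 %, and the
factor is exposed as a parameter rather than fixed); gross weight adds
packaging (1.1 ± 0.1 kg). Inflation can be planted per tag to exercise
the audit flag.

**Genotyping error** is applied after truth assignment: per-allele
dropout (allele set to the missing code 0) and per-locus false-allele
replacement. Both default to 0 so that recovery tests are exact; the
matching layer absorbs dropout through its mismatch tolerance instead.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no kinship structure (captive cohorts
contain relatives; the matching floor `r ≥ 0.9` is designed to reject
full sibs at r ≈ 0.5, but this is only exercised against unrelated
simulants), no population substructure or null alleles within species,
no locus-specific error profiles, no missing-record patterns beyond
random dropout, and idealized SNP calls (fluorescence-to-call mapping
is upstream). Real-data performance therefore depends on marker QC
confirming panel behaviour (HWE, LD, null-allele estimates) before the
matching guarantees can be trusted.

## Species assignment

First pass: unanimity over the determined mtDNA SNP calls; any
disagreement, or no determined locus, is INCONCLUSIVE and triggers
nuclear follow-up. Nuclear evidence combines (i) species-private
allele counts from the reference panels and (ii) a supervised
admixture estimate: q maximizes `Σ log(q·p_lion + (1−q)·p_tiger)` over
all typed allele copies (≥ 5 loci required), by grid search on [0, 1]
with step 0.001. The grid argmax is reported as the mean of the
maximizing set, which makes panel swapping map q → 1−q exactly; a flat
curve (indistinguishable panels) is flagged and q reported as NaN.
Unseen-allele frequencies are floored at ε = 1/(2n+1) for an
n-individual panel (ε = 1/41 behind parametric tables), penalizing
foreign alleles without −∞ log-likelihoods. Thresholds: LION for
q ≥ 0.95, TIGER for q ≤ 0.05, HYBRID_SUSPECT between — or whenever a
sample carries private alleles of both species, or the mitochondrial
and nuclear calls conflict (mtDNA is maternal and cannot exclude
hybridity alone). HYBRID_SUSPECT is an escalation category, not a
definitive call. The supervised grid search replaces unsupervised MCMC
clustering deliberately: reference panels exist by construction, the
estimate is deterministic, and the likelihood is exact at desk scale.

## Marker validation

Per locus, with allele frequencies p and power sums a_k = Σp^k:
A_e = 1/a₂, H_E = 1 − a₂ (uncorrected, so the identity PIC ≤ H_E holds
exactly; the 2n/(2n−1) small-sample correction is available as an
option), PIC = 1 − a₂ − Σ_{i<j} 2p_i²p_j², PID = a₄ + Σ_{i<j}(2p_ip_j)²
with the cumulative PID the product across loci (locus independence
assumed — LD testing backs this), and the Chakraborty null-allele
estimate max(0, (H_E−H_O)/(H_E+H_O)) (a different published estimator
was used in the original casework software; its internals are not
reproducible, so the substitution is deliberate and documented).
Exclusion probabilities are *defined operationally*: Pe1 is the
probability a random unrelated candidate parent is excluded when the
other parent is known; Pe2 the probability a random unrelated candidate
pair is excluded as the parents of a random offspring. Both are
computed by closed forms in power sums —

    Pe1 = 1 − 2a₂ + a₃ + 2a₄ − 3a₅ − 2a₂² + 3a₂a₃
    Pe2 = 1 + 4a₄ − 4a₅ − 3a₆ − 8a₂² + 8a₂a₃ + 2a₃²

— whose coefficients were derived by exact least-squares against the
genotype-configuration enumeration (kept in the package as the
authoritative oracle; the two agree to < 10⁻¹² for ≤ 10 alleles,
consistent with the Jamieson–Taylor family of formulas). The
operational definition sidesteps the ambiguity between textbook
variants of "one parent known".

The exact Hardy–Weinberg test conditions on allele counts (Levene):
the p-value is the total conditional probability of genotype tables no
more probable than the observed one, by full enumeration when the
margin-compatible table count is ≤ 10⁶, else by Monte-Carlo over
random pairings of the 2n allele copies (default 10⁵ reps, seeded;
p = (1 + hits)/(reps + 1)). Log-probability ties use a 10⁻⁹ tolerance.
LD uses a G-statistic on the two-locus genotype contingency table with
a permutation null (p = (1 + #{G* ≥ G})/(reps + 1)). The genotype
accumulation curve resamples locus subsets of each size and counts
distinct multilocus profiles, treating missing loci as wildcards
(greedy grouping; exact when data are complete).

## Individual matching

Queller–Goodnight relatedness, symmetrized and combined across loci as
a ratio of sums: per locus with x = {a,b}, y = {c,d},
num_x = ½(δ_ac+δ_ad+δ_bc+δ_bd) − p_a − p_b and
den_x = 1 + δ_ab − p_a − p_b; r_xy = Σnum_x/Σden_x, and
r = ½(r_xy + r_yx). For identical genotypes num = den per locus, so
r = 1 exactly (bitwise, since the same floating-point operations
produce both sums). Loci where both directional denominators vanish
carry no information and are skipped; if one direction's denominator
*sum* is zero (possible only in near-degenerate panels), the defined
direction alone is reported. Reference frequencies come from the full
farm cohort of the year, without dyad exclusion — stable at n ≈ 800.

Each port sample's null set is its relatedness to all farm samples of
its year. Rosner's generalized ESD test (two-sided, α = 0.05,
k_max = 5) flags outliers; only flags above the cohort mean can be
matches. Decision rule: the same-tag farm sample flagged and maximal
⇒ MATCH; otherwise a flagged different-tag sample with r ≥ 0.9 ⇒
REASSIGNED (facility recorded, cross-facility noted); otherwise
NO_MATCH. The 0.9 identity floor separates same-individual (r = 1 up
to genotyping error) from close kin (full sibs r ≈ 0.5), which captive
cohorts may contain; k_max = 5 bounds the number of near-identical
relatives a sample can plausibly have. All three knobs are
configurable: the original protocol's published description fixes none
of them, so these are declared package choices. Duplicate farm tags
are genotype-identity groups at a mismatch tolerance (default 0;
tolerance 1–2 absorbs dropout), weighted by pairwise r and the
cumulative PID. Classification: reassignments are Type II
(mislabelling / tag-swapping); no-matches and duplicates are Type I
(bone pooling); non-target species are counted separately as
interceptions.

## Weight audit

The flag rule applies to nett (packaging-corrected) port weight: flag
iff port nett − farm > 0.6 kg. The protocol's threshold is stated
without nett/gross qualification, so the nett reading is declared and
the correction configurable (recorded per-skeleton packaging when
available, else a trader-mean default). No multiple-testing correction:
a flag triggers investigation, not a statistical claim. Cohort-level
checks: paired t-test of farm vs port means, one-way ANOVA of weights
by trader. Consignment regressions are OLS of skeleton count on nett
consignment weight, stratified by year group, with OLS prediction
intervals; estimates across year groups emit a warning because mean
skeleton weight drifts between years. Note the deliberate axis choice
(count on weight, matching how such audits are read) puts the sampling
noise in the predictor; the resulting attenuation is ≈ 1–2 % at
realistic consignment sizes and is covered by the reported slope SE.

## Pipeline and determinism

Stages run in hard order: species gating → duplicates → matching →
weight audit → anomaly ledger. The ordering encodes the interception
logic — species results must precede export authorization. Errors
(e.g. a weight-manifest tag with no genotype) accumulate into the
report instead of aborting. All randomness flows from explicit seeds
via numpy Generators; the JSON report contains no timestamps and is
byte-identical on rerun (the custody manifest, a separate artifact,
does carry a timestamp alongside the stable SHA-256 digests).

## Validation scale

The test suite and `scripts/acceptance.py` run at the study scale the
methods are designed for — 800-skeleton cohorts, 18 loci, 20-seed
recovery sweeps, 500-seed calibration of the HWE p-value distribution
(n = 100 diploids at a 4-allele locus, where the discrete conditional
null is fine-grained enough for the uniformity property), 1,000-replicate
species-assignment checks — sizes chosen so each property is measured
with meaningful statistical resolution while the full suite completes
in well under a minute of compute per component.

## Known limitations

- Identity matching only: the pipeline does not infer kinship classes
  (parent–offspring vs full-sib), estimate backcross generations, or
  distinguish F1 from F2 hybrids.
- The admixture estimator is supervised and two-species; it cannot
  discover unexpected source populations.
- PID assumes locus independence and no inbreeding; PID_sib and
  F-statistics are out of scope.
- Weight-based inference is within-year only; cross-year regressions
  are deliberately warned against rather than modelled.
- The anomaly taxonomy records all applicable classes per sample; when
  multiple irregularities coincide the interpretation (Type I vs II) is
  reported per class, not adjudicated.
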