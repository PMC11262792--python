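# Methods

This note documents the models implemented in `mirseed`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Seed-site model

A mature miRNA recognises a target mainly through its seed, nucleotides
2–7/2–8 at the 5' end. The scanner matches the five canonical site
classes by exact string comparison of the reverse-complemented seed
against the 3'-UTR (DNA alphabet): 8mer, 7mer-m8, 7mer-A1, 6mer and
offset-6mer, defined off miRNA positions 1–8 as in the README table. The
"A1" adenosine is required to be a literal A in the target, not a base
complementary to miRNA position 1 — the canonical definition, reflecting
that A across from position 1 is recognised by Argonaute itself.

Although the 6mer core is often described as "nt 2–7", the 7mer/8mer
classes necessarily reach position 8; the implementation therefore
derives all five motifs from positions 1–8 and treats the 2–7 phrase as
describing the core only.

Matches are grouped by *seed register*: the anchor is the UTR index of
the base facing miRNA position 2, shared by every mode that matches in
the same register. One locus is reported per anchor, labelled with the
highest-priority matching mode; `all_modes` retains the rest, and the
per-mode coordinates are recoverable exactly (`SeedSite.mode_spans`).
This avoids double counting in downstream tallies while preserving the
full "all pairing options" information. Overlapping loci of the same
miRNA are all reported (no greedy masking) because the cooperative-site
feature needs them. Loci overlapping `N` can never be reported since
matching is exact over {A,C,G,T}.

Scope limits: no non-canonical sites (3'-compensatory, centred, bulged
seeds), no thermodynamic duplex folding, no context++-style composite
score — features are reported independently and target selection is left
to the analyst.

## Binding-context features

* **Local AU content** — fraction of A/T among up to 30 nt on each side
  of the site (60 nt total window, site excluded, truncated at UTR
  boundaries, `N` in neither numerator nor denominator). A site spanning
  the whole UTR returns an undefined marker (`None`), not 0. Flank size
  is a parameter.
* **3'-supplementary pairing** — the longest run of contiguous
  Watson–Crick pairs between miRNA positions 12–17 and the UTR region 5'
  of the site, in the seed-anchored antiparallel register with a target
  offset tolerance of ±2 nt. The window is the canonical supplementary
  region; window and tolerance are parameters.
* **Position** — distance from the stop codon (UTR position 0) to site
  start, distance from site end to the UTR 3' end, relative position
  min(d_stop, d_end)/length ∈ [0, 0.5], and a near-stop flag
  (d_stop < 15 nt). The distance and flag are reported without a
  favourable/unfavourable valence.
* **Cooperative sites** — unordered pairs of sites on one UTR (same or
  different miRNA) whose gap, measured end-of-upstream to
  start-of-downstream, lies in [8, 40] nt; the range is configurable and
  the default reflects the inter-site spacing at which cooperative
  repression is typically observed.

## Conservation

Two mature miRNAs belong to one seed family when nucleotides 2–8 are
identical (7mer seed match); a miRNA is conserved between species when
the other species' set contains a member of its family. Arm annotation
(-5p/-3p) and the rest of the sequence are deliberately ignored; id
pairs are reported so borderline cases can be inspected. Tallies are
emitted both per family and per mature miRNA of the query species.

## Interaction store

A single flat SQLite table (mirna_id, gene_symbol, source, evidence,
db_origin) with uniqueness over all five fields, so records differing
only in evidence class are kept distinct and re-imports are idempotent.
Gene symbols are upper-cased on import; species context travels in the
miRNA id prefix. `verify_against_utrs` re-runs the scanner per stored
pair and reports whether any canonical site exists and the best mode;
records without a UTR are flagged `no-utr` rather than dropped. The
manual, literature-based triage step that follows such a lookup in
practice is not modelled — only the evidence tag field represents it.

## Association screen

Models are single-miRNA with fixed covariates (NAS, age, sex, BMI); a
response that is itself a covariate (e.g. NAS) is removed from the
design. Continuous traits use OLS; T2D uses a logistic model fitted by
Newton/IRLS (tolerance 1e-8, max 100 iterations) via statsmodels. The
association call uses the Wald p-value of the miRNA coefficient at
α = 0.05. Non-converged or perfectly separated logistic fits are flagged
and never contribute associations. Missing phenotype values are handled
by per-model complete-case deletion with the n used recorded.

Filters and rules:

* **DABG**: a probeset is expressed iff strictly more than 50% of its
  probes have detection p < 0.05.
* **Expression filter**: a miRNA is confidently expressed iff its
  maximal group-mean log2 value is strictly above 2.3.
* **Confounder checks**: age and BMI are modelled with HbA1c, sex and
  the respective other confounder as covariates; a p < 0.05 miRNA
  coefficient raises the flag. Sex is coded 0/1; the mapping affects
  only the sex coefficient, not the miRNA effect.
* **Candidate rule**: expressed ∧ ≥ 2 associated responses ∧ no age/BMI
  flag ∧ (optionally) conserved. "Multiple associations" is
  operationalised as ≥ 2 distinct responses with the threshold exposed
  as a parameter; requiring T2D among them is optional and off by
  default. BH q-values are computed per response family across all
  tested miRNAs and reported, but raw p-values drive candidacy — at
  typical cohort sizes the FDR-adjusted screen is empty and the
  rule-based selection is the operative procedure.

BH-FDR is delegated to `statsmodels.stats.multitest` behind
`assoc.bh_fdr`; the test suite checks it against an independent
brute-force step-up implementation.

## qPCR

ΔΔCt uses group means of per-sample ΔCt (not means of per-sample folds),
so one fold change is produced per group contrast. Outlier exclusion is
a single pass: mean and SD of ΔCt are computed once over all samples of
the gene pooled (both groups together), and a sample is excluded iff its
deviation is strictly greater than 3 SD — a value at exactly 3 SD is
"within the interval" and kept; the multiplier is configurable. With
fewer than 3 samples the filter is skipped with a warning. Adjusted
correlations residualize both variables on the adjusters by OLS and
compute Pearson r on the residuals (partial correlation); with no
adjusters this is numerically identical to plain Pearson. No
amplification-efficiency correction (Pfaffl) or standard curves.

## Synthetic generators

All generators are pure functions of their arguments and a seed
(byte-identical reruns) and emit a truth object sufficient to score
downstream modules.

**UTRs** (`gen_utrs`): i.i.d. background with adjustable GC (no
dinucleotide structure — adequate for oracle testing, not for motif
statistics on real UTRs). Planted motifs are spliced at exact positions
with one deterministic guard base on each side chosen so no
higher-priority mode can form in the same seed register; the planted
label is therefore exact by construction. Background occurrences of
motifs elsewhere are possible and legitimate.

**Cohort** (`gen_cohort`): covariates echo a bariatric-surgery cohort —
age uniform 20–70 y, BMI uniform 32–85 kg/m², sex Bernoulli(0.5), NAS an
integer 0–7 driven by BMI. Continuous traits (HbA1c %, glucose, insulin,
triglycerides in serum units) are linear in the planted miRNA effects
plus a small sex term and Gaussian noise (per-trait scales 0.5, 12, 4,
30 units, times a global multiplier). T2D follows a logistic link over
age, BMI, NAS and planted effects, with the intercept centred to a
target prevalence (default 0.5, mirroring a matched 20/20 design).
Age-proxy miRNAs track standardized age (slope 1.5, residual SD 0.6);
all other miRNAs are independent with means uniform in 4–9 log2 units
and SD 1.2.

A structural point: the continuous traits carry **no direct age/BMI
terms**. The confounder models condition on HbA1c; if HbA1c had both
age/BMI and planted-miRNA parents it would be a collider, and
conditioning on it would induce age/BMI associations for miRNAs planted
as unconfounded — the emitted data would contradict the truth labels.
Age/BMI structure therefore enters only through the T2D response (which
no confounder model conditions on), the NAS–BMI link, and the proxy
mechanism. Consequence for interpretation: passing recovery tests shows
the screen's rules work when the generative assumptions hold; in real
cohorts, strong miRNA–trait effects combined with trait–confounder
coupling can legitimately trigger the age/BMI exclusion, which is a
property of the published selection procedure, not a bug.

**Ct tables** (`gen_ct`): target Ct = housekeeper draw + ΔCt draw, so
housekeeper variation cancels by construction. Outliers are displaced by
8 SD of the pooled ΔCt mixture (within-group variance plus between-group
mean spread), placing them far outside the 3-SD exclusion boundary that
is computed over all samples pooled.

## Problem sizes and numerical choices

The verification experiments use: 1,000 random miRNA/UTR pairs (UTRs up
to 5 kb) for scanner/oracle equality; 100 planted sites across 20 × 2 kb
UTRs for recovery; 20 cohorts of n = 500 with 200 miRNAs (5 planted
candidates with effects 0.6 %-HbA1c, 10 glucose units and 1.0 logit per
log2 unit; 3 age proxies) for candidate recall; 1,000 null miRNAs at
n = 500 for Wald calibration; and 40 + 40 samples with ΔCt 5.0 vs 3.8
(SD 0.2) for the fold-change pipeline. These sizes give tight
Monte-Carlo error while staying desk-scale.

Floating-point: the ΔΔCt closed form is bit-exact only when the planted
ΔCt values are exactly representable and the housekeeper is noise-free
(otherwise `(hk + x) − hk` rounds); tests assert exactness on a dyadic
construction and 1e-12 relative agreement otherwise. OLS coefficients
agree with the normal-equations solution to 1e-8 absolute. Ties and
degenerate inputs: constant responses or constant miRNAs raise a
singular-design error rather than returning meaningless estimates;
undefined AU content returns `None`, never 0.

## Known limitations

* Real 3'-UTR base composition, repeats and secondary structure are not
  modelled; scanner performance on real UTR dumps is exact string
  matching regardless, but context-feature distributions will differ.
* The candidate rules assume complete covariates; there is no imputation.
* The conservation call ignores arm annotation and expression levels —
  it partitions sequence sets only.
* The interaction store does not model per-publication evidence
  normalization or licensing-encumbered database redistribution.
* RMA normalization of raw arrays is upstream of this package: the
  screen consumes a pre-normalized log2 matrix, and the DABG rule
  operates on externally computed detection p-values.
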