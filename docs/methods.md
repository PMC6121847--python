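# Methods

`opsinshift` analyses retinal transcriptome count tables from fish
populations sampled across photic environments and asks whether independent
species changed their predicted visual sensitivity in parallel after
colonizing the same new environments. The motivating system is the
Nicaraguan cichlid radiation — seven species that each occur in turbid
rivers, a turbid great lake (colonized from rivers), and a clear,
short-wavelength-shifted crater lake (colonized from a great lake) — but
every study-specific quantity (λmax values, environment labels, sample
sizes) is data, not code, so the pipeline applies to other taxa.

## Expression measures

For each individual, proportional expression of cone opsin *i* is

    PE_i = reads_i / Σ_j reads_j,   j over the seven cone opsins
           (sws1, sws2b, sws2a, rh2b, rh2aβ, rh2aα, lws)

cyp27c1 and total library size are excluded from the denominator. The
predicted sensitivity index integrates expression with the pigments' peak
absorptions:

    X = Σ_i PE_i · λmax_i   (nm)

With the default λmax table (sws1 360, sws2b 425, sws2a 456, rh2b 472,
rh2aβ 517, rh2aα 527, lws 560 nm — Midas cichlid values, sws1 from Nile
tilapia) X is bounded by [360, 560] nm and is monotone under moving
expression mass toward longer-wavelength opsins. λmax values are a config
TSV so other taxa need no code change. The rh2b value is taken as 472 nm.
Because X is linear in PE, the mean of individual indices in a population
equals the index of the mean PE vector; population-level points use the
arithmetic mean of individual indices (asserted equivalent by a test).

Derived measures: single-cone fraction (PE_sws1+PE_sws2b+PE_sws2a), the
rh2aβ/(rh2aβ+rh2aα) ratio (undefined when neither paralog is expressed —
such samples are dropped from ratio tests only), and the lws fraction.
cyp27c1 — a proxy for vitamin-A1→A2 chromophore conversion, which
red-shifts all pigments — is normalized two ways: reads per million
(absolute; the `total_reads` column is the per-sample count of QC-passed
reads, and whether that is raw or mapped reads is the table producer's
documented choice), and relative to the species' maximum (each species'
highest value maps to 1), which removes among-species level differences
when looking for convergent environmental patterns.

Photon flux conversion for irradiance spectra uses the Planck relation:
watts × λ/(hc) with CODATA constants, giving photons s⁻¹ m⁻² nm⁻¹.

## Rank-based tests

All tests replace values by mid-ranks, so they are invariant to monotone
transformations and robust to the heavy tails of expression ratios.

**Scheirer–Ray–Hare.** The two-factor rank test ranks all N observations,
computes two-way ANOVA sums of squares on the ranks, and refers
H_term = SS_term / MS_total to χ² with (a−1), (b−1), (a−1)(b−1) degrees of
freedom, where MS_total = SS_total/(N−1) is computed from the realized
(tied) ranks and therefore absorbs the tie correction. Sums of squares are
Type II (via OLS on ranks): on balanced designs this equals the sequential
decomposition used by common R implementations, and on unbalanced designs
it is order-independent. A factor with one level is an error pointing the
user to Kruskal–Wallis. A simulation test at the study design size
(7 × 3 cells, n = 5) checks that each term's type-I error is within the
binomial 99% interval of the nominal 5%.

**Kruskal–Wallis per species, with FDR.** Each of four a-priori measures
(single-cone fraction, rh2a ratio, lws fraction, species-relative cyp27c1)
is tested within each species across its environments. The
Benjamini–Hochberg correction is applied per measure across species
(7 tests per family) by default, matching how per-measure significance is
usually annotated; a global family is available by flag.

**Rank maintenance.** Whether species keep their rank order of mean
sensitivity after colonizing a new environment is tested with Spearman's ρ
between species means in the ancestral and derived environment. The
p-value is an exact permutation p — full enumeration of all n! orderings —
for n ≤ 8 (5040 orderings at n = 7; perfect maintenance gives p = 1/5040),
one-sided toward positive association by default since the hypothesis is
maintenance; two-sided is available. For n > 8 the large-sample
approximation is used.

## Parallelism vector test

Each species' phenotypic change per colonization event is a 2-D vector in
(predicted sensitivity index, species-relative cyp27c1) space connecting
the ancestral-environment population mean to the derived-environment mean.
Because nm and relative expression are incommensurable and angles depend on
axis scaling, each axis is divided by the standard deviation of the
population means before vectors are built (`scale="sd"`, the default);
`scale="none"` keeps raw axes. Both modes are first-class since the
appropriate scaling is a modelling choice.

Parallelism is measured by the sums over all unordered species pairs
(21 pairs for 7 species) of (a) the angle between the two vectors
(arccos of the normalized dot product, in [0, 180]°) and (b) the absolute
difference of their lengths. Small sums mean parallel direction and
magnitude of change.

The null randomizes species identity within each environment: in each of
the permuted datasets (999 by default) a pseudo-species' vector connects
one randomly drawn individual from the ancestral environment to one from
the derived environment, and the same pair sums are computed. The p-value
is (k + 1)/(n_perm + 1) where k counts null sums strictly smaller than the
observed sum — "smaller" is strict and ties count against rejection, and p
is never 0. The observed/null asymmetry (means vs single individuals) is
deliberate and preserved as the procedure's definition. The combined scope
adds observed and null sums over both colonization events within each
permutation. Species missing an environment are excluded from the event —
consistently from the observed vectors and from the null pools.
Zero-length vectors have undefined direction: their pairs are skipped in
angle sums and retained in length sums, with a warning.

Under an exchangeable null the direction of a mean of i.i.d. noise has the
same distribution as the direction of a single draw, so the angle test
calibrates despite the mean/individual asymmetry; the length statistic does
not share this property and its null behaviour is assessed only through the
permutation distribution itself. Calibration is verified by simulation
(500 exchangeable datasets; rejection rate within the exact binomial 99%
interval of 5%), and the Monte-Carlo p is checked against exhaustive
enumeration of all (6·5·4)² equally likely null datasets on a 3-species ×
2-individual toy.

## Consensus calling and variable sites

Per-individual consensus coding sequences are called from site-level base
counts: coverage < 10× masks to N; else if the minor-allele frequency
exceeds 0.35 the site is a heterozygote and receives the two-base IUPAC
code; else the majority base is called. Calls depend only on base
frequencies (scale-invariant). Only two-fold ambiguity is supported (diploid
assumption): a third allele above the threshold, or a three-way tie for the
major allele, masks to N with a warning. Indels are out of scope; pileups
are assumed gap-free against the reference.

Translation uses the standard genetic code; a codon with one two-fold
ambiguity expands into both resolved codons (up to two amino-acid states
per site), codons containing N give X, and internal stops are flagged but
translated as `*`. A codon with two heterozygous positions has unknown
phase and is reported as X. A site is "variable within species" when
conspecific individuals — pooled across populations, heterozygotes
contributing both states, X ignored — carry at least two states; both
states are always reported rather than collapsed to one. Per-population
state summaries accompany each site. Residue numbering against bovine
rhodopsin (RH1), the field's convention for opsin tuning sites, is a
user-supplied per-gene alignment table; unmapped positions keep their raw
codon index and are flagged.

In the callable regime — realized minor-allele fraction in (0.35, 0.5] at
coverage ≥ 10 with no sequencing error — heterozygote precision and recall
are exactly 1 by construction of the rule, which a simulation test
confirms. A true heterozygote whose sampled minor fraction falls at or
below 0.35 is correctly (per the rule) called as the majority base; that is
a property of the threshold, not a defect of the caller.

## Synthetic data

The generator emulates the study design: 7 species × 3 environments, 5–6
individuals per population with one population of 3, library sizes
log-normal with median 1.4 × 10⁶ reads. Opsin composition is modelled on
the centred log-ratio (clr) scale, where displacements compose additively
and map back to the simplex by softmax: species baselines are clr-jittered
(σ = 0.4) around a long-wavelength template (most expression in sws2a,
rh2aβ/α, lws), the environment adds a short-wavelength clr displacement
whose magnitude grows river → great lake → crater lake (multipliers 0, 1,
2.5, so the crater-lake shift is largest), and individuals add clr noise
(σ = 0.15). Opsin counts are multinomial given a budget of 0.5% of library
size — an arbitrary but configurable fraction; no proportion-based
statistic depends on it. cyp27c1 counts are negative binomial (dispersion
8) with environment-dependent per-million means peaking in the turbid great
lake (river 25, great lake 60, crater lake 15). The `paper_like` preset
additionally includes one "switch species" that exchanges sws2a↔sws2b and
rh2aα↔rh2b expression in the crater lake, emulating the one species in the
study system that changes its expressed opsin subset as an adult.

Presets: `null` is fully exchangeable (zero shift, zero species jitter,
flat cyp27c1 means) and defines the calibration condition;
`parallel_weak`/`parallel_strong` share the displacement across all species
with small individual noise (strong: magnitude 0.5, noise 0.12, strongly
ordered cyp27c1 means), embodying the "all species move together" condition
the power analysis requires; `paper_like` is the study design. Pileups are
simulated per site by binomial sampling of the two alleles (0.5/0.5) plus a
uniform sequencing-error substitution to one of the other three bases.

What the generator does **not** emulate: mapping ambiguity between the
rh2aα/rh2aβ paralogs (real quantification must use the distinguishable
5′ region because gene conversion homogenized the rest of the CDS),
ontogenetic and diurnal expression variation, correlated noise between
opsins beyond compositional closure, batch effects, and indels or mapping
error in pileups. Passing tests therefore demonstrate correctness of the
statistical machinery under the assumed data-generating structure, not
robustness to these real-data complications.

## Numerical choices and problem sizes

Proportional expression requires at least one nonzero opsin count (error
otherwise); sensitivity-index inputs must sum to 1 within 1e-6; arccos
arguments are clipped to [−1, 1] (pair angles are accurate to ~1e-5
degrees, below any biological signal); permutation p-values use the add-one
convention; all randomness flows through a NumPy `Generator` seeded
explicitly — a missing seed is an error in the pipeline, not a silent
fresh draw. Test simulations use 500 replicates × 199 permutations for
calibration, 200 replicates for power, 300 simulations for the
Scheirer–Ray–Hare calibration and 10⁴ for Kruskal–Wallis; the analysis
drivers use 999 permutations. These sizes give binomial confidence
intervals tight enough for the properties checked while keeping the whole
suite fast.

## Known limitations

- The sensitivity index is a linear summary; it ignores chromophore (A1/A2)
  effects on λmax, opsin coexpression within single cones, and ocular media
  transmission. Microspectrophotometry would be needed for realized
  sensitivities.
- The SRH χ² reference is asymptotic; at very small N per cell the test is
  conservative/anticonservative in the usual ways of rank χ² tests.
- The parallelism length statistic inherits a scale asymmetry from the
  mean-vs-individual null construction; interpret its p-value only against
  the permutation null, not as a calibrated test of "no length difference".
- Exact rank-maintenance p-values are enumerated only to n = 8 species.
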