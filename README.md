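# opsinshift

Analysis pipeline for asking how predictably fish visual systems evolve
when multiple species colonize the same new light environment. Given
per-sample read counts for the seven cichlid cone opsins (*sws1, sws2b,
sws2a, rh2b, rh2aβ, rh2aα, lws*) plus *cyp27c1*, the package computes
proportional opsin expression and an expression-weighted **predicted
sensitivity index**

    X = Σ_i PE_i · λmax_i        PE_i = reads_i / Σ_j reads_j

(nm; λmax from 360 nm for sws1 to 560 nm for lws), runs rank-based
statistics (Scheirer–Ray–Hare two-factor tests, per-species Kruskal–Wallis
with Benjamini–Hochberg FDR, exact Spearman rank-maintenance tests), and
tests for **parallelism** of phenotypic change: one 2-D vector per species
in (sensitivity index, relative *cyp27c1*) space per colonization event,
with the sums of all 21 pairwise angle and length differences compared
against 999 datasets in which species identity is randomized within each
environment. A sequence arm calls per-individual consensus coding
sequences from pileups (10× minimum coverage, heterozygotes at minor-allele
frequency > 0.35 as IUPAC codes), translates them with ambiguity expansion,
and reports amino-acid sites variable within species, numbered against
bovine RH1. A synthetic-data module generates count tables and pileups
with the full study structure (7 species × river/great lake/crater lake),
so every stage runs and is validated without any download.

Intended users: evolutionary biologists and vision scientists working with
retinal RNA-seq count tables from wild populations.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated
data (fixed seed 42) and write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_expression_profiles.py
python analysis/03_rank_tests.py
python analysis/04_parallelism.py
python analysis/05_consensus_variants.py
```

`02_expression_profiles.py` prints the per-environment mean sensitivity:

```
mean predicted sensitivity index (nm) by environment:
  river          521.54
  great_lake     506.21
  crater_lake    483.76
mean cyp27c1 reads per million by environment:
  river           24.69
  great_lake      57.09
  crater_lake     17.46
```

— sensitivity shifts toward shorter wavelengths from river to great lake to
crater lake (the simulated short-wavelength expression shift), while
*cyp27c1* peaks in the turbid great lake. `04_parallelism.py` then reports

```
colonization_1  p_angle=0.003  p_length=0.008  (observed sums: angle=167.4 deg, length=9.83)
colonization_2  p_angle=0.015  p_length=0.002  (observed sums: angle=203.7 deg, length=6.71)
combined        p_angle=0.002  p_length=0.001  (observed sums: angle=371.1 deg, length=16.53)
```

i.e. the 21 pairwise differences between species vectors are far smaller
than under randomized species identity: the simulated species changed in
parallel. `05_consensus_variants.py` plants one heterozygous
nonsynonymous variant in a synthetic population and recovers exactly that
site:

```
codon 3 (RH1 40): states A/S [crater_lake=A/S;river=S]
```

The same functionality is exposed as a CLI for real data:

```bash
opsinshift simulate --preset paper_like --seed 42 --out data/
opsinshift profiles --counts data/counts.tsv --metadata data/metadata.tsv --out profiles.tsv
opsinshift parallelism --profiles profiles.tsv --event combined --n-perm 999 --seed 42 --out par.tsv
opsinshift run-all --config config.yaml
```

Input formats (tab-separated, `#` comments allowed): a count table with
columns `sample_id`, the seven opsins, `cyp27c1`, `total_reads`; metadata
with `sample_id`, `species`, `environment` (river / great_lake /
crater_lake); optionally a λmax table (`opsin`, `lambda_max`) to override
the defaults, pileups (`gene`, `position`, `A`, `C`, `G`, `T`) and an RH1
alignment table (`codon_index`, `rh1_position`).

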