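# dumbopt

A toolkit for two jobs that bracket the heterologous-expression workflow
of a membrane receptor:

1. **Construct design** — codon harmonization by *DUMB optimization*
   (DNA codon usage for measured base optimization): synonymous recoding
   of a human gene for expression in *E. coli* that matches each codon's
   *relative usage* in the host to its relative usage in the native
   organism, instead of simply maximizing codon frequency. Rare codons in
   the native gene are mapped to correspondingly rare host codons, which
   preserves the programmed slow-translation stretches thought to guide
   cotranslational folding of membrane proteins. A fully optimized (FO)
   baseline, a random synonymous control, and %MinMax sliding-window
   profiling (to visualize how far each construct sits from the native
   codon-usage landscape) are included.
2. **Receptor pharmacology analysis** — fluorescence-polarization
   saturation binding with ligand-depletion-aware Kd estimation and
   receptor-orientation correction, and luminescence GTPase
   %-hydrolysis analysis with pairwise significance testing. These are
   the analyses used to establish that membrane cholesterol
   dose-dependently increases a chemokine receptor's agonist affinity and
   G-protein activation.

Intended users: protein biochemists designing expression constructs and
analyzing binding/activity assays, without spreadsheet gymnastics.

## The core quantities

**Harmonization rule.** At codon position *i* with native codon *c*, among
host codons *c′* synonymous with *c* and eligible under the rare-codon
threshold (host relative fraction ≥ τ·native fraction, τ = 0.05 by
default), choose

&nbsp;&nbsp;argmin<sub>c′</sub> | f<sub>host</sub>(c′) − f<sub>native</sub>(c) |

where f(·) is a codon's share of its synonymous family.

**%MinMax.** Per window of W = 21 codons, with window means Actual, Max,
Min, Avg of per-thousand codon usage (codons used / family maxima /
family minima / family means):

&nbsp;&nbsp;%MinMax = 100·(Actual − Avg)/(Max − Avg) if Actual ≥ Avg, else
100·(Actual − Avg)/(Avg − Min) ∈ [−100, +100].

**Binding.** P = (I∥ − I⊥)/(I∥ + I⊥); titration model
P(R) = P₀ + ΔP·FB(f·R, L, K<sub>d</sub>) with the exact one-site
ligand-depletion bound fraction
FB = ((R+L+K<sub>d</sub>) − √((R+L+K<sub>d</sub>)² − 4RL))/(2L)
and orientation factor f (0.5 for proteoliposomes, 1.0 for open discs).

**GTPase.** After subtracting the mean blank,
% GTP hydrolysis = 100·(RLU<sub>std</sub> − RLU<sub>replicate</sub>)/RLU<sub>std</sub>;
pairwise Student t-tests with tiers \* p<0.05, \*\* p<0.01, \*\*\* p<0.001.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

```python
from dumbopt import *

human, ecoli = example_table("human"), example_table("ecoli")

# a 120-codon "native" human-like gene, harmonized for E. coli
gene = generate_gene(GeneGenSpec(table=human, seed=7, length=120))
do = dumb_optimize(gene, human, ecoli)
fo = fully_optimize(gene, ecoli)

native = minmax_profile(gene, human)
print("dist(native, DO) = %.1f" % profile_distance(native, minmax_profile(do.output_sequence, ecoli)))
print("dist(native, FO) = %.1f" % profile_distance(native, minmax_profile(fo.output_sequence, ecoli)))
```

prints

```
dist(native, DO) = 6.4
dist(native, FO) = 79.6
```

— the harmonized construct's host-usage profile sits 6.4 %MinMax points
(mean absolute difference) from the native profile, while the fully
optimized construct, pinned near +100, sits 79.6 points away: full
optimization erases the native rarity landscape, harmonization keeps it.

```python
curve = generate_binding_curve(BindingGenSpec(kd=30e-9, seed=42, noise_sd=0.01))
fit = fit_kd(curve, bootstrap=200, seed=1)
print("Kd = %.0f ± %.0f nM (SE), 95%% CI [%.0f, %.0f] nM"
      % (fit.kd/1e-9, fit.se["kd"]/1e-9, fit.ci95["kd"][0]/1e-9, fit.ci95["kd"][1]/1e-9))
```

prints

```
Kd = 31 ± 6 nM (SE), 95% CI [20, 43] nM
```

recovering the generating K<sub>d</sub> of 30 nM from a noisy 3-replicate
titration at 100 nM labeled ligand. A cholesterol-titration GTPase plate
analyzes to:

```
condition  mean_percent_hydrolysis       sd  n
  0% chol                     38.1     1.6  3
 20% chol                     54.1     1.6  3
 40% chol                     71.4     2.5  3

condition_a condition_b       t        p tier
    0% chol    20% chol  -12.24 0.000256  ***
    0% chol    40% chol  -19.44 0.000041  ***
   20% chol    40% chol  -10.17 0.000527  ***
```

## Command line

```bash
dumbopt harmonize genes.fasta --mode dumb --native-table human --host-table ecoli --audit audit.csv
dumbopt minmax genes.fasta --table ecoli --window 21 --plot profiles.png
dumbopt fit-kd curve.csv --ligand-nm 100 --orientation-factor 0.5 --model depletion
dumbopt gtpase --input plate.csv --test student
dumbopt simulate binding --spec spec.json --seed 1 --out curve.csv
```

Input schemas: codon tables as `codon,amino_acid,usage_per_1000[,rel_fraction]`
CSV; binding data as `receptor_conc_nM,replicate,polarization` (or raw
`I_parallel,I_perp`); GTPase plates as
`well_type{blank|standard|sample},condition,replicate,rlu`.

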