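# Methods

## Founder genomes

Founder haplotypes are drawn from a standard coalescent with a
piecewise-constant effective-population-size history mimicking landrace
demography: Ne = 100 today, rising stepwise to 500 / 1,500 / 6,000 at 100 /
1,000 / 10,000 generations ago and 10,000 beyond 100,000 generations ago.
The boundaries follow the generic crop history encoded in the Markovian
coalescent tooling this trajectory is modeled on (epoch changes at 0.25,
2.5, 25 and 250 units of 4Ne with Ne = 100). The short recent bottleneck
matters scientifically: it leaves many intermediate-frequency variants, and
those are what allow different subpopulations to fix different QTL
combinations later — the allo-elite premise.

The genome is pearl-millet-like: 7 chromosomes, each 1e8 bp and 1 Morgan,
mutation rate 2.5e-8 per bp per generation. Each chromosome is thinned to
exactly 1000 biallelic segregating sites chosen uniformly at random
(seeded); an error names the chromosome if the coalescent yields fewer.
Alleles are coded ancestral = 0 / derived = 1; dosages count derived
alleles. Meiosis is Haldane: Poisson crossover count with mean equal to the
map length, positions uniform on the genetic map, no interference, no
obligate chiasma, random starting haplotype. Because statistics that depend
only on a subset of loci have the exact marginal recombination process on
the restricted site set, family simulation for trait evaluation runs on
panels restricted to the trait's QTL sites (`HaplotypePanel.restrict`).

## Traits

Both traits are strictly additive with equal per-QTL effects.

| parameter | attained (flowering time) | desired (grain yield) |
|---|---|---|
| QTLs | 2 / 4 / 20 (scenario) | 100 |
| per-QTL effect | (window width + 3)/nQTL = 8/nQTL d | scaled so founder CV = 10% |
| founder mean | 55 d | 900 kg/ha |
| variance target | 10 d² (genetic) | (0.10 × 900)² kg²/ha² |
| h² | 0.6 | 0.1 |
| acceptable range | 52.5–57.5 d | — |

QTLs are placed uniformly at random over the site registry, the two traits'
QTL sets disjoint. The intercept anchors the founder phenotype mean to the
target. The "variance of 10" is read as the founder *genetic* variance
target and used only to fix the environmental variance,
Ve = Vg·(1−h²)/h² = 6.67 d²; the per-QTL effects themselves stay at their
equal-effect values (a `rescale_to_target_variance` mode that forces
realized founder Vg onto the target exists but is not the default). With
raw effects the closed-form 2-QTL allo F2 variance is
2·(a²/2) + Ve = 16 + 6.67 ≈ 22.7 d², the algebraic anchor for the
family-variance comparisons.

### Two environmental-variance conventions

`phenotype()` supports two conventions because no single one is coherent
for every stage of the study:

* **fixed** — Ve frozen at its founder calibration. Used for all
  program-simulation decisions (divergence selection, assembly, IPS
  ranking, FPI classification): the trial error a breeder faces does not
  shrink because the population narrowed. Under this convention realized
  heritability drifts as Vg changes. Scientifically load-bearing side
  effect: a constant 6.67 d² error against a 5 d window makes per-locus
  stabilizing selection weak, so drift diversifies the QTL combinations
  fixed by different subpopulations.
* **evolving** — Ve recomputed from the phenotyped cohort's realized
  genetic variance, keeping realized h² at its nominal value while both
  variances shrink across cycles. Used for family evaluation and PRS
  cycles; it is the only convention compatible with near-zero iso-family
  variances and with >94% of 20-QTL progeny falling in a 5-day window.

For family evaluation, each elite type's families are pooled into one
phenotyping cohort (mirroring a 5-pair × 100-individual evaluation trial
per scenario), so an iso cohort's Ve reflects between-family spread while
within-family variance stays near zero.

## Breeding-program trajectory

1. **Divergence.** Five subpopulations of 100, sampled without replacement
   from 500 founders, evolve 50 generations. Each generation all attained
   traits are phenotyped (fixed Ve), individuals outside any window are
   excluded, survivors are ranked by quadratically penalized yield
   (coefficient 2% of target yield per day², floor 0), the top 10% of the
   subpopulation size is kept, and random non-self mating with replacement
   rebuilds the population. Shortfalls fill by smallest total range
   deviation, then yield.
2. **Assembly & purification.** The five subpopulations merge; 200 lines
   within all acceptable windows are sampled, stratified across
   subpopulations proportional to availability, and each is advanced 6
   generations of single-seed descent (residual heterozygosity
   (1/2)^6 ≈ 1.6% of starting heterozygosity).
3. **IPS.** The top 10% of purified lines by penalized-yield phenotype are
   designated elite — the no-inference baseline and the candidate pool for
   pair nomination.

Ground truth for a pair is genotype-state (dosage) identity at every
attained-trait QTL — exactly the criterion QGI applies through IBS = 1 at
the causal markers. Residual heterozygosity is allowed; a shared
heterozygous QTL counts as an identical state, so "iso" families can still
segregate residually, as finite selfing leaves them in practice.

## Inference procedures

* **FPI** builds a fresh 100-individual F2 family per candidate pair
  (half-diallel over the elite set), phenotypes it with the fixed trial
  error, and calls *allo* iff strictly more than 75% fall outside the
  window. The strict reading means a family centered in the window can
  never exceed the threshold on noise alone, so FPI is conservative:
  its errors are nearly always allo-called-iso.
* **QGI** computes pairwise IBS as the fraction of marker sites with equal
  dosage codes (no half-credit for heterozygote overlap) and calls *iso*
  iff IBS = 1 exactly. On the causal QTLs it reproduces the ground truth
  by construction.
* **PGI** centers the genome-wide dosage matrix, projects onto leading
  PCs, scans k = 1..10 with K-means, fits DAPC (PCA → LDA) with the
  retained-PC count maximizing the a-score (observed reassignment minus
  the mean over 10 label permutations; ties → fewest PCs), and nominates
  the closest / farthest pairs on the first two discriminant axes within
  the best-reassigned cluster.

**k selection.** The classic hard-assignment criterion
n·ln(WSS/n) + k·ln(n) over-splits isotropic noise: a K-means split of pure
noise cuts WSS by a roughly dimension-independent factor that always beats
the k·ln(n) penalty at moderate n (it chose k = 5 on two cleanly separated
blobs). The retained k therefore minimizes the BIC of a tied-covariance
Gaussian mixture on the same PC scores, which picks k = 2 on two blobs at
any separation, k = 1 on noise, and k = 3 on three blobs; K-means still
produces the partition at the chosen k.

## Recurrent selection

Cycle 0 founds a 500-individual population from five parent pairs (each:
one F1 → 100 F2 → F5 by SSD). Four attained traits (independent QTL sets,
flowering-time template) plus the desired trait are modeled; each cycle
phenotypes the population (evolving Ve), keeps candidates inside all four
windows, truncation-selects the top 10% of the population size by desired
phenotype among survivors (fewer survivors ⇒ weaker effective selection —
the allo handicap), intercrosses five random non-self pairs, and rebuilds
via the same F1 → F5 route.

Each attained trait carries **4 QTLs** (effect 2.0 d). With 2 QTLs the
equal-effect homozygous-genotype lattice steps by 2·a = 8 d against a 5 d
window, so most runs admit no fully acceptable fixed genotype and "iso
stability" is unreachable; at 4 QTLs the lattice (4 d) is finer than the
window and a reachable optimum exists.

Scenario pairs (iso-same-subpopulation, iso-different-subpopulation, allo)
are QGI calls on the union of the attained QTLs. All scenarios of one
replicate draw from the same candidate pool — elites preferred, all
purified lines when any requested scenario cannot fill its five pairs —
because comparing cycle-10 means across pools founded from different yield
strata would confound the contrast.

## Cost model

Per-line costs are linear: genome-wide genotyping $20/line, QTL assay
$5/line/locus, phenotyping $64/line/environment. Analysis overheads are
free parameters calibrated once so the model reproduces the published
per-line totals (QGI overhead $65 ⇒ $75/$85/$165 at 2/4/20 known loci;
PGI overhead $105 ⇒ $125; FPI program overhead $840 ⇒ $904 per line per
environment; amortized discovery surcharges $768 GWAS / $595 mapping ⇒
$843 / $670). The decomposition is a model, not an audit — the true line
items are not public. The QGI-vs-PGI crossover is
ceil((125 − 65)/5) = 12 loci.

## What the generator does and does not emulate

The synthetic data reproduce the study conditions: stepwise demography,
equal-effect additive architectures, parallel stabilizing + directional
selection, SSD purification, and the family designs. Real data differ in
ways that passing tests cannot vouch for: dominance, epistasis, G×E,
genotyping error, linked (rather than causal) markers, non-Gaussian
environmental error, and seed-exchange migration between landraces are all
absent. QGI's perfection here is a design property (it reads the causal
loci); with linked markers its accuracy would degrade with LD decay.

## Problem sizes used by tests and the acceptance script

The acceptance script runs the full study design (7 × 1000 sites, 500
founders, 5 × 100 subpopulations, 50 generations, 200 lines, 100 F2/F5 per
family): 50 replicates at 4 QTLs and 20 at 20 QTLs. The acceptance test
suite uses 20 replicates per architecture for the stochastic comparisons,
and the recurrent-selection ordering property runs 50 replicates at a
reduced design chosen for desk-scale wall time (3 chromosomes × 300 sites,
250 founders, 4 subpopulations of 60 for 25 generations, 100 purified
lines, 3 pairs × 60 F2 per scenario); the contrast mechanism (filter
survival and pool diversity) is scale-free, only its Monte-Carlo spread
grows at the smaller size.

## Known limitations

* The published iso-family F2 variances (2.54 / 1.24 d² at 2 / 4 QTLs) are
  reproduced only in order of magnitude: under any fixed Ve ≥ 2.5 they are
  impossible (iso families have Vg ≈ 0), and under cohort-level Ve they
  depend on how many distinct in-window QTL classes a replicate happens to
  retain. The allo-family variances and all 20-QTL quantities reproduce
  well.
* FPI accuracy depends mostly on the iso/allo composition of the elite
  half-diallel, not on the threshold — with equal effects, a window-centred
  family essentially never exceeds 75% outside.
* K-means/DAPC results depend on the PC count and k; the a-score guards
  against gross overfitting but PGI remains the least stable approach at
  oligogenic architectures, which is itself one of the study's findings.
* Cost figures inherit their calibration; they generalize only through the
  explicit unit costs.
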