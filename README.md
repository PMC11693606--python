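# fstrat — time-stratified f-statistics on genome-wide genealogies

`fstrat` computes f-statistics directly on dated genealogies (tskit tree
sequences or Relate-style `.anc`/`.mut` text output) and restricts them
to branches younger than a time cut-off.  Coalescences older than the
divergence of two admixing sources carry no information about a recent
admixture event — they only add drift noise — so stratifying on time
concentrates the statistic on the informative recent coalescences and
can shrink standard errors of admixture-proportion estimates by up to an
order of magnitude without introducing bias.  The package is aimed at
population geneticists modelling fine-scale or recent ancestry (for
example from ancient DNA cohorts) with the f-statistics toolbox.

On a genealogy, every branch contributes

    f2(A, B)  +=  [ (w_A - w_B)^2 - h_A - h_B ] * mu * l_eff * span

where `w_X` is the fraction of group X's samples below the branch,
`h_X = w_X(1-w_X)/(n_X-1)` the sample-size correction, and `l_eff` the
branch length clipped to `[t_low, t_high)` (branches crossing a
threshold count only the portion inside).  From block-partitioned f2 the
package derives f3, f4 and the f4-ratio
`alpha = f4(PI,PO;P1,PX) / f4(PI,PO;P1,P2)` with weighted block-jackknife
standard errors, and provides a self-contained admixture-modelling
stack: qpWave rank tests, qpAdm mixture fits with rotational model
search, UPGMA cladality clustering of individuals, outgroup-f3 MDS, and
first-coalescence chromosome painting with constrained NNLS mixture
weights.  An msprime-based scenario catalogue (`fstrat.simstudy`)
generates every validation dataset, so nothing external is required.

## Worked example

Simulate a two-way admixture (sources P1/P2 split 500 generations ago;
PX receives 30% from P2 in a pulse 50 generations ago; 20 haploid
genomes per population, 30 Mb), then estimate the admixture proportion
with and without time stratification:

```python
from fstrat import simstudy
from fstrat.fstats import (AscertainmentSpec, f2_blocks_from_genealogy,
                           f4_ratio_alpha)

cfg = simstudy.build_scenario("f4ratio", sequence_length=30e6)
g = simstudy.simulate(cfg, seed=3)
pops = simstudy.scenario_assignment(g)

for spec in [AscertainmentSpec(mode="genotype"),          # classical
             AscertainmentSpec(t_high=700)]:              # stratified
    tensor = f2_blocks_from_genealogy(g, pops, spec, blocks=1e6)
    print(spec.mode, spec.t_high,
          f4_ratio_alpha(tensor, "PO", "P1", "P2", "PI", "PX"))
```

Output from this exact run:

```
genotype inf alpha[PX=P2|P1; outgroup PO, sister PI] = 0.397451 +/- 0.111 (z=3.58, blocks=30)
branch 700 alpha[PX=P2|P1; outgroup PO, sister PI] = 0.222024 +/- 0.0391 (z=5.67, blocks=30)
```

Both estimates are consistent with the true proportion 0.3 (the truth
lies within ~2 standard errors of each), but restricting to branches
younger than 700 generations shrinks the jackknife standard error
roughly threefold — the entire point of time stratification.  Averaged
over replicates the stratified estimator is unbiased
(`simstudy.power_study` runs that experiment, and
`simstudy.optimal_cutoff` locates the best cut-off, about 1.4x the
source split time).

The same operations are available from the command line:

```bash
fstrat simulate --scenario f4ratio --length 30000000 --seed 3 --out sim/
fstrat f2 --trees sim/f4ratio.trees --pops sim/pops.tsv \
          --t-high 700 --blocks 1000000 --out f2out/
fstrat f4ratio --f2 f2out/f2dir --groups PO,P1,P2,PI,PX --out res/
```

## Layout

| module | contents |
| --- | --- |
| `fstrat.genealogy` | `GenealogySequence`, population tables, VCF input |
| `fstrat.relate` | Relate-style `.anc`/`.mut` dialect reader/writer |
| `fstrat.fstats` | ascertainment, per-block f2 tensors, f3/f4/f4-ratio, export |
| `fstrat.jackknife` | weighted block-jackknife estimators |
| `fstrat.admixture` | qpWave, qpAdm, rotation, cladality clustering, MDS |
| `fstrat.painting` | first-coalescence profiles, constrained NNLS |
| `fstrat.simstudy` | scenario catalogue, error models, power studies |
| `fstrat.cli` | `fstrat` command-line entry point |

See `docs/methods.md` for the statistical details, default parameters
and known limitations.
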