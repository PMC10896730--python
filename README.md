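# metaboloq

Kinetic modelling of the ETFDH-assisted complex III Q cycle, and
spectral-count estimation of molar stoichiometry between respiratory-chain
complexes in a metabolon.

## The scientific problem

Complex III (CIII) of the mitochondrial respiratory chain oxidizes
ubiquinol (QH₂) in the two-step Q cycle, passing electrons to cytochrome c
while a semiquinone radical (QH•) waits on the enzyme for the cycle to
complete. Electron-transfer flavoprotein dehydrogenase (ETFDH), the
membrane Q reductase fed by fatty-acid β-oxidation, can assist CIII by
re-reducing the Qi-site semiquinone, shortening the radical's dwell on the
enzyme and regenerating QH₂. `metaboloq` implements:

1. **A generalized mass-action ODE model** of this assisted Q cycle —
   14 state variables (quinone species, cytochrome c redox states, proton
   pools, three ETFDH flavin states, an electron budget) driven by 7
   reactions whose kinetic rate laws are decoupled from their net
   stoichiometries. For reaction *j* with rate constant *k_j* and factor
   set *F_j*,

       r_j = k_j · Π_{i ∈ F_j} x_i,        dx/dt = S · r(x),

   where *S* is the signed stoichiometry matrix. The ETFDH level enters as
   the initial amount of reduced flavin, x₉(0) ∈ {1, 0.5, 0} for wild
   type / heterozygote / knockout.
2. **Simulation and observables** — adaptive stiff integration, conserved-
   pool verification (exact rational left null space of *S*), reduced-
   cytochrome-c final value and AUC, semiquinone dwell areas, integrated
   fluxes and the proton-per-cytochrome yield, and multi-scenario
   comparison across ETFDH levels.
3. **Parameter recovery** — bounded multistart least squares fitting the
   model to noisy absorbance traces (signal = baseline + gain·x₅(t) + ε),
   in particular recovery of the generating ETFDH level.
4. **The spectral-count stoichiometry estimator** — in-silico tryptic
   digestion, effective NOP (number of detectable peptides × response
   factor), per-complex zero-intercept regression of PSM counts on
   effective NOP, and the slope ratio as the molar stoichiometry of two
   complexes, with a protein-level bootstrap interval:

       β_C = Σ_p PSM_p · NOPeff_p / Σ_p NOPeff_p²,   ratio = β_A / β_B.

Synthetic-data generators (seeded, returning their ground truth) produce
every input the pipeline consumes, so all stages are testable offline.

## Worked example

```python
import numpy as np
from metaboloq import (compare_scenarios, make_synthetic_proteome,
                       stoichiometry_ratio, synth_psm_table)

comp = compare_scenarios([0.0, 0.5, 1.0])
for label in comp.labels:
    o = comp.observables[label]
    print(f"{label:3s} cytc_red_auc={o.cytc_red_auc:.3f} "
          f"standby_auc={o.semiquinone_auc_standby:.3f}")
print(comp.ordering)

proteome = make_synthetic_proteome({"ETF": 1.0, "CIII": 2.0},
                                   proteins_per_complex=4, depth=1e4, seed=1)
table, truth = synth_psm_table(proteome)
res = stoichiometry_ratio(table, proteome.proteins, "ETF", "CIII", seed=1)
print(f"ETF:CIII slope ratio = {res.ratio:.3f} "
      f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
```

prints

```
ko  cytc_red_auc=8.323 standby_auc=3.404
het cytc_red_auc=8.648 standby_auc=1.333
wt  cytc_red_auc=8.993 standby_auc=0.479
{'cytc_red_auc_strictly_increasing': True, 'semiquinone_standby_strictly_decreasing': True, 'semiquinone_qi_auc_strictly_decreasing': False}
ETF:CIII slope ratio = 0.497 (95% CI 0.470-0.520)
```

More ETFDH means more cytochrome c reduced over the run and far less
semiquinone stranded at the Qo site (in the knockout, 0.35 a.u. of radical
is left on the enzyme indefinitely once the N-side proton pool empties);
the slope-ratio estimator recovers the generating 1:2 ETF:CIII molar
abundance from Poisson spectral counts.

The same pipeline is scriptable from the shell:

```bash
metaboloq compare --levels 0,0.5,1 -o out/compare
metaboloq synth-psm --abundances ETF=1,CIII=2 --seed 1 -o out/psm
metaboloq stoich --fasta out/psm/proteome.fasta --complexes out/psm/complexes.tsv \
    --psm out/psm/psm.tsv --pair ETF,CIII --seed 1 -o out/stoich
```

## Layout

- `src/metaboloq/network.py` — generalized mass-action networks, rates,
  stoichiometry matrix, conservation laws, symbolic ODEs
- `src/metaboloq/qcycle.py` — the canonical 14-state network and ETFDH scenarios
- `src/metaboloq/simulate.py` — integration, observables, fluxes, comparison
- `src/metaboloq/fitting.py` — trace fitting and ETFDH-level recovery
- `src/metaboloq/synth.py` — seeded generators for traces and proteomics
- `src/metaboloq/stoich.py` — digestion, effective NOP, slope-ratio estimator
- `src/metaboloq/io.py`, `cli.py` — file formats and the `metaboloq` CLI
- `docs/methods.md` — model, assumptions, numerical choices, limitations
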