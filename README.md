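# thiorate

Estimation of per-gene mRNA **synthesis and decay rates** from
4-thiouracil (4SU) metabolic-labeling experiments at two growth
temperatures, and analysis of their **temperature coefficients (Q10)**.

## The problem

4SU is a non-toxic base analogue incorporated into RNA during
transcription. Biotinylating the thiol group and capturing on
streptavidin splits the RNA harvested at the end of a labeling window of
length *t*<sub>L</sub> into a **newly synthesized** (NS, labeled) and a
**pre-existing** (PE, unlabeled) pool; together with total RNA measured
at the start (*A*<sub>0</sub>) and end (*A*) of the window, a single
two-timepoint experiment yields both rates of mRNA turnover. Doing this
at two temperatures 10 °C apart measures, gene by gene, how strongly
transcription and decay respond to temperature — and whether
temperature-responsive transcript levels are driven by transcription or
by stability.

## The model

Assuming first-order decay, the pre-existing pool decays as
PE = *A*<sub>0</sub>·e<sup>−λt<sub>L</sub></sup>, so

- **half-life** *t*<sub>1/2</sub> = −*t*<sub>L</sub>·ln2 / ln(P/*A*<sub>0</sub>), with λ = ln2/*t*<sub>1/2</sub>;
- **synthesis rate** α = N·λ / (1 − e<sup>−λt<sub>L</sub></sup>), correcting the observed
  nascent amount N for decay during the window;
- **Q10** of a rate over ΔT degrees = (rate<sub>warm</sub>/rate<sub>cool</sub>)<sup>10/ΔT</sup>.

Because equal RNA amounts are hybridized per chip, the separated
fractions lose their absolute scale. The per-gene constraint
Cp·PE/T + Cn·NS/T = 1 rearranges to PE/T = 1/Cp − (Cn/Cp)·NS/T, so an
ordinary least-squares fit of PE/T on NS/T across genes recovers the
scale factors (Cp = 1/intercept, Cn = −slope/intercept) that restore
the fractions to the total-sample scale.

At steady state the abundance fold-change between temperatures equals
Q10<sub>syn</sub>/Q10<sub>dec</sub>: a transcript can only become more
abundant at the warmer temperature when its transcription Q10 exceeds
its decay Q10.

The package covers the full analysis: present/absent-call filtering,
regression normalization, rate estimation with explicit per-gene drop
reasons, a SAM-style permutation-FDR test for differential abundance,
warm/unchanged/cool (WG/UG/CG) classification, Q10-binned frequencies of
chromatin-mark and promoter-motif features (IUPAC motif scanning on both
strands), rank tests between gene groups and rate–feature correlations.
A synthetic-data generator with known ground truth backs every stage
with parameter-recovery tests.

## Worked example

```python
from thiorate import SimulationConfig, simulate_experiment, filter_present
from thiorate.normalization import normalize_all
from thiorate.kinetics import estimate_gene_kinetics
from thiorate.thermal_response import sam_test, classify_genes, classification_summary

import numpy as np

cfg = SimulationConfig(n_genes=1000, noise_sd=0.1, seed=42)
es, truth = simulate_experiment(cfg)           # 17/27 degC, 3 replicates
es, dropped = filter_present(es)               # drop MAS5-absent genes
corrected, factors = normalize_all(es)         # fit + apply Cp, Cn per temperature
for t, f in sorted(factors.items()):
    print(f"{t:g} degC: Cp={f.Cp:.3f} Cn={f.Cn:.3f} R2={f.r_squared:.3f} (n={f.n_genes_used})")
kin = {t: estimate_gene_kinetics(corrected, t) for t in (17.0, 27.0)}
for t in (17.0, 27.0):
    rated = [k for k in kin[t] if k.drop_reason == "none"]
    print(f"{t:g} degC: {len(rated)} genes rated, median t1/2 = "
          f"{np.median([k.half_life for k in rated]):.2f} h, "
          f"median alpha = {np.median([k.syn_rate for k in rated]):.1f} units/h")
sam = sam_test(es, 27.0, 17.0, n_perm=200, target_fdr=0.01, seed=42)
profiles, _ = classify_genes(kin[17.0], kin[27.0], sam)
print(classification_summary(profiles).to_string(index=False))
```

prints

```
17 degC: Cp=0.766 Cn=0.232 R2=0.832 (n=930)
27 degC: Cp=0.759 Cn=0.244 R2=0.860 (n=833)
17 degC: 987 genes rated, median t1/2 = 3.46 h, median alpha = 43.1 units/h
27 degC: 990 genes rated, median t1/2 = 1.27 h, median alpha = 150.1 units/h
change_class  n_genes  mean_q10_syn  median_q10_syn  mean_q10_dec  median_q10_dec
          CG       80      2.785247        2.695310      9.527359        7.162501
          UG      676      3.426078        3.263035      3.566138        2.966732
          WG      222      4.405502        4.156318      2.562954        1.590774
```

Reading the table: decay
is about 2.7-fold faster and transcription about 3.5-fold faster at
27 °C; warm genes (WG, ≥ 2-fold more abundant when warm) carry high
transcription Q10s and low decay Q10s, cool genes the reverse —
abundance changes are transcription-driven.

The same pipeline runs from the shell on TSV inputs:

```sh
thiorate --outdir out --seed 1 all        # simulate + rates + q10 + classify + enrich
thiorate --outdir out --config cfg.yaml rates   # or stage by stage on your own TSVs
```

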