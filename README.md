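# nbcensus

Structural and pharmacological analysis of nanobody (VHH) antagonists of
G-protein-coupled receptors, built around three questions that arise when
characterizing an extracellular nanobody inhibitor such as VUN701, an
antagonist of the atypical chemokine receptor ACKR3:

1. **What conformation does the CDR3 loop adopt?**  Nanobody CDR3 loops
   fall into three conformational classes — a protruding β-hairpin
   (*extended*), a loop packed back against the framework (*folded-back*),
   or a minimal-length turn (*short*).  Extended CDR3s are the hallmark of
   orthosteric GPCR binders.  `nbcensus` assigns secondary structure from
   backbone geometry, builds an all-vs-all framework-superposed RMSD
   matrix, and classifies CDR3 conformations with an explicit, tunable
   rule.
2. **Where does the nanobody touch the receptor?**  Heavy-atom contacts at
   a van-der-Waals + 0.5 Å cutoff, fingerprinted along receptor numbering
   (GPCRdb generic labels supported) and partitioned by the CDR making the
   contact, next to a per-column sequence-conservation track.
3. **Is it a simple competitive antagonist, and how tight?**  Fixed-slope
   (Hill = 1) dose-response fits, Cheng-Prusoff conversion of functional
   IC₅₀ values, and Schild regression.

A synthetic-data module generates every input with ground truth known by
construction — idealized β-sandwich scaffolds with designed CDR3 classes,
two-chain complexes with planted contact counts, Gaddum-model titration
families, alignments with prescribed conservation — so the full pipeline is
testable without downloading a single structure.

## The quantitative core

**Secondary structure** uses the Kabsch–Sander electrostatic model: with an
amide hydrogen placed 1 Å from N along the bisector of the N–C(i−1) and
N–O(i−1) directions, the donor→acceptor bond energy is

```
E = 27.888 · (1/r(ON) + 1/r(CH) − 1/r(OH) − 1/r(CN))   kcal/mol
```

and a hydrogen bond is recorded when E < −0.5 kcal/mol.  Helices come from
runs of i→i+4 turns, strands from bridge patterns grown into ladders, on
the reduced alphabet {H, E, T, C}.  β-hairpins are the longest antiparallel
ladder whose strands flank the CDR3.

**Superposition** is the Kabsch algorithm (SVD with reflection correction)
on matched framework Cα positions; the reported distance covers the whole
domain, so divergent CDR3 placements dominate the matrix.  Average-linkage
hierarchical clustering cut at k = 3 recovers the conformational classes.

**Pharmacology**: for an agonist response `y = b + (t−b)/(1 + EC50/[A])`
and surmountable (Gaddum) antagonism, `EC50([B]) = EC50·(1 + [B]/K_B)`.
Cheng-Prusoff converts a functional IC₅₀:

```
K_B = IC50 / (1 + [Agonist]/EC50)
```

and the Schild regression of log₁₀(r−1) on log₁₀[B] (dose ratio
r = EC50([B])/EC50(0)) has slope 1 and x-intercept −pA₂ = log₁₀ K_B for a
simple competitive antagonist.

## Worked example

```python
from nbcensus import synthetic_data as sd
from nbcensus.pipeline import RunConfig, run_census, run_pharm

scaffolds, truth = sd.gen_census(n_per_class=10, seed=1, jitter_sd=0.3)
report = run_census([(s.structure.label, s.structure) for s in scaffolds])
print(report.proportions_all)
# {'extended': 0.333333, 'folded_back': 0.333333, 'short': 0.333333}

schild = run_pharm(sd.gen_bret(sd.BretSpec(k_b=18.2e-9, seed=1)), "schild")
print(round(schild["schild_slope"].iloc[0], 3), round(schild["k_b_M"].iloc[0] * 1e9, 1))
# 0.995 17.3
```

The census report classifies all 30 scaffolds into the three CDR3 classes
(100% agreement with the generator truth; cluster/class adjusted Rand
index 1.0), and the Schild fit on the noisy simulated family returns a
slope statistically indistinguishable from 1 with K_B within a few percent
of the generator's 18.2 nM.  The same stages run from the shell:

```
nbcensus simulate --what census --out sim --n-per-class 10
nbcensus census sim/*.pdb --out census_out
nbcensus pharm bret.csv --mode schild --out pharm_out
```

or as the numbered drivers under `analysis/` (01 simulate → 02 census →
03 interface → 04 conservation → 05 pharmacology), which write their
tables under `results/`.

Published constants of the VUN701–ACKR3 system used as reference points
throughout (sequences in `nbcensus.datasets`; pK conversions in the
pharmacology stage): CXCL12-competition K_B = 9.8 nM (pK_B 8.01), Schild
K_B = 18.2 nM (pK_B 7.74), CXCR4 ∆CDR1 K_B = 948 nM (pK_B 6.02),
radioligand K_D = 10 nM (pK_D 8.00).

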