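#!/usr/bin/env python
"""Competitive-antagonism pharmacology on the simulated BRET family.

Three stages: (1) pK conversions of the published affinity constants of
the VUN701-ACKR3 system; (2) Schild regression over the simulated
titration family (generator K_B = 18.2 nM); (3) a closed-loop
Cheng-Prusoff conversion from a noise-free competition curve.
"""

import argparse
import os

import numpy as np
import pandas as pd

from nbcensus.pharm import cheng_prusoff, fit_fixed_slope, p_value_log
from nbcensus.pipeline import run_pharm, write_manifest
from nbcensus.synthetic_data import gaddum_response

parser = argparse.ArgumentParser()
parser.add_argument("--inputs", default="results/synthetic")
parser.add_argument("--out", default="results/pharm")
args = parser.parse_args()
os.makedirs(args.out, exist_ok=True)

# 1. pK conversions of published constants (VUN701 on ACKR3 / CXCR4)
published = [
    ("CXCL12 competition K_B", 9.8e-9),
    ("Schild K_B", 18.2e-9),
    ("CXCR4 (dCDR1) K_B", 948e-9),
    ("radioligand K_D", 10e-9),
]
pk = pd.DataFrame(
    [{"constant": name, "molar": conc, "pK": round(p_value_log(conc), 2)}
     for name, conc in published]
)
pk.to_csv(os.path.join(args.out, "pk_conversions.csv"), index=False)
print(pk.to_string(index=False))

# 2. Schild regression on the simulated family
csv = os.path.join(args.inputs, "bret_schild_family.csv")
schild = run_pharm(csv, "schild")
schild.to_csv(os.path.join(args.out, "schild.csv"), index=False)
print(f"\nSchild slope {schild['schild_slope'].iloc[0]:.3f}, "
      f"K_B {schild['k_b_M'].iloc[0] * 1e9:.1f} nM "
      f"(pK_B {schild['p_kb'].iloc[0]:.2f}; generator 18.2 nM)")

# 3. Cheng-Prusoff closed loop on a noise-free competition curve
ec50, k_b, agonist = 3.3e-9, 18.2e-9, 3.3e-9
bconc = 10.0 ** np.arange(-10.0, -5.49, 0.5)
resp = np.array([gaddum_response(np.array([agonist]), b, ec50, k_b)[0] for b in bconc])
fit = fit_fixed_slope(bconc, resp, "antagonist")
res = cheng_prusoff(fit.ic50, agonist, ec50)
print(f"competition IC50 {fit.ic50 * 1e9:.1f} nM -> "
      f"Cheng-Prusoff K_B {res.k_b * 1e9:.2f} nM (pK_B {res.p_kb:.2f})")
pd.DataFrame(
    [{"ic50_M": fit.ic50, "k_b_M": res.k_b, "p_kb": res.p_kb}]
).to_csv(os.path.join(args.out, "competition.csv"), index=False)

write_manifest(args.out, {"command": "analysis/05_pharmacology"}, [csv])
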