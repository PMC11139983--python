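#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes under results/synthetic/: a labeled scaffold census (PDB files +
truth table), a Gaddum-model BRET titration family, toy two-chain
complexes with planted contacts, and an alignment with a prescribed
conservation profile.
"""

import argparse
import os

import numpy as np
import pandas as pd

from nbcensus import synthetic_data as sd
from nbcensus.structio import write_pdb

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", default="results/synthetic")
args = parser.parse_args()

os.makedirs(args.out, exist_ok=True)

# scaffold census: 10 per CDR3 class at the default 0.3 A jitter
scaffolds, truth = sd.gen_census(n_per_class=10, seed=args.seed, jitter_sd=0.3)
pdb_dir = os.path.join(args.out, "census_pdb")
os.makedirs(pdb_dir, exist_ok=True)
for sc in scaffolds:
    write_pdb(sc.structure, os.path.join(pdb_dir, f"{sc.structure.label}.pdb"))
truth.to_csv(os.path.join(args.out, "census_truth.tsv"), sep="\t", index=False)
print(f"census: {len(scaffolds)} scaffolds -> {pdb_dir}")

# BRET family: agonist titrations at 8 antagonist concentrations + control
bret = sd.gen_bret(sd.BretSpec(k_b=18.2e-9, noise_sd=0.02, seed=args.seed))
bret.to_csv(os.path.join(args.out, "bret_schild_family.csv"), index=False)
print(f"bret: {len(bret)} rows, antagonist K_B 18.2 nM, 2% noise")

# toy complexes with planted contact counts
ledgers = []
for n_planted in (70, 84, 12):
    st, ledger = sd.gen_toy_complex(n_planted, seed=args.seed)
    write_pdb(st, os.path.join(args.out, f"{st.label}.pdb"))
    ledger.insert(0, "complex", st.label)
    ledgers.append(ledger)
pd.concat(ledgers).to_csv(
    os.path.join(args.out, "planted_contacts.tsv"), sep="\t", index=False
)
print("toy complexes: planted totals 70, 84, 12")

# alignment with a sawtooth conservation profile
profile = np.tile([1.0, 0.9, 0.7, 0.5, 0.3], 8)
records, realized = sd.gen_alignment(profile, n_seqs=24, seed=args.seed)
with open(os.path.join(args.out, "alignment.fasta"), "w") as fh:
    for header, seq in records:
        fh.write(f">{header}\n{seq}\n")
pd.DataFrame({"column": np.arange(1, len(profile) + 1), "realized": realized}).to_csv(
    os.path.join(args.out, "alignment_truth.tsv"), sep="\t", index=False
)
print(f"alignment: {len(records)} sequences x {len(profile)} columns")
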