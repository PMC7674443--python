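#!/usr/bin/env python
"""Representative-model selection, ensemble precision, and displacement profile.

Computes the all-against-all C-alpha RMSD matrix on the rigid-core selection
(residues 10-18, 36-81, 96-145), picks the member with the lowest average
pairwise RMSD, summarises precision as mean +/- SD RMSD to that
representative, and writes the per-residue displacement profile that
localises the disordered segments.
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from glucnmr import geometry
from glucnmr.sequences import GLUC_CORE_RANGES
from glucnmr.structure_io import read_multimodel_pdb

out = Path("results")
ens = read_multimodel_pdb(out / "inputs" / "ensemble.pdb")

matrix = geometry.pairwise_rmsd_matrix(ens, "CA", GLUC_CORE_RANGES)
rep = geometry.select_representative(matrix)
mean, sd = geometry.rmsd_to_reference_stats(ens, rep, "CA", GLUC_CORE_RANGES)
hmean, hsd = geometry.rmsd_to_reference_stats_heavy(ens, rep, GLUC_CORE_RANGES)

np.savetxt(out / "rmsd_matrix.tsv", matrix.values, delimiter="\t", fmt="%.4f")
profile = geometry.per_residue_displacement(ens, rep, "CA", GLUC_CORE_RANGES)
pd.DataFrame(
    {"residue": profile.seq_ids, "mean_A": profile.mean, "sd_A": profile.sd}
).to_csv(out / "displacement.tsv", sep="\t", index=False, float_format="%.4f")

report = {
    "representative_index": rep,
    "core_ca_rmsd_mean_A": round(mean, 2),
    "core_ca_rmsd_sd_A": round(sd, 2),
    "core_heavy_rmsd_mean_A": round(hmean, 2),
    "core_heavy_rmsd_sd_A": round(hsd, 2),
}
(out / "represent.json").write_text(json.dumps(report, indent=2) + "\n")

core = np.isin(profile.seq_ids, [s for lo, hi in GLUC_CORE_RANGES for s in range(lo, hi + 1)])
print(f"representative model index: {rep}")
print(f"core C-alpha RMSD to representative: {mean:.2f} +/- {sd:.2f} A")
print(f"mean displacement, core {profile.mean[core].mean():.2f} A vs "
      f"flexible {profile.mean[~core].mean():.2f} A — disordered segments dominate")
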