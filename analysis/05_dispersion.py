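#!/usr/bin/env python
"""CPMG relaxation dispersion: Delta-R2 screen and global two-state fit.

Computes R2eff(nu) from the constant-time intensities, the screening
statistic Delta R2 = R2eff(50 Hz) - R2eff(1 kHz) with its strict > 2 1/s
flag, and fits the fast-exchange (Luz-Meiboom) model with one global kex
shared across residues, bootstrap over residues for the uncertainty.
"""
import json
from pathlib import Path

import pandas as pd

from glucnmr import relaxation, tables

out = Path("results")
series = tables.read_cpmg_tsv(out / "inputs" / "cpmg.tsv")
rows = relaxation.delta_r2(series)
fit = relaxation.fit_two_state(series, n_bootstrap=200, seed=0)

pd.DataFrame(rows).to_csv(out / "delta_r2.tsv", sep="\t", index=False, float_format="%.4f")
report = {
    "kex_per_s": round(fit.kex, 1),
    "kex_sd_per_s": round(fit.kex_sd, 1),
    "identifiable": fit.identifiable,
    "residues": [
        {"residue": int(s), "r20_per_s": round(float(r), 2), "phiex_per_s2": round(float(p), 0)}
        for s, r, p in zip(fit.seq_ids, fit.r20, fit.phiex)
    ],
}
(out / "dispersion.json").write_text(json.dumps(report, indent=2) + "\n")

flagged = [r["seq_id"] for r in rows if r["flagged"]]
print(f"Delta R2 > 2 1/s for residues {flagged}")
print(f"global kex = {fit.kex:.0f} +/- {fit.kex_sd:.0f} 1/s "
      f"(truth 2500; fast-exchange model, bootstrap over residues)")
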