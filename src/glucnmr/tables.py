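"""TSV schemas shared by the CLI, the analysis drivers and the generators.

Schemas (tab-separated, header row):

* hetNOE:      residue, noe                     (blank noe = missing)
* H/D:         residue, retained_20min, retained_18h   (0/1)
* CPMG:        residue, nu_cpmg_hz, intensity, intensity_ref
* AUC scans:   radius_cm, absorbance, rpm, conc_label
* masses:      observed_mass_da, description
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .auc import AucScan
from .relaxation import CpmgSeries, HdxRecord, HetNoeProfile

__all__ = [
    "write_noe_tsv", "read_noe_tsv",
    "write_hdx_tsv", "read_hdx_tsv",
    "write_cpmg_tsv", "read_cpmg_tsv",
    "write_auc_tsv", "read_auc_tsv",
    "write_masses_tsv", "read_masses_tsv",
]


def write_noe_tsv(profile: HetNoeProfile, path: str | Path) -> None:
    df = pd.DataFrame({"residue": profile.seq_ids, "noe": profile.values})
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_noe_tsv(path: str | Path) -> HetNoeProfile:
    df = pd.read_csv(path, sep="\t")
    return HetNoeProfile(
        seq_ids=df["residue"].to_numpy(int), values=df["noe"].to_numpy(float)
    )


def write_hdx_tsv(records: list[HdxRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "residue": [r.seq_id for r in records],
            "retained_20min": [int(r.retained_20min) for r in records],
            "retained_18h": [int(r.retained_18h) for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_hdx_tsv(path: str | Path) -> list[HdxRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        HdxRecord(
            seq_id=int(r.residue),
            retained_20min=bool(r.retained_20min),
            retained_18h=bool(r.retained_18h),
        )
        for r in df.itertuples()
    ]


def write_cpmg_tsv(series_set: list[CpmgSeries], path: str | Path) -> None:
    rows = []
    for s in series_set:
        for nu, i in zip(s.rates, s.intensities):
            rows.append(
                {
                    "residue": s.seq_id,
                    "nu_cpmg_hz": nu,
                    "intensity": i,
                    "intensity_ref": s.intensity_ref,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_cpmg_tsv(path: str | Path, t_relax: float | None = None) -> list[CpmgSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, grp in df.groupby("residue", sort=True):
        kwargs = {} if t_relax is None else {"t_relax": t_relax}
        out.append(
            CpmgSeries(
                seq_id=int(sid),
                rates=grp["nu_cpmg_hz"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                intensity_ref=float(grp["intensity_ref"].iloc[0]),
                **kwargs,
            )
        )
    return out


def write_auc_tsv(scans: list[AucScan], path: str | Path) -> None:
    rows = []
    for s in scans:
        for r, a in zip(s.radii, s.absorbance):
            rows.append(
                {
                    "radius_cm": r,
                    "absorbance": a,
                    "rpm": s.rotor_speed,
                    "conc_label": s.loading_conc,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_auc_tsv(path: str | Path) -> list[AucScan]:
    df = pd.read_csv(path, sep="\t")
    df["conc_label"] = df.get("conc_label", "").fillna("")
    out = []
    for (rpm, label), grp in df.groupby(["rpm", "conc_label"], sort=True):
        grp = grp.sort_values("radius_cm")
        out.append(
            AucScan(
                radii=grp["radius_cm"].to_numpy(float),
                absorbance=grp["absorbance"].to_numpy(float),
                rotor_speed=float(rpm),
                loading_conc=str(label),
            )
        )
    return out


def write_masses_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_masses_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
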