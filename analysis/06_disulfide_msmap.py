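#!/usr/bin/env python
"""Match observed LC-MS masses to disulfide-linked tryptic species.

Digests the mature GLuc sequence in silico (trypsin, no missed cleavages),
enumerates species of up to three cystine-linked fragments under the
fully-oxidized assumption, matches the observed masses within 0.5 Da, and
reports the connectivity constraints each match implies.
"""
import json
from pathlib import Path

from glucnmr import msmap, tables
from glucnmr.sequences import GLUC_MATURE

out = Path("results")
observed = tables.read_masses_tsv(out / "inputs" / "masses.tsv")

peptides = msmap.digest(GLUC_MATURE)
species = msmap.enumerate_linked_species(peptides, max_peptides=3)
results = []
for obs in observed.observed_mass_da:
    matches = msmap.match_mass(float(obs), species, tolerance=0.5)
    entry = {"observed_da": float(obs), "matches": []}
    for m in matches[:3]:
        imp = msmap.connectivity_implications(m)
        entry["matches"].append(
            {
                "spans": [list(p.span) for p in m.species.peptides],
                "n_disulfides": m.species.n_disulfides,
                "computed_da": round(m.species.mass, 3),
                "delta_da": round(m.delta, 3),
                "partner_options": {
                    str(c): sorted(v) for c, v in imp["partner_options"].items()
                },
            }
        )
    results.append(entry)

(out / "msmap.json").write_text(json.dumps(results, indent=2) + "\n")
best = results[0]["matches"][0]
print(f"observed {results[0]['observed_da']:.2f} Da -> fragments {best['spans']} "
      f"with {best['n_disulfides']} disulfides (computed {best['computed_da']} Da, "
      f"delta {best['delta_da']} Da)")
if best["partner_options"]:
    print("cross-fragment constraint: C52 must bond one of",
          best["partner_options"].get("52"))
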