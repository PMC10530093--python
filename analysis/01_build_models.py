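#!/usr/bin/env python
"""Build the idealized RNA models behind every profile in this study.

Constructs: the disordered single strands rU30 and rA30, the 62-nt
hairpin (29-bp A-form stem + 4-nt loop), the 29-nt hairpin intermediate
12U-5C-12A, the 24-triple U.A-U reference triplex, and the folded 46-nt
12U-5C-12U-5C-12A construct.  Writes PDBs under results/models/ and a
bookkeeping table of residue counts.
"""

from pathlib import Path

import pandas as pd

from rnawaxs import (build_a_form_helix, build_uau12_construct,
                     build_uau_triplex, parse_construct_spec,
                     sample_disordered_ensemble)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
# PDB coordinate files are bulky; they are regenerated on demand and
# kept out of the curated results tree
MODELS = Path(__file__).resolve().parent.parent / "scratch" / "models"
MODELS.mkdir(parents=True, exist_ok=True)

rows = []

for text, propensity in (("rU30", 0.0), ("rA30", 0.6)):
    spec = parse_construct_spec(text)
    ens = sample_disordered_ensemble(spec, 5, seed=7,
                                     stacking_propensity=propensity)
    ens.members[0].to_pdb(MODELS / f"{text}_conformer0.pdb")
    rows.append((text, len(spec), "disordered ensemble",
                 f"stacked fraction {ens.stacked_fraction:.2f}"))

hairpin62 = build_a_form_helix(29, 4)
hairpin62.to_pdb(MODELS / "hairpin_29bp_4nt.pdb")
rows.append(("62-nt hairpin", int(hairpin62.res_index.max()),
             "A-form stem + loop", "29 bp stem, 4-nt loop"))

hp29 = build_a_form_helix(parse_construct_spec("12U-5C-12A"), 5)
hp29.to_pdb(MODELS / "hairpin_12U-5C-12A.pdb")
rows.append(("12U-5C-12A", int(hp29.res_index.max()),
             "A-form hairpin", "12-bp A-U stem, 5-C loop"))

triplex24 = build_uau_triplex(24)
triplex24.to_pdb(MODELS / "uau_triplex_24.pdb")
rows.append(("U.A-U triplex", int(triplex24.res_index.max()) * 3 // 3,
             "triple helix", "24 triples, rise 3.26 A"))

uau12 = build_uau12_construct()
uau12.to_pdb(MODELS / "uau12_folded.pdb")
rows.append(("12U-5C-12U-5C-12A", int(uau12.res_index.max()),
             "folded triplex construct", "12 triples + two 5-C linkers"))

df = pd.DataFrame(rows, columns=["construct", "n_residues", "kind", "notes"])
df.to_csv(OUT / "model_sizes.csv", index=False)
print(df.to_string(index=False))
print(f"\nPDB models in {MODELS}")
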