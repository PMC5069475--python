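#!/usr/bin/env python
"""tRNA-family conservation profiling with a planted strand contrast.

Synthetic family alignments emulate the observation that J-strand tRNA
genes are more conserved than N-strand ones, with stems more conserved
than loops.  Writes results/trna_conservation.tsv and a strand contrast
JSON.
"""

import json
from pathlib import Path

import pandas as pd

from mitocr.synthetic import generate_family_alignment
from mitocr.trna import inp_percent, region_conservation, strand_conservation_contrast

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

# (family, strand, identity probability): J families planted more conserved
FAMILIES = [
    ("tRNA-Ile", "J", 0.80), ("tRNA-Met", "J", 0.85), ("tRNA-Trp", "J", 0.75),
    ("tRNA-Gly", "J", 0.82), ("tRNA-Lys", "J", 0.78), ("tRNA-Asp", "J", 0.72),
    ("tRNA-Gln", "N", 0.60), ("tRNA-Cys", "N", 0.45), ("tRNA-Tyr", "N", 0.50),
    ("tRNA-Phe", "N", 0.35), ("tRNA-Pro", "N", 0.55), ("tRNA-Val", "N", 0.48),
]
STRUCTURE = (
    ["acceptor_stem"] * 14 + ["DHU_stem"] * 8 + ["DHU_loop"] * 8
    + ["anticodon_stem"] * 10 + ["anticodon_loop"] * 7 + ["variable_loop"] * 4
    + ["TpsiC_stem"] * 10 + ["TpsiC_loop"] * 7
)
REGION_FACTORS = {  # stems conserved, loops variable
    "acceptor_stem": 1.15, "DHU_stem": 1.15, "anticodon_stem": 1.2,
    "TpsiC_stem": 1.1, "DHU_loop": 0.6, "anticodon_loop": 0.9,
    "variable_loop": 0.5, "TpsiC_loop": 0.6,
}

profiles, strands, rows = {}, {}, []
for i, (family, strand, p) in enumerate(FAMILIES):
    region_probs = {r: min(1.0, p * f) for r, f in REGION_FACTORS.items()}
    aln, _ = generate_family_alignment(
        n_taxa=14, length=len(STRUCTURE), identity_prob=p,
        structure=STRUCTURE, region_identity_probs=region_probs, seed=SEED + i,
        family=family,
    )
    prof = inp_percent(aln)
    profiles[family] = prof
    strands[family] = strand
    regional = region_conservation(aln, STRUCTURE)
    stems = [v for k, v in regional.items() if k.endswith("_stem")]
    loops = [v for k, v in regional.items() if k.endswith("_loop")]
    rows.append(
        {
            "family": family,
            "strand": strand,
            "inp_percent": round(prof.inp_percent, 1),
            "stem_inp_percent": round(sum(stems) / len(stems), 1),
            "loop_inp_percent": round(sum(loops) / len(loops), 1),
        }
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "trna_conservation.tsv", sep="\t", index=False)
contrast = strand_conservation_contrast(profiles, strands)
(OUT / "trna_strand_contrast.json").write_text(
    json.dumps({"seed": SEED, "contrast": contrast}, indent=2, default=float) + "\n"
)

print(df.to_string(index=False))
print(
    f"\nmean INP%: J {contrast['J']['mean_inp_percent']:.1f} vs "
    f"N {contrast['N']['mean_inp_percent']:.1f}"
)
stems_beat_loops = (df.stem_inp_percent > df.loop_inp_percent).mean()
print(f"stems more conserved than loops in {100 * stems_beat_loops:.0f}% of families")
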