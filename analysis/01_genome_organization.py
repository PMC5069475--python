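#!/usr/bin/env python
"""Genome organization of the *Panaorus albomaculatus* mitogenome.

Parses the packaged organization table (37 genes + control region),
computes signed junction gaps, and summarizes overlaps and intergenic
spacers.  Writes results/genome_organization.json and a per-junction TSV.
"""

import json
from pathlib import Path

import pandas as pd

from mitocr.annotation_stats import junction_gaps, organization_summary
from mitocr.core import load_reference_annotation

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

ann = load_reference_annotation()
gaps = junction_gaps(ann)
summary = organization_summary(gaps)

df = pd.DataFrame(
    [
        {
            "upstream": g.upstream,
            "downstream": g.downstream,
            "gap_bp": g.gap,
            "origin": g.origin,
            "touches_control_region": g.touches_control_region,
        }
        for g in gaps
    ]
)
df.to_csv(OUT / "junction_gaps.tsv", sep="\t", index=False)

payload = {
    "genome_length_bp": ann.genome_length,
    "n_features": len(ann),
    **summary.to_dict(),
    "control_region_bp": ann.get("control_region").length,
    "rrn16S_bp": ann.get("16S").length,
    "rrn12S_bp": ann.get("12S").length,
}
(OUT / "genome_organization.json").write_text(json.dumps(payload, indent=2) + "\n")

print(f"genome: {payload['genome_length_bp']:,} bp, {payload['n_features']} features")
print(
    f"overlaps: {summary.n_overlap_junctions} junctions, {summary.total_overlap_bp} bp total, "
    f"max {summary.max_overlap[0]} bp at {summary.max_overlap[1]}"
)
print(
    f"spacers (control region excluded): {summary.n_spacers} totaling "
    f"{summary.total_spacer_bp} bp, range {summary.spacer_range}"
)
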