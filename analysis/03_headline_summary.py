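"""Condense the study report bundle into a short markdown summary.

Reads the tables written by 02_encoding_study.py and writes
results/summary.md with the headline numbers: the condition × model Δr
pattern, the mixed-model tests, and the significant ERP clusters.
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY = RESULTS / "study"

tidy = pd.read_csv(STUDY / "delta_r_roi.csv")
stats = json.loads((STUDY / "group_stats.json").read_text())
clusters = pd.read_csv(STUDY / "erp_clusters.csv")

lines = ["# Synthetic encoding study — headline summary", ""]

lines.append("## ROI Δr (full − reduced accuracy) by model and condition")
lines.append("")
cell = tidy.groupby(["model", "condition"], observed=True)["dr"].mean().unstack()
lines.append(cell.round(4).to_markdown())
lines.append("")

if "timing_vs_pitch" in stats:
    lines.append("## Timing vs pitch mixed-model tests")
    lines.append("")
    for term, res in stats["timing_vs_pitch"]["lmm"].items():
        lines.append(f"- {term}: chi2 = {res['chi2']:.1f}, p = {res['p']:.2e}")
    lines.append("")
    lines.append("Wilcoxon (per-subject Δr > 0):")
    for cell_name, res in stats["timing_vs_pitch"]["wilcoxon"].items():
        lines.append(f"- {cell_name}: W = {res['W']:.0f}, p = {res['p']:.3g}")
    lines.append("")

lines.append("## ERP surprise-quantile cluster tests")
lines.append("")
sig = clusters[clusters["p"] < 0.05]
if len(sig):
    lines.append(sig.round(4).to_markdown(index=False))
else:
    lines.append("No clusters below p = 0.05.")
lines.append("")

(RESULTS / "summary.md").write_text("\n".join(lines))
print("\n".join(lines))
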