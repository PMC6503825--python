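"""Genome scan for viability selection on a simulated seedling cohort.

Builds a dataset of 25 loci sampled twice from one cohort — 20 neutral, 5
under strong selective mortality (s = -0.1) — then tests every locus for
allele-frequency change beyond random mortality plus sampling, with
Benjamini-Hochberg FDR control at 5%.
"""

import tempfile
from pathlib import Path

from cohortsel import generate_fixture, read_counts_tsv, scan, scan_to_frame

with tempfile.TemporaryDirectory() as tmp:
    counts_path, truth_path = generate_fixture("strong_selection", seed=42, out_dir=tmp)
    data = read_counts_tsv(counts_path)
    truth = Path(truth_path).read_text()

out = scan(data, method="quasi_exact", maf_threshold=0.05, fdr_level=0.05, seed=1)
table = scan_to_frame(out).sort_values("p_value")

print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print()
top10 = table.head(10)["locus_id"].str.startswith("S").sum()
raw = table[table["p_value"] <= 0.05]
fdr = table[table["significant"]]
print(f"selected loci in the top 10 ranks: {top10} of 5 planted")
print(f"raw p <= 0.05: {len(raw)} loci;  significant after BH FDR at 5%: {len(fdr)}")
print("(locus ids starting with 'S' carry s = -0.1; 'L' loci are neutral).")
print("delta_obs is the standardized allele-frequency change between the two")
print("samples; q_value is the BH-adjusted p-value.  With s = -0.1 and samples")
print("of 1,000, per-locus power is modest (~20-50%), so selected loci crowd")
print("the top of the ranking but rarely survive FDR - larger samples sharpen this.")
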