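"""Reproduce the published reporting-ratio arithmetic from printed counts.

The packaged per-PT and per-drug case/total counts are the published
ones; recomputing each ratio (100 x case / total, half-up to one
decimal) must give back every printed percentage.
"""

from irae_som import CountTables, drug_level_ratios, load_drug_counts, load_pt_counts
from irae_som.tables import pt_level_ratios

drugs = load_drug_counts()
ct = CountTables(roster=list(drugs["drug"]))
for _, row in drugs.iterrows():
    ct.n_drug_irae[row.drug] = int(row.case)
    ct.n_drug_all[row.drug] = int(row.total)
out = drug_level_ratios(ct)
out["published"] = drugs["ratio"].values
print("drug-level irAE reporting ratios (recomputed vs published):")
print(out[["drug", "case", "total", "ratio_display", "published"]].to_string(index=False))

pt = load_pt_counts()
ct = CountTables(roster=["ICI"])
for _, row in pt.iterrows():
    ct.n_pt_roster[row.pt_name] = int(row.case)
    ct.n_pt_total[row.pt_name] = int(row.total)
recomputed = pt_level_ratios(ct).set_index("pt_name")["ratio_display"]
mismatches = [(name, recomputed[name], want)
              for name, want in zip(pt["pt_name"], pt["ratio"])
              if recomputed[name] != want]
print(f"\nper-PT ratios: {len(pt)} rows recomputed, {len(mismatches)} mismatches")
# 0 mismatches: every printed percentage follows from its case/total pair
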