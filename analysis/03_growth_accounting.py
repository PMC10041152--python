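"""Expansion factors and generation counts of the focal-species pool.

Flow-cytometry totals give community size; CFU proportions apportion it to
the focal species; the ratio across the growth period is the expansion
factor d entering the fitness equation, and log2(d) is the generation count.
"""

from pathlib import Path

import pandas as pd

import phycofit as pf

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "sim_experiment"
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

records = pf.io_formats.read_cell_abundance(DATA / "cell_abundance.tsv")
by_key = {(r.treatment, r.replicate, r.day): r for r in records}
rows = []
for (treatment, replicate, day), rec in sorted(by_key.items()):
    if day != 0.0:
        continue
    final = by_key[(treatment, replicate, 8.0)]
    est = pf.expansion_factor(rec, final)
    rows.append(
        {"treatment": treatment, "replicate": replicate,
         "d": est.d, "generations": est.generations}
    )
table = pd.DataFrame(rows)
table.to_csv(RESULTS / "expansion_factors.tsv", sep="\t", index=False)

summary = table.groupby("treatment")[["d", "generations"]].mean()
print("mean expansion per treatment:")
print(summary.round(2).to_string())
print(f"grand mean: {table['generations'].mean():.1f} generations")
print(f"table written to {RESULTS / 'expansion_factors.tsv'}")
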