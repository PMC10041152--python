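"""Generate the benchmark synthetic phycosphere TnSeq experiment.

500 genes tiled on a synthetic replicon, four treatments x four replicate
flasks plus four inoculum aliquots, 2e6 reads per sample. Five percent of
genes carry planted fitness effects (growth-rate multipliers 0.5 or 1.5, each
in one multispecies treatment); everything else is neutral. Writes wig
tracks, annotation, metadata, cell-abundance tables and the ground truth
under scratch/sim_experiment/ for the downstream analysis scripts.
"""

from pathlib import Path

import phycofit as pf
from phycofit.simulate import write_experiment

OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim_experiment"
SEED = 7

N_GENES = 500
gene_ids = [f"SYN{i + 1:03d}" for i in range(N_GENES)]
MULTIS = ("Rp+V", "Rp+M", "Rp+V+M")

effect = {}
for i, gene in enumerate(gene_ids[:25]):
    effect[(gene, MULTIS[i % 3])] = 0.5 if i % 2 == 0 else 1.5

config = pf.SimulationConfig(
    n_genes=N_GENES, read_depth=2_000_000, seed=SEED, effect_table=effect
)
library = pf.simulate_library(config)
exp = pf.simulate_experiment(config, library)
write_experiment(exp, OUT)

n_sites = len(library.positions)
n_in_gene = int((library.site_gene != "").sum())
print(f"wrote synthetic experiment to {OUT}")
print(f"  genes: {N_GENES}, insertion sites: {n_sites} "
      f"({n_in_gene} within genes, {n_sites - n_in_gene} intergenic)")
print(f"  samples: {len(exp.samples)} "
      f"(4 inoculum aliquots + 4 treatments x 4 replicates)")
print(f"  planted effects: {len(effect)} gene/treatment pairs "
      f"(multipliers 0.5 and 1.5)")
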