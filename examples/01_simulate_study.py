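"""Generate a complete synthetic pY-Y2H study and write its fixture files.

The generator plants a ground-truth network (with a known dependent/
independent split, reader-reader excess and motif-bearing prey) and then
simulates the pooled screen, the pairwise retest, co-IP triplicates and
kinase-plate profiles. Everything is reproducible from the seed.
"""

import tempfile
from pathlib import Path

from phosphonet import SimulationConfig, simulate_study
from phosphonet.io import (
    write_fasta,
    write_interaction_tsv,
    write_mitab,
    write_motif_table,
    write_phospho_sites,
    write_retest_matrices,
    write_screen_observations,
)

config = SimulationConfig(seed=7)
study = simulate_study(config)

outdir = Path(tempfile.mkdtemp(prefix="phosphonet_study_"))
write_fasta(study["proteins"], outdir / "proteins.fa")
write_motif_table(study["motifs"], outdir / "motifs.tsv")
write_phospho_sites(
    {p.protein_id: p.phospho_sites for p in study["proteins"] if p.phospho_sites},
    outdir / "phospho_sites.tsv",
)
write_screen_observations(study["observations"], outdir / "screen_observations.tsv")
write_retest_matrices(study["retests"], outdir / "retest.tsv")
write_interaction_tsv(study["network"].interactions, outdir / "truth_network.tsv")
write_mitab(study["network"].interactions, outdir / "truth_network.mitab")

n_dep = sum(e.dependence == "dependent" for e in study["network"].interactions)
print(f"universe: {len(study['proteins'])} proteins, "
      f"{sum(p.is_reader for p in study['proteins'])} pY readers")
print(f"truth network: {len(study['network'].interactions)} edges "
      f"({n_dep} dependent), {len(study['network'].planted_sites)} with a planted "
      "motif at a phospho-Y")
print(f"screen: {len(study['observations'])} observed pairs, "
      f"{len(study['retests'])} retested")
print(f"fixtures written to {outdir}")
# Each file is in the same format the analysis functions read back, so this
# directory is a self-contained, fully-labelled test bed for the pipeline.
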