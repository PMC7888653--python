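"""Generate and write a complete synthetic study dataset to disk.

One call per assay arm; the same files the `uroscent simulate` CLI
subcommand produces. Everything is a pure function of the design and seed,
so reruns are byte-identical.
"""

from pathlib import Path

from uroscent import SimulationDesign, simulate_chromatograms, simulate_taxa_table, simulate_trial, simulate_voc_table
from uroscent.readwrite import (
    write_chromatograms,
    write_manifest,
    write_result_json,
    write_taxa_table,
    write_trial_record,
    write_voc_table,
)

out = Path("scratch_dataset")
out.mkdir(exist_ok=True)
design = SimulationDesign(seed=42)

chroms, records = simulate_chromatograms(design)
write_chromatograms(out / "chromatograms.csv", chroms)
write_manifest(out / "manifest.csv", records)

write_voc_table(out / "voc_table.csv", simulate_voc_table(design))

taxa, taxa_truth = simulate_taxa_table(design)
write_taxa_table(out / "taxa_table.tsv", taxa)

trial, trial_truth = simulate_trial(design, n_sets=7)
write_trial_record(out / "trial.json", trial)
write_result_json(out / "truth.json",
                  {"taxa": taxa_truth, "trial": trial_truth})

print(f"wrote {len(chroms)} chromatograms, "
      f"{taxa.n_species}x{taxa.n_samples} taxa table, "
      f"{design.n_voc}-compound VOC table and a {len(trial.sets)}-set trial "
      f"to {out}/")
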