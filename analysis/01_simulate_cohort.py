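#!/usr/bin/env python
"""Generate the synthetic study inputs: panel, healthy plasma, dilution series.

Writes the TSV tables every later stage consumes under results/data/.
Run from the repository root:  python analysis/01_simulate_cohort.py [--seed 1]
"""

import argparse
from pathlib import Path

import timmrd as T

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()

out = args.out
out.mkdir(parents=True, exist_ok=True)

spec = T.SimulationSpec(n_blocks=1000, n_dmb_true=50, seed=args.seed)
blocks = T.simulate.make_block_defs(spec)
T.write_block_defs(blocks, out / "blocks.tsv")

healthy, true_prior = T.simulate_healthy_plasma(spec, 30)
T.write_block_counts(healthy, out / "healthy_counts.tsv")
T.write_prior(true_prior, out / "true_prior.tsv")

tumor, normal, planted = T.simulate_tissue_pair(spec, true_prior)
with open(out / "tissue_levels.tsv", "w") as handle:
    handle.write("#sample_id\trole\tblock_id\tlevel\n")
    for tissue in (tumor, normal):
        for block_id, (level, _) in tissue.levels.items():
            handle.write(f"{tissue.sample_id}\t{tissue.tissue_role}\t{block_id}\t{level:.6g}\n")

series = T.simulate_dilution_series([0.1, 0.01, 0.001, 2e-4, 0.0], 5, spec)
T.write_block_counts([c for _, c in series.samples], out / "dilution_counts.tsv")
with open(out / "dilution_truth.tsv", "w") as handle:
    handle.write("#sample_id\ttrue_fraction\n")
    for frac, counts in series.samples:
        handle.write(f"{counts.sample_id}\t{frac:g}\n")

print(f"panel of {len(blocks)} blocks ({len(planted)} planted DMBs), "
      f"{len(healthy)} healthy plasma samples, "
      f"{len(series.samples)} dilution samples -> {out}")
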