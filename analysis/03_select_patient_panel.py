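#!/usr/bin/env python
"""Select the patient-specific DMB panel from the synthetic tissue pair.

Applies the tumor-over-prior and tumor-over-normal margins against the
fitted background prior and reports recovery of the planted blocks.
"""

import argparse
from pathlib import Path

import timmrd as T
from timmrd.panel_io import _data_lines

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
args = parser.parse_args()

tumor = T.TissueMethylome("SIM-T-tumor", "tumor")
normal = T.TissueMethylome("SIM-T-normal", "adjacent_normal")
for _, fields in _data_lines(args.data / "tissue_levels.tsv"):
    sample_id, role, block_id, level = fields
    (tumor if role == "tumor" else normal).add(block_id, float(level), 1000)

prior = T.read_prior(args.data / "fitted_prior.tsv")
panel = T.select_patient_dmbs(tumor, normal, prior, patient_id="SIM-T")
from timmrd.dmb_selection import write_panel

write_panel(panel, args.data / "patient_panel.tsv")

ratio = T.hypermethylation_ratio(tumor, prior, margin=0.2)
print(f"selected m = {panel.m} blocks for patient SIM-T "
      f"(tumor hypermethylation ratio {ratio:.3f})")
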