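#!/usr/bin/env python
"""End-to-end longitudinal surveillance comparison on a synthetic cohort.

Simulates a post-surgical cohort, runs the full pipeline (prior fitting,
per-patient panel selection, sample scoring), and compares the
methylation score against the mutation (maxAF) readout at a 120-day
horizon before relapse. Writes the confusion metrics and the
survival-ready export table under results/.
"""

import argparse
import json
from pathlib import Path

from timmrd.studies import surveillance_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-patients", type=int, default=100)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

res = surveillance_study(args.seed, n_patients=args.n_patients)
args.out.mkdir(parents=True, exist_ok=True)
with open(args.out / "surveillance_summary.json", "w") as handle:
    json.dump(res, handle, indent=2)

print(f"{res['n_timelines']} evaluable patients "
      f"({res['n_unscoreable']} unscoreable)")
print(f"  horizon 120 d sensitivity: methylation {res['sens_timmrd']:.1%} "
      f"vs mutation {res['sens_mutation']:.1%}")
print(f"  horizon specificity:       methylation {res['spec_timmrd']:.1%} "
      f"vs mutation {res['spec_mutation']:.1%}")
print(f"  methylation NPV {res['npv_timmrd']:.1%}, ROC AUC {res['auc_timmrd']:.3f}")
print(f"  mean lead time: methylation {res['mean_lead_timmrd']:.0f} d "
      f"vs mutation {res['mean_lead_mutation']:.0f} d")
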