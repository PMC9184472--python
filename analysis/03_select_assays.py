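#!/usr/bin/env python
"""Step 3 — four-criterion assay evaluation and selection.

Applies detectability, baseline, dose-dependency and time-persistency
criteria, ranks assays by summed across-donor SD of the fold change, and
writes evaluation.tsv + summary.json. Prints the per-gene verdict counts
and the selected assays.
"""

import argparse
import json
from pathlib import Path

from exonqpcr import io, selection
from exonqpcr.model import Dataset

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--sim", type=Path, default=Path("results/analysis/sim"))
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

records = io.read_ct_table(args.sim / "ct_table.csv")
manifest = io.load_manifest(args.sim / "manifest.csv")
dataset = Dataset(records=records, manifest=manifest)

evaluations = selection.evaluate_assays(dataset)
args.out.mkdir(parents=True, exist_ok=True)
io.write_evaluation_table(evaluations, args.out / "evaluation.tsv")
io.write_summary_json(evaluations, args.out / "summary.json")

summary = json.loads((args.out / "summary.json").read_text())
for gene, info in summary.items():
    print(f"{gene:<8} {info['n_detectable']}/{info['n_assays']} detectable, "
          f"selected: {', '.join(info['selected']) or 'none this draw'}")
print(f"full table -> {args.out / 'evaluation.tsv'}")
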