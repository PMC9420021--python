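"""One-command pipeline run: simulate -> norms -> classify -> reports.

Runs every stage on a small seeded synthetic dataset and lists the
artifacts it writes (volume tables, norms JSON, age curves, per-region
classification, Markdown subject reports, cognitive statistics).  Rerun
with the same config to get byte-identical tables.
"""

import json

import normvol as nv

cfg = nv.PipelineConfig(
    out_dir="scratch/pipeline_demo", seed=11, n_subjects=300, min_bin_n=10,
    n_patients=4,
)
artifacts = nv.run_pipeline(cfg)
for name, path in sorted(artifacts.items()):
    print(f"{name:22s} {path}")

labels = json.loads(artifacts["subject_labels"].read_text())["labels"]
print("\nsubject labels:", labels)
print(
    "\nEach synthetic patient carries a 5 SD genu deficit, so all should "
    "be labelled 'low volume'; artifacts are stamped with the config "
    "hash and seed for bit-identical reruns."
)
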