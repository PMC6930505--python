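"""Run the whole analysis from a single config on self-contained inputs.

Writes a synthetic survey CSV (with a 30%-prevalence cohort condition),
a predication CSV and a YAML config, then executes encode -> mine ->
select -> subset -> correlate -> litmine and prints the manifest summary.
Equivalent shell usage:

    ckdrules simulate --out demo --seed 3
    ckdrules run --config demo/config.yaml
"""

import json
import tempfile
from pathlib import Path

from ckdrules.pipeline import PipelineConfig, run_pipeline, write_demo_inputs

workdir = Path(tempfile.mkdtemp())
cfg_path = write_demo_inputs(workdir, seed=3, n=10_000)
manifest = run_pipeline(PipelineConfig.from_yaml(cfg_path))

print("stage status:", {k: v["status"] for k, v in manifest["stages"].items()})
sel = manifest["stages"]["select"]
print(f"selection: {sel['n_input']} rules -> {sel['n_after_stage1']} "
      f"(support > {sel['mean_support']:.4f}, lift > 1) -> {sel['n_final']} "
      f"(lift > {sel['mean_lift']:.4f})")
print("outputs in", PipelineConfig.from_yaml(cfg_path).out_dir)
print(json.dumps(manifest["stages"]["litmine"], indent=2))
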