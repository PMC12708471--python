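"""End-to-end pipeline run from a YAML config, writing all result tables.

Equivalent to `mortlag run --config cfg.yaml`; shows the files a run
produces and reprints the trend-slope summary from the written CSV to
demonstrate that outputs are self-contained.
"""
import tempfile
from pathlib import Path

import pandas as pd
import yaml

import mortlag as ml
from mortlag.pipeline import RunConfig, run_pipeline

tmp = Path(tempfile.mkdtemp(prefix="mortlag_run_"))
ml.default_scenario(seed=0).to_yaml(tmp / "scenario.yaml")
cfg_path = tmp / "config.yaml"
cfg_path.write_text(yaml.safe_dump({
    "scenario": str(tmp / "scenario.yaml"),
    "outdir": str(tmp / "results"),
    "analysis_years": [2000, 2019],
    "seed": 0,
}))

res = run_pipeline(RunConfig.from_yaml(cfg_path))
print(f"results written to {res.outdir}:")
for p in sorted(res.outdir.iterdir()):
    print(f"  {p.name}")

slopes = pd.read_csv(res.outdir / "trend_slopes.csv")
print("\nrecord-trend slopes (years of e0 per decade) from the written CSV:")
print(slopes.round(3).to_string(index=False))
print("\nRe-running with the same config and seed reproduces every CSV "
      "byte for byte.")
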