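"""Time lags behind the record smoking-eliminated trend.

Runs the full pipeline in memory and prints the 2019 lag table (how many
calendar years each country's life expectancy trails the benchmark), the
change in lags since 2000, and a slice of the age-specific lag grid.
"""
import tempfile
from pathlib import Path

import mortlag as ml
from mortlag.pipeline import RunConfig, run_pipeline

tmp = Path(tempfile.mkdtemp(prefix="mortlag_lags_"))
ml.default_scenario(seed=0).to_yaml(tmp / "scenario.yaml")
res = run_pipeline(RunConfig(scenario=str(tmp / "scenario.yaml"), outdir=None))

tab = res.lag_tables[2019]
cols = ["country", "sex", "lag_observed", "lag_eliminated",
        "smoking_contribution"]
print("lags behind record smoking-eliminated e0, 2019 (calendar years):")
print(tab[cols].round(1).to_string(index=False))

print("\nchange in lag 2000 -> 2019 (positive = falling further behind):")
print(res.lag_changes.round(1).to_string(index=False))

grid = res.age_grids[("observed", "M")]
slice_ = grid[grid["age_start"].isin([45, 65, 85])]
print("\nage-specific death-rate lags, men, 2019 (bin labels per figure "
      "conventions):")
print(slice_[["country", "age_start", "lag", "label"]].to_string(index=False))
print("\nThe planted 12-year clone (LAG) shows a smoking-eliminated lag of "
      "12.0; 'MEAN' is the average-rate pseudo-country; '≤0' marks rates "
      "already at or better than today's reference.")
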