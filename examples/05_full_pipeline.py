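"""Full pipeline: simulate, write inputs, run, inspect the outputs.

Produces the four comparison tables, the GL-contribution ranking, the
under-reporting flags, the comparison list and a JSON run log in a
temporary directory, then prints the significant arm differences and the
sensitivity re-run verdict.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

import glycodiary as gd

workdir = Path(tempfile.mkdtemp(prefix="glycodiary_"))
data_dir, out_dir = workdir / "inputs", workdir / "results"

gd.generate_cohort(n_pairs=40, seed=3).write(data_dir)

config = gd.RunConfig(
    profiles=data_dir / "profiles.csv",
    diary=data_dir / "diary.csv",
    composition=data_dir / "composition.csv",
    gi_table=data_dir / "gi_table.csv",
    analogue_map=data_dir / "analogue_map.csv",
    recipes=data_dir / "recipes.csv",
    out_dir=out_dir,
)
result = gd.run_pipeline(config)

print("outputs:", ", ".join(sorted(p.name for p in out_dir.iterdir())))

comps = result.comparisons
sig = comps[comps["significant"]].sort_values("p_value")
print(f"\n{len(sig)}/{len(comps)} comparisons significant at p <= 0.05; strongest:")
print(sig.head(8)[["family", "variable", "test", "p_value"]].to_string(index=False))

fig1 = pd.read_csv(out_dir / "fig1.csv")
print("\ntop GL contributors (T2DM arm, median % of load):")
print(fig1.head(5)[["rank", "display_name", "t2dm_median", "nd_median"]]
      .to_string(index=False))

log = json.loads((out_dir / "log.json").read_text())
s = log["sensitivity"]
print(f"\nsensitivity re-run on {s['n_pairs_retained']} complete pairs: "
      f"{s['n_flags_changed']} significance flags changed")
print("(dropping every pair containing a possible under-reporter costs power;"
      "\n at this small example size many borderline flags move, while at the"
      "\n full 124-pair design the main conclusions are expected to be stable)")
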