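"""Run the whole workflow in one call and inspect the run directory.

generate → augment → train (full + simplified) → explain → validate → CV,
with every stage seeded from one master seed and every artifact written as
CSV/JSON plus a checksummed manifest.  Equivalent to
``digestnn run-all --seed 42 --out run42`` on the command line.
"""

import json
from pathlib import Path

from digestnn import RunConfig, run_pipeline

out = run_pipeline(RunConfig(seed=42), "run42")
print("artifacts:", ", ".join(sorted(p.name for p in Path(out).iterdir())))

metrics = json.loads((out / "metrics.json").read_text())
for variant, m in metrics.items():
    print(f"{variant:10s} R2 {m['r2']:.3f}  RMSE {m['rmse']:.3f}  "
          f"stopped at epoch {m['stopped_epoch']}")
cv = json.loads((out / "cv.json").read_text())
print(f"5-fold CV  R2 {cv['mean']['r2']:.3f} ± {cv['sd']['r2']:.3f}")
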