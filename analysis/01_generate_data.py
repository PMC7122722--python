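"""Generate the synthetic monthly fire-climate system and record its truth.

Writes the 216-month log-scale dataset (area burned plus seven climate
drivers tied to it through one cointegrating relation) and the generating
parameters, so every later stage can be checked by parameter recovery.
"""

import json
import sys
from dataclasses import asdict
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import dataset, outdir

from fireardl import write_timeseries

ds, truth = dataset()
out = outdir()
write_timeseries(ds, out / "synthetic_data.csv")
(out / "synthetic_truth.json").write_text(json.dumps(asdict(truth), indent=2, sort_keys=True))

print(f"generated {ds.n_obs} months, {len(ds.variables)} variables -> {out/'synthetic_data.csv'}")
print(f"true adjustment speed rho = {truth.adjustment_speed}")
print(f"true wind elasticity       = {truth.long_run_elasticities['wind']}")
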