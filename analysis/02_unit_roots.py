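"""Classify each variable's integration order with ADF and PP tests.

Bounds cointegration testing requires every series to be I(0) or I(1) but
never I(2); this stage verifies that precondition and writes the unit-root
grid (variables x level/1st-difference x ADF/PP).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import dataset, outdir

from fireardl import adf_test, classify_integration_order, pp_test

ds, _ = dataset()
rows = []
for v in ds.variables:
    x = ds.series(v)
    for test, fn in (("ADF", adf_test), ("PP", pp_test)):
        lvl = fn(x, deterministic="ct", variable=v)
        d1 = fn(np.diff(x), deterministic="c", variable=v, order_tested="1st diff")
        d2 = fn(np.diff(x, n=2), deterministic="c", variable=v, order_tested="2nd diff")
        d = classify_integration_order(lvl, d1, d2)
        rows.append(
            {
                "variable": v, "test": test,
                "level": round(lvl.statistic, 3),
                "1st_diff": round(d1.statistic, 3),
                "cv_5pct_level": round(lvl.crit_values[0.05], 3),
                "order": f"I({d})",
            }
        )

table = pd.DataFrame(rows)
table.to_csv(outdir() / "unit_roots.csv", index=False)
print(table.to_string(index=False))
orders = set(table["order"])
print(f"\nintegration orders found: {sorted(orders)} -> bounds testing is "
      + ("valid (no I(2))" if "I(2)" not in orders else "INVALID: I(2) present"))
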