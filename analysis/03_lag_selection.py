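"""Select the common lag order for the ARDL stage by VAR information criteria.

All candidate orders are scored on one common estimation sample; the
Schwarz criterion (SBC) is the operative selection.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import dataset, outdir

from fireardl import var_lag_selection

ds, _ = dataset()
table = var_lag_selection(ds, max_lag=3)
table.table.reset_index().to_csv(outdir() / "lag_selection.csv", index=False)
print(table)
print(f"\nselections: { {k: int(v) for k, v in table.selected.items()} }")
print(f"operative (SBC) lag order: {table.chosen}")
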