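"""Fragility table and worst-case index from conditional probability curves.

Two headline summaries: per (region, crop, hazard) the conditional loss
probability at the 98th-percentile hazard level (cells whose 95% CI touches
zero are flagged as not shown), and per region the worst case — the maximum
CI upper bound over all crop x hazard combinations, with its argmax labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LABELS = ["region", "crop", "variable", "orientation"]


def fragility_table(curves: pd.DataFrame, q_c: float = 0.98) -> pd.DataFrame:
    """One cell per (region, crop, variable, orientation) at conditioning level q_c.

    ``curves`` is a long table with columns region, crop, variable,
    orientation, q_c, point, ci_low, ci_high (the stacked output of
    ``extrapolate.bootstrap_cis`` over the analysis grid). Cells with
    ci_low <= 0 are flagged ``shown=False`` — no evidence of association.
    """
    required = set(LABELS + ["q_c", "point", "ci_low", "ci_high"])
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curves table missing columns: {sorted(missing)}")
    cells = []
    for labels, grp in curves.groupby(LABELS, sort=True):
        at = grp[np.isclose(grp["q_c"], q_c)]
        if at.empty:
            raise ValueError(f"curve {labels} has no grid level at q_c={q_c}")
        row = at.iloc[0]
        cells.append(dict(zip(LABELS, labels))
                     | {"q_c": q_c,
                        "point": float(row["point"]),
                        "ci_low": float(row["ci_low"]),
                        "ci_high": float(row["ci_high"]),
                        "shown": bool(row["ci_low"] > 0.0)})
    return pd.DataFrame(cells)


def worst_case(cells: pd.DataFrame) -> pd.DataFrame:
    """Per region, the maximum CI upper bound over crop x hazard cells.

    Ties broken lexicographically by (crop, variable, orientation). Returns
    one row per region with the argmax labels and the bound.
    """
    if cells.empty:
        raise ValueError("no fragility cells provided")
    rows = []
    for region, grp in cells.groupby("region", sort=True):
        grp = grp.sort_values(["crop", "variable", "orientation"]).reset_index(drop=True)
        i = int(np.argmax(grp["ci_high"].to_numpy()))
        rows.append({"region": region,
                     "crop": grp.loc[i, "crop"],
                     "variable": grp.loc[i, "variable"],
                     "orientation": grp.loc[i, "orientation"],
                     "worst_case": float(grp.loc[i, "ci_high"])})
    return pd.DataFrame(rows)
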