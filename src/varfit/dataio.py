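"""CSV data exchange.

One row per data point; for each model output ``<name>`` the file carries a
value column ``<name>`` and a variance column ``<name>_var``.  An empty
cell marks the output unobserved in that data point.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .polysys import DataPoint, ModelSpec

__all__ = ["read_data_csv", "write_data_csv"]


def read_data_csv(source, outputs: Sequence[str] | ModelSpec) -> list[DataPoint]:
    if isinstance(outputs, ModelSpec):
        outputs = outputs.outputs
    df = pd.read_csv(source)
    points = []
    for _, row in df.iterrows():
        values, variances = [], []
        for name in outputs:
            if name not in df.columns:
                raise KeyError(f"data file lacks a column for output {name!r}")
            v = row[name]
            if pd.isna(v):
                values.append(None)
                variances.append(1.0)  # placeholder; unobserved entries carry no weight
            else:
                values.append(float(v))
                var_col = f"{name}_var"
                if var_col not in df.columns or pd.isna(row[var_col]):
                    raise KeyError(f"observed output {name!r} needs a variance column {var_col!r}")
                variances.append(float(row[var_col]))
        points.append(DataPoint(values, variances))
    return points


def write_data_csv(path, outputs: Sequence[str], points: Sequence[DataPoint]) -> None:
    rows = []
    for dp in points:
        row = {}
        for i, name in enumerate(outputs):
            row[name] = np.nan if dp.values[i] is None else dp.values[i]
            row[f"{name}_var"] = dp.variances[i] if dp.values[i] is not None else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
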