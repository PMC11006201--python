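"""Reading survey tables and writing analysis outputs.

``load_survey`` reads a flat per-respondent table (CSV or Excel) and applies
an optional column-name map so that external files with arbitrary headers
can feed the scoring and modelling pipeline, whose canonical item names are
``phq1..9, gad1..7, sss1..8, pss1..10, osss1..3`` plus covariate names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def load_survey(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load a respondent table; ``column_map`` maps file headers to canonical
    names.  Excel files require openpyxl (.xlsx); legacy .xls should be
    re-saved as .xlsx or CSV first."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survey file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        table = pd.read_excel(path)
    elif path.suffix.lower() == ".csv":
        table = pd.read_csv(path)
    else:
        raise ValueError(f"unsupported survey format {path.suffix!r} (use .csv or .xlsx)")
    if column_map:
        missing = [c for c in column_map if c not in table.columns]
        if missing:
            raise ValueError(f"column map refers to absent columns: {missing}")
        table = table.rename(columns=column_map)
    return table


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
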