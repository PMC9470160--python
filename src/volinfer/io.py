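"""Readers for externally recorded behavioral data.

Deposited per-trial behavioral CSVs (one row per trial: trial index,
condition, stimulus orientations, response, confidence) are mapped onto the
package's session/response schema through a small YAML column-mapping
declaration, so analyses run unchanged on recorded data.

Example mapping file::

    columns:
      trial: trial_idx
      block: block
      condition: cond          # values mapped through condition_values
      orientations: seq_angles # semicolon- or comma-delimited radians
      response: resp
      confidence: conf
    condition_values: {"0": "C-", "1": "C+"}
    orientation_delimiter: ";"
    orientation_units: radians   # or "degrees"
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import C_MINUS, C_PLUS


def load_column_mapping(path: str | Path) -> dict:
    mapping = yaml.safe_load(Path(path).read_text())
    if "columns" not in mapping:
        raise ValueError("mapping YAML must declare a 'columns' section")
    return mapping


def read_behavioral_csv(
    csv_path: str | Path, mapping: dict | str | Path
) -> pd.DataFrame:
    """Read a recorded behavioral CSV into the package's tidy trial frame.

    Returns one row per trial with columns: trial, block, condition,
    orientations (list of radians in [0, pi)), choice, confidence,
    is_switch, is_confirmed (switch/confirmation flags derived from the
    choice stream, null at block boundaries).
    """
    if not isinstance(mapping, dict):
        mapping = load_column_mapping(mapping)
    cols = mapping["columns"]
    raw = pd.read_csv(csv_path)
    delim = mapping.get("orientation_delimiter", ";")
    units = mapping.get("orientation_units", "radians")
    cond_map = {str(k): v for k, v in mapping.get("condition_values", {}).items()}

    def parse_orients(s):
        vals = np.array([float(x) for x in str(s).split(delim) if x != ""])
        if units == "degrees":
            vals = np.deg2rad(vals)
        return np.mod(vals, np.pi)

    out = pd.DataFrame(
        {
            "trial": raw[cols["trial"]].astype(int),
            "block": raw[cols["block"]].astype(int) if "block" in cols else 0,
            "condition": raw[cols["condition"]].astype(str).map(
                lambda v: cond_map.get(v, v)
            ),
            "orientations": raw[cols["orientations"]].map(parse_orients),
            "choice": raw[cols["response"]].astype(int),
            "confidence": raw[cols["confidence"]].astype(int),
        }
    )
    bad = ~out["condition"].isin([C_MINUS, C_PLUS])
    if bad.any():
        raise ValueError(
            f"unmapped condition values: {sorted(out.loc[bad, 'condition'].unique())}"
        )
    out = out.sort_values("trial").reset_index(drop=True)
    choice = out["choice"].to_numpy()
    block = out["block"].to_numpy()
    n = len(out)
    is_switch = np.full(n, np.nan)
    is_confirmed = np.full(n, np.nan)
    for t in range(1, n):
        if block[t] == block[t - 1]:
            is_switch[t] = float(choice[t] != choice[t - 1])
    for t in range(n - 1):
        if is_switch[t] == 1 and block[t + 1] == block[t]:
            is_confirmed[t] = float(choice[t + 1] == choice[t])
    out["is_switch"] = is_switch
    out["is_confirmed"] = is_confirmed
    return out
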