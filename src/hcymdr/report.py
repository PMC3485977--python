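"""Deterministic TSV/JSON report writers.

JSON output keeps full float precision and sorted keys so identical
runs are byte-identical; TSV output is display-rounded.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mdr import MdrSearchResult, PermutationResult, RiskCellSummary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_metadata(seed: int | None, config: dict) -> dict:
    return {"tool": "hcymdr", "version": __version__, "seed": seed, "config": _jsonable(config)}


def write_json(payload: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_tsv(df: pd.DataFrame, path, float_decimals: int = 4) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_decimals}f")


def mdr_model_table(result: MdrSearchResult, perm: PermutationResult | None = None) -> pd.DataFrame:
    """Best model per size: model, training accuracy, TA, CVC, optional P."""
    rows = []
    for k in sorted(result.best_per_size):
        ev = result.best_per_size[k]
        row = {
            "model": ev.label,
            "k": k,
            "training_accuracy": ev.training_accuracy,
            "testing_accuracy": ev.testing_accuracy,
            "cvc": f"{ev.cvc}/{ev.n_splits}",
            "overall_best": ev.markers == result.best.markers,
        }
        if perm is not None and ev.markers == result.best.markers:
            row["p_value"] = perm.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def risk_grid_table(summary: RiskCellSummary) -> pd.DataFrame:
    """One row per multilocus cell: genotype combination, counts, risk label."""
    rows = []
    for combo in sorted(summary.cells):
        cell = summary.cells[combo]
        rows.append(
            {
                **{m: g for m, g in zip(summary.markers, combo)},
                "n_case": cell.n_case,
                "n_control": cell.n_control,
                "risk": cell.label,
            }
        )
    return pd.DataFrame(rows)
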