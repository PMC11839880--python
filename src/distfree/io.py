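"""File readers and seeded fixture generation for the command-line surface."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .power import SimSpec, sim_data

__all__ = ["read_vector", "read_contingency", "generate_fixture"]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline()
    sep = "," if "," in first else ("\t" if "\t" in first else r"\s+")
    return pd.read_csv(path, sep=sep, engine="python", header=None)


def read_vector(path, column: int = 0) -> np.ndarray:
    """Read one numeric column from a CSV/TSV file, order-preserving.

    Non-numeric or missing cells are rejected with the (1-based) row index
    in the message.
    """
    frame = _read_table(path)
    if column >= frame.shape[1]:
        raise ValueError(f"{path} has only {frame.shape[1]} column(s)")
    raw = frame.iloc[:, column]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna()
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValueError(f"non-numeric or missing value at row {row} of {path}")
    if values.size == 0:
        raise ValueError(f"empty column in {path}")
    return values.to_numpy(dtype=float)


def read_contingency(path) -> np.ndarray:
    """Read an R x C ordered contingency table of non-negative integers."""
    frame = _read_table(path)
    if frame.isna().any().any():
        raise ValueError(f"ragged or incomplete table in {path}")
    cells = frame.to_numpy()
    try:
        cells = cells.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric entry in {path}") from exc
    if np.any(cells < 0) or np.any(cells != np.rint(cells)):
        raise ValueError(f"table entries must be non-negative integers in {path}")
    if cells.shape[0] < 2 or cells.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    return cells.astype(int)


def generate_fixture(spec: SimSpec, path_prefix) -> dict:
    """Write a seeded synthetic data set plus a JSON sidecar.

    Paired designs produce `<prefix>.csv` with columns y1, y2; independent
    designs produce columns group (C/E), value.  The sidecar records the
    generating spec and, where a closed form exists (normal model with equal
    spreads), the implied true dominance parameter
    Omega_E = Phi(delta / (sigma * sqrt(2))).
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    result = sim_data(spec)
    csv_path = prefix.with_suffix(".csv")
    if spec.design == "paired":
        pd.DataFrame({"y1": result.sample_e, "y2": result.sample_c}).to_csv(
            csv_path, index=False
        )
    else:
        pd.DataFrame(
            {
                "group": ["C"] * spec.n + ["E"] * spec.n,
                "value": np.concatenate([result.sample_c, result.sample_e]),
            }
        ).to_csv(csv_path, index=False)
    sidecar = {
        "model": spec.model,
        "design": spec.design,
        "n": spec.n,
        "delta": spec.delta,
        "shape1": spec.shape1,
        "shape2": spec.shape2,
        "block_max": spec.block_max,
        "seed": spec.seed,
        "files": {"data": csv_path.name},
    }
    if spec.model == "normal" and spec.shape1 == spec.shape2:
        sidecar["true_omega_e"] = float(
            _st.norm.cdf(spec.delta / (spec.shape1 * np.sqrt(2.0)))
        )
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return sidecar
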