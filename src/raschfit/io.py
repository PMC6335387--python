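"""CSV and config I/O for response matrices, specs and study grids."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .datagen import GeneratingModelSpec, ResponseMatrix
from .simstudy import SimulationCondition


def read_response_matrix(path) -> ResponseMatrix:
    """Read a 0/1 CSV, with an optional header row and person-label column.

    A non-numeric first row is taken as item labels; a non-numeric first
    column as person labels. Any cell other than 0 or 1 raises a parse
    error naming its location.
    """
    raw = pd.read_csv(path, header=None, dtype=str, skipinitialspace=True)
    raw = raw.dropna(how="all")

    def _is_int(v) -> bool:
        try:
            int(str(v))
            return True
        except (TypeError, ValueError):
            return False

    items = None
    persons = None
    has_header = not all(_is_int(v) for v in raw.iloc[0])
    if has_header:
        header = [str(v) for v in raw.iloc[0]]
        raw = raw.iloc[1:]
        if raw.empty:
            raise ValueError("no data rows below the header")
    has_labels = not all(_is_int(v) for v in raw.iloc[:, 0])
    if has_labels:
        persons = [str(v) for v in raw.iloc[:, 0]]
        raw = raw.iloc[:, 1:]
    if has_header:
        items = header[1:] if has_labels and len(header) == raw.shape[1] + 1 else header

    data = np.empty(raw.shape, dtype=np.int8)
    for j, (_, row) in enumerate(raw.iterrows()):
        for i, v in enumerate(row):
            if not _is_int(v) or int(v) not in (0, 1):
                raise ValueError(
                    f"non-binary cell {v!r} at data row {j + 1}, column {i + 1}"
                )
            data[j, i] = int(v)
    return ResponseMatrix(data=data, persons=persons, items=items)


def write_response_matrix(X: ResponseMatrix, path, labels: bool = True) -> None:
    """Write a matrix as CSV; with labels, a header row and person column."""
    if labels:
        df = pd.DataFrame(X.data, index=X.persons, columns=X.items)
        df.to_csv(path, index=True, index_label="person")
    else:
        pd.DataFrame(X.data).to_csv(path, index=False, header=False)


def spec_to_config(spec: GeneratingModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def spec_from_config(path) -> GeneratingModelSpec:
    with open(path) as fh:
        return GeneratingModelSpec.from_dict(yaml.safe_load(fh))


def grid_from_config(path) -> tuple[list[SimulationCondition], list[str]]:
    """Load a study grid config.

    Layout::

        tests: [LR, M2]
        defaults: {reps: 500, bootstrap: 300, alphas: [0.05, 0.01]}
        conditions:
          - {family: rasch, N: 500, n: 10, seed: 1}
          - {family: multidim, trait_corr: 0.3, N: 100, n: 10, seed: 2}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    tests = [str(t).upper() for t in cfg.get("tests", ["LR"])]
    defaults = cfg.get("defaults", {})
    conditions = []
    for entry in cfg["conditions"]:
        merged = {**defaults, **entry}
        spec = GeneratingModelSpec.from_dict(merged)
        conditions.append(SimulationCondition(
            N=int(merged["N"]),
            n=int(merged["n"]),
            spec=spec,
            reps=int(merged.get("reps", 500)),
            alphas=tuple(merged.get("alphas", (0.05, 0.01))),
            seed=int(merged.get("seed", 0)),
            bootstrap=int(merged.get("bootstrap", 300)),
        ))
    return conditions, tests
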