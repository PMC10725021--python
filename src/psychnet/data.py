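"""Cohort data model and on-disk artifact I/O.

A :class:`CohortDataset` is a participants x variables table together with
one :class:`VariableSpec` per column.  Each spec declares the column's
statistical type (continuous vs categorical), its admissible range or level
codes, the community it belongs to (the source questionnaire -- used by the
bridge-centrality statistics) and its analysis role (symptom, factor or
covariate).

Data files are delimited text with a header row; the variable specification
is a YAML (or JSON) mapping ``column name -> spec fields``.  Estimated
networks are written as a tab-separated edge list plus a JSON metadata
sidecar, and round-trip bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataValidationError, SpecError

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
ROLES = ("symptom", "factor", "covariate")


@dataclass(frozen=True)
class VariableSpec:
    """Per-column metadata: type, admissible values, community, role."""

    name: str
    var_type: str = CONTINUOUS
    levels: tuple[int, ...] | None = None
    min_value: float | None = None
    max_value: float | None = None
    community: str = ""
    role: str = "factor"

    def __post_init__(self) -> None:
        if not self.name:
            raise SpecError("variable name must be non-empty")
        if self.var_type not in (CONTINUOUS, CATEGORICAL):
            raise SpecError(
                f"{self.name}: var_type must be 'continuous' or 'categorical', "
                f"got {self.var_type!r}"
            )
        if self.role not in ROLES:
            raise SpecError(f"{self.name}: role must be one of {ROLES}, got {self.role!r}")
        if not self.community:
            raise SpecError(f"{self.name}: community label must be non-empty")
        if self.var_type == CATEGORICAL:
            if self.levels is None or len(self.levels) < 2:
                raise SpecError(f"{self.name}: categorical spec needs >=2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise SpecError(f"{self.name}: duplicate level codes")
        else:
            if self.min_value is not None and self.max_value is not None:
                if self.min_value > self.max_value:
                    raise SpecError(
                        f"{self.name}: min_value {self.min_value} > max_value {self.max_value}"
                    )

    @property
    def is_categorical(self) -> bool:
        return self.var_type == CATEGORICAL

    def to_dict(self) -> dict:
        d: dict = {"type": self.var_type, "community": self.community, "role": self.role}
        if self.is_categorical:
            d["levels"] = list(self.levels)
        else:
            if self.min_value is not None:
                d["min"] = self.min_value
            if self.max_value is not None:
                d["max"] = self.max_value
        return d

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "VariableSpec":
        levels = d.get("levels")
        return cls(
            name=name,
            var_type=d.get("type", CONTINUOUS),
            levels=tuple(levels) if levels is not None else None,
            min_value=d.get("min"),
            max_value=d.get("max"),
            community=d.get("community", ""),
            role=d.get("role", "factor"),
        )


@dataclass
class CohortDataset:
    """A validated participants x variables table plus its specs.

    ``values`` is a DataFrame whose columns match ``specs`` in order.
    """

    values: pd.DataFrame
    specs: list[VariableSpec]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise SpecError("variable names must be unique within a dataset")
        if list(self.values.columns) != names:
            raise DataValidationError(
                "column order/names do not match specs: "
                f"{list(self.values.columns)} vs {names}"
            )
        validate_values(self.values, self.specs)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    @property
    def communities(self) -> dict[str, str]:
        return {s.name: s.community for s in self.specs}

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def subset(self, columns: Sequence[str], provenance: str | None = None) -> "CohortDataset":
        """New dataset restricted to ``columns`` (order as given)."""
        missing = [c for c in columns if c not in self.values.columns]
        if missing:
            raise SpecError(f"unknown columns requested: {missing}")
        specs = [self.spec(c) for c in columns]
        return CohortDataset(
            self.values[list(columns)].copy(),
            specs,
            provenance or self.provenance,
        )

    def with_values(self, values: pd.DataFrame, provenance: str | None = None) -> "CohortDataset":
        return CohortDataset(values, list(self.specs), provenance or self.provenance)


def validate_values(values: pd.DataFrame, specs: Sequence[VariableSpec]) -> None:
    """Raise :class:`DataValidationError` on any spec violation.

    Checks: numeric cells, declared level codes, declared bounds, no missing
    values, no constant column.
    """
    if values.isna().any().any():
        rows = values.index[values.isna().any(axis=1)].tolist()
        raise DataValidationError(f"missing values in rows {rows[:10]} after loading")
    for s in specs:
        col = values[s.name]
        if not np.issubdtype(col.dtype, np.number):
            raise DataValidationError(f"column {s.name!r} is not numeric")
        arr = col.to_numpy()
        if s.is_categorical:
            bad = ~np.isin(arr, np.asarray(s.levels))
            if bad.any():
                i = int(np.argmax(bad))
                raise DataValidationError(
                    f"column {s.name!r}, row {values.index[i]}: value {arr[i]} "
                    f"not a declared level {list(s.levels)}"
                )
        else:
            if s.min_value is not None and (arr < s.min_value).any():
                i = int(np.argmax(arr < s.min_value))
                raise DataValidationError(
                    f"column {s.name!r}, row {values.index[i]}: value {arr[i]} "
                    f"below minimum {s.min_value}"
                )
            if s.max_value is not None and (arr > s.max_value).any():
                i = int(np.argmax(arr > s.max_value))
                raise DataValidationError(
                    f"column {s.name!r}, row {values.index[i]}: value {arr[i]} "
                    f"above maximum {s.max_value}"
                )
        if np.all(arr == arr[0]) if len(arr) else False:
            raise DataValidationError(
                f"column {s.name!r} is constant; drop it before estimation"
            )


def read_spec_file(spec_path: str | Path) -> list[VariableSpec]:
    """Read a YAML/JSON variable-spec config (mapping name -> fields)."""
    text = Path(spec_path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping) or not raw:
        raise SpecError(f"{spec_path}: expected a non-empty mapping of column specs")
    return [VariableSpec.from_dict(str(name), d or {}) for name, d in raw.items()]


def write_spec_file(specs: Sequence[VariableSpec], spec_path: str | Path) -> None:
    mapping = {s.name: s.to_dict() for s in specs}
    Path(spec_path).write_text(yaml.safe_dump(mapping, sort_keys=False))


def read_dataset(
    path: str | Path,
    spec_path: str | Path,
    *,
    sep: str = ",",
    missing_policy: str = "listwise",
) -> CohortDataset:
    """Load and validate a delimited cohort file against its spec config.

    Columns present in the file but absent from the spec are ignored with a
    logged notice; a declared column missing from the file is fatal.  Rows
    with missing values are removed under the default listwise policy
    (``missing_policy="listwise"``, deletion count logged) or rejected
    outright (``"fail"``).
    """
    specs = read_spec_file(spec_path)
    try:
        table = pd.read_csv(path, sep=sep)
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise DataValidationError(f"could not parse {path}: {exc}") from exc

    declared = [s.name for s in specs]
    missing_cols = [c for c in declared if c not in table.columns]
    if missing_cols:
        raise DataValidationError(f"declared columns missing from {path}: {missing_cols}")
    extra = [c for c in table.columns if c not in declared]
    if extra:
        logger.info("ignoring %d undeclared columns: %s", len(extra), extra)
    table = table[declared]

    for name in declared:
        if not np.issubdtype(table[name].dtype, np.number):
            coerced = pd.to_numeric(table[name], errors="coerce")
            newly_bad = coerced.isna() & table[name].notna()
            if newly_bad.any():
                i = int(np.argmax(newly_bad.to_numpy()))
                raise DataValidationError(
                    f"column {name!r}, row {table.index[i]}: non-numeric cell "
                    f"{table[name].iloc[i]!r}"
                )
            table[name] = coerced

    n_before = len(table)
    if table.isna().any().any():
        if missing_policy == "listwise":
            table = table.dropna(axis=0)
            logger.warning(
                "listwise deletion removed %d of %d rows with missing values",
                n_before - len(table),
                n_before,
            )
        elif missing_policy == "fail":
            raise DataValidationError("missing values present and policy is 'fail'")
        else:
            raise SpecError(f"unknown missing_policy {missing_policy!r}")
    table = table.reset_index(drop=True)
    return CohortDataset(table, specs, provenance=str(path))


def write_dataset(data: CohortDataset, path: str | Path, *, sep: str = ",") -> None:
    data.values.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Network artifacts


@dataclass
class NetworkModel:
    """Symmetric weighted conditional-dependence graph.

    ``weights`` is a symmetric matrix with zero diagonal; ``sign_defined``
    marks edges whose sign is interpretable (False whenever either endpoint
    is categorical, in which case the stored weight is a magnitude >= 0).
    """

    nodes: list[str]
    communities: dict[str, str]
    weights: np.ndarray
    sign_defined: np.ndarray
    n: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        p = len(self.nodes)
        if self.weights.shape != (p, p):
            raise SpecError(f"weights shape {self.weights.shape} != ({p}, {p})")
        if not np.array_equal(self.weights, self.weights.T):
            raise SpecError("weight matrix must be exactly symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise SpecError("weight matrix must have zero diagonal")
        self.sign_defined = np.asarray(self.sign_defined, dtype=bool)
        if self.sign_defined.shape != (p, p):
            raise SpecError("sign_defined must match weights shape")
        unsigned_neg = (~self.sign_defined) & (self.weights < 0)
        np.fill_diagonal(unsigned_neg, False)
        if unsigned_neg.any():
            raise SpecError("unsigned edges must carry non-negative magnitudes")
        missing = [v for v in self.nodes if v not in self.communities]
        if missing:
            raise SpecError(f"nodes missing community labels: {missing}")

    @property
    def p(self) -> int:
        return len(self.nodes)

    def edge_list(self) -> list[tuple[str, str, float, bool]]:
        """Nonzero edges as (node_a, node_b, weight, sign_defined), i < j order."""
        out = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0:
                    out.append((self.nodes[i], self.nodes[j], float(w), bool(self.sign_defined[i, j])))
        return out

    def n_edges(self) -> int:
        return len(self.edge_list())


def write_network(network: NetworkModel, path: str | Path) -> None:
    """Write the nonzero edge list (TSV) plus a JSON metadata sidecar.

    The sidecar (``<path>.json``) records nodes, communities, sample size
    and estimation metadata; :func:`read_network` restores the edge weights
    bit-exactly (floats serialized with repr round-trip).
    """
    path = Path(path)
    lines = ["node_a\tnode_b\tweight\tsign_defined"]
    for a, b, w, sd in network.edge_list():
        lines.append(f"{a}\t{b}\t{w!r}\t{int(sd)}")
    try:
        path.write_text("\n".join(lines) + "\n")
        sidecar = {
            "nodes": network.nodes,
            "communities": network.communities,
            "n": network.n,
            "meta": network.meta,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    except OSError as exc:
        raise PsychnetIOError(f"cannot write network to {path}: {exc}") from exc


class PsychnetIOError(OSError):
    """Unwritable or unreadable artifact path."""


def read_network(path: str | Path) -> NetworkModel:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    nodes = list(sidecar["nodes"])
    index = {v: i for i, v in enumerate(nodes)}
    p = len(nodes)
    weights = np.zeros((p, p))
    sign_defined = np.ones((p, p), dtype=bool)
    lines = path.read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        a, b, w, sd = line.split("\t")
        i, j = index[a], index[b]
        weights[i, j] = weights[j, i] = float(w)
        sign_defined[i, j] = sign_defined[j, i] = bool(int(sd))
    return NetworkModel(
        nodes=nodes,
        communities=dict(sidecar["communities"]),
        weights=weights,
        sign_defined=sign_defined,
        n=int(sidecar.get("n", 0)),
        meta=dict(sidecar.get("meta", {})),
    )


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis table (centrality, stability, descriptives) as TSV."""
    table.to_csv(path, sep="\t", index=True)


__all__ = [
    "CONTINUOUS",
    "CATEGORICAL",
    "VariableSpec",
    "CohortDataset",
    "NetworkModel",
    "validate_values",
    "read_spec_file",
    "write_spec_file",
    "read_dataset",
    "write_dataset",
    "write_network",
    "read_network",
    "write_table",
    "replace",
]
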