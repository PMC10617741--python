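"""Participant-by-variable feature tables partitioned into five analysis domains.

The cohort is a table of continuous (and a few binary) measurements, one row
per participant, with a binary faller / non-faller outcome.  Every variable
belongs to exactly one of five domains -- balance, gait, clinical, strength,
body composition -- and the whole analysis strategy is organised around that
partition ("data packages").  Missing cells are carried as an explicit boolean
mask so that imputation is a deliberate, visible step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DOMAINS = ("balance", "gait", "clinical", "strength", "body_composition")

#: group coding used by every classifier and effect sign in the package
FALLER, NON_FALLER = "faller", "non_faller"
GROUP_CODE = {FALLER: 1, NON_FALLER: 0}


@dataclass(frozen=True)
class VariableSpec:
    """One measured variable: a unique name, its domain, kind and units."""

    name: str
    domain: str
    kind: str = "continuous"  # "continuous" | "binary"
    units: str = ""

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(
                f"unknown domain {self.domain!r} for {self.name!r}; "
                f"expected one of {DOMAINS}"
            )
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")


@dataclass
class FeatureTable:
    """Participants x variables matrix with group labels and a missing mask.

    ``values`` holds floats with NaN at missing cells; ``mask`` is True where
    a cell is missing.  ``group`` holds the labels ``"faller"`` /
    ``"non_faller"``; :attr:`y` gives the 1/0 coding (faller = 1).
    """

    participant_ids: list[str]
    group: list[str]
    variables: list[VariableSpec]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, p = self.values.shape
        if len(self.participant_ids) != n:
            raise ValueError("participant_ids length does not match row count")
        if len(self.group) != n:
            raise ValueError("group length does not match row count")
        if len(self.variables) != p:
            raise ValueError("variables length does not match column count")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values shape")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        levels = set(self.group)
        if not levels <= {FALLER, NON_FALLER}:
            raise ValueError(f"unexpected group labels: {levels}")
        # NaN and mask must agree: a masked cell is NaN, an unmasked cell finite
        self.values = self.values.copy()
        self.values[self.mask] = np.nan
        if np.isnan(self.values[~self.mask]).any():
            raise ValueError("NaN present in cells not covered by the mask")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def y(self) -> np.ndarray:
        """Group coding: faller = 1, non_faller = 0."""
        return np.array([GROUP_CODE[g] for g in self.group], dtype=int)

    @property
    def n_fallers(self) -> int:
        return int(self.y.sum())

    @property
    def n_nonfallers(self) -> int:
        return int(self.n - self.y.sum())

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "FeatureTable":
        """New table restricted to the given columns (order as given)."""
        idx = [self.names.index(nm) for nm in names]
        return FeatureTable(
            participant_ids=list(self.participant_ids),
            group=list(self.group),
            variables=[self.variables[i] for i in idx],
            values=self.values[:, idx].copy(),
            mask=self.mask[:, idx].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names, index=self.participant_ids)
        df.insert(0, "group", self.group)
        return df

    # -- persistence -----------------------------------------------------
    def save(self, data_path: str | Path, metadata_path: str | Path) -> None:
        """Write the data CSV and the variable-metadata sidecar CSV.

        Missing cells are written as empty strings; column order is the
        table's variable order, so writes are deterministic.
        """
        data_path, metadata_path = Path(data_path), Path(metadata_path)
        with open(data_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["participant_id", "group"] + self.names)
            for i, pid in enumerate(self.participant_ids):
                row: list[str] = [pid, self.group[i]]
                for j in range(self.p):
                    row.append("" if self.mask[i, j] else repr(float(self.values[i, j])))
                w.writerow(row)
        with open(metadata_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "domain", "kind", "units"])
            for v in self.variables:
                w.writerow([v.name, v.domain, v.kind, v.units])


def load_metadata(path: str | Path) -> dict[str, VariableSpec]:
    specs: dict[str, VariableSpec] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            specs[row["name"]] = VariableSpec(
                name=row["name"],
                domain=row["domain"],
                kind=row.get("kind", "continuous") or "continuous",
                units=row.get("units", "") or "",
            )
    return specs


def load_table(
    path: str | Path,
    group_column: str = "group",
    metadata: str | Path | Mapping[str, VariableSpec] | None = None,
    id_column: str = "participant_id",
    missing_token: str = "",
) -> FeatureTable:
    """Read a feature table from a CSV with a header row.

    The group column must contain exactly the two labels ``faller`` and
    ``non_faller``.  Domain tags come from a sidecar metadata CSV (columns
    name, domain, kind, units) or a mapping of :class:`VariableSpec`; without
    metadata, a ``domain__name`` column-prefix convention is used.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if group_column not in df.columns:
        raise ValueError(f"group column {group_column!r} not found")
    if id_column in df.columns:
        ids = df[id_column].tolist()
        df = df.drop(columns=[id_column])
    else:
        ids = [f"P{i + 1:03d}" for i in range(len(df))]
    group = df[group_column].tolist()
    df = df.drop(columns=[group_column])
    levels = sorted(set(group))
    if len(levels) != 2:
        raise ValueError(f"group column must have exactly 2 levels, got {levels}")
    if set(levels) != {FALLER, NON_FALLER}:
        raise ValueError(
            f"group labels must be {FALLER!r}/{NON_FALLER!r}, got {levels}"
        )
    for lv in levels:
        if group.count(lv) < 2:
            raise ValueError(f"fewer than 2 participants in group {lv!r}")
    names = list(df.columns)
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names in CSV header")

    if metadata is None:
        specs = []
        for nm in names:
            if "__" not in nm:
                raise ValueError(
                    f"no metadata given and column {nm!r} lacks a "
                    "'domain__name' prefix"
                )
            dom, _ = nm.split("__", 1)
            specs.append(VariableSpec(name=nm, domain=dom))
    else:
        if not isinstance(metadata, Mapping):
            metadata = load_metadata(metadata)
        missing_meta = [nm for nm in names if nm not in metadata]
        if missing_meta:
            raise ValueError(f"variables without metadata: {missing_meta}")
        specs = [metadata[nm] for nm in names]

    n, p = len(ids), len(names)
    values = np.full((n, p), np.nan)
    mask = np.zeros((n, p), dtype=bool)
    for j, nm in enumerate(names):
        for i, cell in enumerate(df[nm]):
            if cell == missing_token:
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} in column {nm!r}, row {i}"
                    ) from None
    return FeatureTable(ids, group, specs, values, mask)


def partition_domains(t: FeatureTable) -> dict[str, FeatureTable]:
    """Split a table into per-domain sub-tables ("data packages").

    Domains with no variables are omitted; the union of columns across the
    returned tables equals the parent's columns and no column appears twice.
    """
    out: dict[str, FeatureTable] = {}
    for dom in DOMAINS:
        names = [v.name for v in t.variables if v.domain == dom]
        if names:
            out[dom] = t.subset(names)
    return out


def concat_columns(tables: Iterable[FeatureTable]) -> FeatureTable:
    """Column-concatenate tables over the same participants (inverse of
    :func:`partition_domains` up to column order)."""
    tables = list(tables)
    first = tables[0]
    for t in tables[1:]:
        if t.participant_ids != first.participant_ids or t.group != first.group:
            raise ValueError("tables do not share participants/groups")
    return FeatureTable(
        participant_ids=list(first.participant_ids),
        group=list(first.group),
        variables=[v for t in tables for v in t.variables],
        values=np.hstack([t.values for t in tables]),
        mask=np.hstack([t.mask for t in tables]),
    )


def zscore_columns(t: FeatureTable, ddof: int = 1) -> FeatureTable:
    """Standardize each column to mean 0, sample SD 1 over observed entries.

    The missing mask is preserved.  Raises on constant columns (SD = 0) and on
    columns with fewer than two observed values.
    """
    vals = t.values.copy()
    for j, v in enumerate(t.variables):
        obs = vals[~t.mask[:, j], j]
        if obs.size < 2:
            raise ValueError(f"column {v.name!r} has fewer than 2 observed values")
        sd = obs.std(ddof=ddof)
        if sd == 0:
            raise ValueError(f"column {v.name!r} is constant (SD = 0)")
        vals[:, j] = (vals[:, j] - obs.mean()) / sd
    return replace(t, values=vals, mask=t.mask.copy())
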