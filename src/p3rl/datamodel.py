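"""Shared record containers, column typing and CSV input/output.

Every stage of the three-party protocol (the two data-holding sites and the
linkage centre) exchanges flat delimited tables.  A :class:`RecordTable` pairs
a pandas DataFrame of string cells with an explicit schema of
:class:`ColumnSpec` entries; the column *role* controls which downstream stage
is allowed to read a column (only ``plain_linkage`` and ``site_id`` columns may
ever reach the linkage centre unencrypted).  The linkage output is a
:class:`LinkTable` of mapped site-local identifiers that carries no person
identifiable content.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

MISSING = ""  # canonical in-memory missing value after cleaning


class Role(str, Enum):
    """What a column holds, hence which stage may read it in plain form."""

    SITE_ID = "site_id"
    SENSITIVE_STRING = "sensitive_string"
    SENSITIVE_DATE = "sensitive_date"
    PLAIN = "plain_linkage"
    PAYLOAD = "payload"


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    role: Role
    declared_format: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnSpec":
        return cls(name=d["name"], role=Role(d["role"]),
                   declared_format=d.get("format"))

    def to_dict(self) -> dict:
        d = {"name": self.name, "role": self.role.value}
        if self.declared_format:
            d["format"] = self.declared_format
        return d


class SchemaError(ValueError):
    """The table does not satisfy its declared schema."""


class ProtocolViolation(RuntimeError):
    """An operation was handed data in a state the protocol forbids."""


@dataclass
class RecordTable:
    """A site extract: ordered typed columns over string-valued rows.

    All cells are strings; :data:`MISSING` (the empty string) marks a missing
    value.  ``meta`` carries stage flags such as the cleaning-template
    fingerprint set by preprocessing and checked by encryption.
    """

    columns: list[ColumnSpec]
    df: pd.DataFrame
    site_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c for c in self.columns if c.role is Role.SITE_ID]
        if len(ids) != 1:
            raise SchemaError(
                f"exactly one site_id column required, found {len(ids)}")
        names = [c.name for c in self.columns]
        if list(self.df.columns) != names:
            raise SchemaError("DataFrame columns do not match schema order")
        dup = self.df[self.id_column][self.df[self.id_column].duplicated()]
        if len(dup):
            raise SchemaError(
                "duplicate site_id values: " + ", ".join(sorted(set(dup))))

    # -- convenience -------------------------------------------------------
    @property
    def id_column(self) -> str:
        return next(c.name for c in self.columns if c.role is Role.SITE_ID)

    def spec(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def columns_with_role(self, *roles: Role) -> list[str]:
        return [c.name for c in self.columns if c.role in roles]

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "RecordTable":
        return RecordTable(list(self.columns), self.df.copy(),
                           self.site_label, dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, lineterminator="\n")


def read_table(path: str | Path, schema: Sequence[ColumnSpec],
               site_label: str = "") -> RecordTable:
    """Read a delimited site extract against a declared schema.

    Unknown columns are kept with role ``payload``; missing cells become the
    empty string.  Duplicate site identifiers or a declared column absent from
    the file are hard errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    declared = {c.name: c for c in schema}
    missing_cols = [n for n in declared if n not in df.columns]
    if missing_cols:
        raise SchemaError("declared columns absent from file: "
                          + ", ".join(missing_cols))
    columns = [declared.get(n, ColumnSpec(n, Role.PAYLOAD))
               for n in df.columns]
    return RecordTable(columns=columns, df=df, site_label=site_label)


def load_schema(path: str | Path) -> list[ColumnSpec]:
    """Load a YAML schema file: ``columns: [{name, role, format?}, ...]``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [ColumnSpec.from_dict(d) for d in doc["columns"]]


def save_schema(schema: Iterable[ColumnSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"columns": [c.to_dict() for c in schema]}, fh,
                       sort_keys=False)


# ---------------------------------------------------------------------------
# Link table
# ---------------------------------------------------------------------------

DECISIONS = ("link", "possible", "nonlink")


@dataclass
class LinkTable:
    """Mapped site-A/site-B identifier pairs with decision and weight.

    Contains no sensitive content by construction: only the site-local
    identifiers, the total agreement weight and the decision class.
    """

    pairs: pd.DataFrame  # columns id_a, id_b, total_weight, decision
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = ["id_a", "id_b", "total_weight", "decision"]
        if list(self.pairs.columns) != expected:
            raise SchemaError(f"link table columns must be {expected}")
        if self.pairs.duplicated(subset=["id_a", "id_b"]).any():
            raise SchemaError("duplicate (id_a, id_b) pairs in link table")
        bad = set(self.pairs["decision"]) - set(DECISIONS)
        if bad:
            raise SchemaError(f"unknown decision classes: {sorted(bad)}")

    def links(self) -> pd.DataFrame:
        return self.pairs[self.pairs["decision"] == "link"]


def write_link_table(lt: LinkTable, path: str | Path) -> None:
    """Write the link table as CSV, byte-stable (sorted by id_a then id_b)."""
    out = lt.pairs.sort_values(["id_a", "id_b"], kind="mergesort")
    out.to_csv(path, index=False, lineterminator="\n")


def read_link_table(path: str | Path) -> LinkTable:
    df = pd.read_csv(path, dtype={"id_a": str, "id_b": str,
                                  "total_weight": float, "decision": str},
                     keep_default_na=False)
    return LinkTable(pairs=df)


def write_report(report: dict, path: str | Path) -> None:
    """Write the linkage report as JSON (counts and histograms only)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_fingerprint(params: dict) -> str:
    """Stable hash of public (non-secret) configuration parameters."""
    blob = json.dumps(params, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
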