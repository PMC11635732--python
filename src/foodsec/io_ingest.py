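"""Microdata ingestion: CSV / SAS transport reading, recoding, pooling.

Public-release survey files name the same logical variable differently
across 2-year cycles and encode refusals and "don't know" responses as
numeric sentinels.  A :class:`VariableMap` declares, per cycle, the
source column and a value-recode table for each logical variable;
reading applies the map and converts sentinel codes to typed missing
states.  Cycles are pooled by concatenation after recoding, with the
cycle label retained for multiyear weight construction.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Distinct missing states.  All three count as missing for inclusion /
#: exclusion rules; they are kept distinct so exclusion tallies can say why.
MISSING = float("nan")
MISSING_STATES = ("missing", "refused", "dont_know")


@dataclasses.dataclass
class VariableMap:
    """Mapping from logical variable names to per-cycle source columns.

    ``columns[logical][cycle]`` is the source column name;
    ``recodes[logical]`` optionally maps source codes to logical codes,
    with the strings ``"missing"``, ``"refused"`` and ``"dont_know"``
    recoding to missing.
    """

    columns: dict
    recodes: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "VariableMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        columns, recodes = {}, {}
        for logical, spec in raw["variables"].items():
            if isinstance(spec, str):
                columns[logical] = {"*": spec}
            else:
                src = spec["source"]
                columns[logical] = {"*": src} if isinstance(src, str) else dict(src)
                if "recode" in spec:
                    recodes[logical] = dict(spec["recode"])
        return cls(columns=columns, recodes=recodes)

    def source_column(self, logical: str, cycle: str) -> str:
        spec = self.columns[logical]
        if cycle in spec:
            return spec[cycle]
        if "*" in spec:
            return spec["*"]
        raise KeyError(f"variable {logical!r} has no mapping for cycle {cycle!r}")


def read_microdata(
    path,
    fmt: str = "csv",
    variable_map: VariableMap | None = None,
    cycle: str = "*",
) -> pd.DataFrame:
    """Read one cycle file into a logically-named respondent table.

    ``fmt`` is ``"csv"`` (UTF-8, header row) or ``"xpt"`` (SAS
    transport, read via pandas).  Columns not named by the map are
    ignored; a mapped column absent from the file is a hard error.
    Without a map, columns pass through unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        raw = pd.read_csv(path)
    elif fmt == "xpt":
        try:
            raw = pd.read_sas(path, format="xport")
        except Exception as exc:
            raise ValueError(f"malformed SAS transport file {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'xpt'")

    if variable_map is None:
        out = raw.copy()
    else:
        out = pd.DataFrame(index=raw.index)
        for logical in variable_map.columns:
            src = variable_map.source_column(logical, cycle)
            if src not in raw.columns:
                raise KeyError(
                    f"mapped column {src!r} (logical {logical!r}) missing from {path}"
                )
            col = raw[src]
            recode = variable_map.recodes.get(logical)
            if recode:
                col = col.map(lambda v, rc=recode: _apply_recode(v, rc))
            try:
                out[logical] = pd.to_numeric(col)
            except (ValueError, TypeError):
                out[logical] = col
    out["cycle"] = cycle
    return out


def _apply_recode(value, recode):
    if value in recode:
        target = recode[value]
        return np.nan if target in MISSING_STATES else target
    return value


def pool_cycles(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate recoded cycle tables into one analysis table."""
    return pd.concat(tables, ignore_index=True)


def write_microdata(table: pd.DataFrame, path) -> None:
    """Write a typed table as UTF-8 CSV (the round-trippable dialect)."""
    table.to_csv(path, index=False)


def apply_inclusion_filter(
    table: pd.DataFrame, min_age: int = 60
) -> tuple[pd.DataFrame, dict]:
    """Restrict to the analytic sample; tally exclusions by reason.

    Retains respondents aged ``min_age`` or older with all 10 AFSSM
    items and all 6 PFS items non-missing.  Each excluded record counts
    under exactly one reason, checked in order: ``age``,
    ``afssm_incomplete``, ``pfs_incomplete``.
    """
    from . import scales

    afssm_ok = ~table[scales.AFSSM_ITEMS].isna().any(axis=1)
    pfs_ok = ~table[scales.PFS_ITEMS].isna().any(axis=1)
    age_ok = table["age_years"] >= min_age

    tally = {
        "age": int((~age_ok).sum()),
        "afssm_incomplete": int((age_ok & ~afssm_ok).sum()),
        "pfs_incomplete": int((age_ok & afssm_ok & ~pfs_ok).sum()),
    }
    keep = age_ok & afssm_ok & pfs_ok
    return table[keep].reset_index(drop=True), tally
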