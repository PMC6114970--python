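"""Panel schema, concentration tables, validation and reference flags.

The data model is a sample × analyte concentration matrix in μmol/L of
plasma.  Missing values are carried as NaN, never as zero: input zeros
are treated as below the limit of detection (LOD) and, by default,
replaced with half the per-analyte minimum positive value — the common
targeted-metabolomics convention, which also keeps downstream ratios
finite.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import _roster
from .nomenclature import parse_metabolite_name

__all__ = [
    "PanelSchema",
    "SampleTable",
    "ReferenceRanges",
    "ValidationReport",
    "default_schema",
    "load_panel_table",
    "write_panel_table",
    "validate_panel",
    "reference_flags",
]

RESERVED_COLUMNS = ("sample_id", "group")


@dataclass(frozen=True)
class PanelSchema:
    """Ordered analyte roster with class assignments."""

    metabolite_names: tuple[str, ...]
    class_of: Mapping[str, str]
    include_energy: bool = True

    def __post_init__(self):
        names = self.metabolite_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate analyte names in schema")
        missing = [n for n in names if n not in self.class_of]
        if missing:
            raise ValueError(f"analytes without class assignment: {missing}")

    @property
    def counts_by_class(self) -> dict[str, int]:
        return dict(Counter(self.class_of[n] for n in self.metabolite_names))

    def __contains__(self, name: str) -> bool:
        return name in self.class_of

    def to_json(self) -> str:
        """Schema export: names, classes, and structured parse fields."""
        entries = []
        for name in self.metabolite_names:
            parsed = parse_metabolite_name(name)
            entry = {"name": name, "class": self.class_of[name]}
            if hasattr(parsed, "family"):
                entry.update(
                    family=parsed.family, bond=parsed.bond,
                    carbons=parsed.carbons, double_bonds=parsed.double_bonds,
                    hydroxyl=parsed.hydroxyl, dicarboxyl=parsed.dicarboxyl,
                )
            entries.append(entry)
        doc = {
            "n_analytes": len(entries),
            "essential_aa": list(_roster.ESSENTIAL_AA),
            "non_essential_aa": list(_roster.NON_ESSENTIAL_AA),
            "analytes": entries,
        }
        return json.dumps(doc, indent=1)


def default_schema(include_energy: bool = True) -> PanelSchema:
    """The 186-analyte core panel, optionally with the 5 energy channels.

    Lactate and the combined pyruvate/oxaloacetate channel (named
    ``Pyr``) were measured only for part of the study population, so
    the energy metabolites are an extension rather than core analytes.
    """
    names = _roster.CORE_PANEL + (_roster.ENERGY if include_energy else ())
    return PanelSchema(names, {n: _roster.CLASS_OF[n] for n in names},
                       include_energy)


@dataclass
class SampleTable:
    """Sample × analyte concentration matrix with group labels.

    ``data`` is indexed by sample_id with analyte columns (float,
    NaN = missing); ``group`` is a per-sample label aligned to it.
    """

    data: pd.DataFrame
    group: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample_ids: {dupes}")
        self.data.index.name = "sample_id"
        self.group = self.group.reindex(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class ReferenceRanges:
    """Clinically reported reference levels (μmol/L; ratios unitless)."""

    gln_normal_mean: float = 800.0
    glu_normal: float = 40.0
    asp_normal_range: tuple[float, float] = (0.0, 5.0)
    phe_normal_range: tuple[float, float] = (40.0, 74.0)
    lac_pyr_upper_normal: float = 25.8

    def __post_init__(self):
        for lo, hi in (self.asp_normal_range, self.phe_normal_range):
            if lo > hi:
                raise ValueError("reference range has lower > upper")


@dataclass
class ValidationReport:
    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)
    n_missing: int = 0
    missing_by_analyte: dict[str, int] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return not self.errors


def _dialect_map(schema: PanelSchema) -> dict[str, str]:
    """Map normalized dialect keys (dotted/underscored exports) back to
    canonical names."""
    import re

    out = {}
    for name in schema.metabolite_names:
        key = re.sub(r"[^0-9A-Za-z]+", ".", name).strip(".").lower()
        out[key] = name
    return out


def normalize_analyte_name(name: str, schema: PanelSchema) -> str | None:
    """Resolve a (possibly dotted or underscored) header to its canonical
    analyte name, or None if it is not a panel analyte."""
    import re

    if name in schema.class_of:
        return name
    key = re.sub(r"[^0-9A-Za-z]+", ".", name).strip(".").lower()
    return _dialect_map(schema).get(key)


def load_panel_table(
    path,
    schema: PanelSchema | None = None,
    lod_policy: str = "half_min",
) -> SampleTable:
    """Read a delimited concentration table.

    The file must have a header row with a ``sample_id`` column (or the
    first column is taken as sample ids), an optional ``group`` column,
    and analyte columns in any recognized dialect.  ``lod_policy``
    governs input zeros: ``half_min`` (default) replaces them with half
    the analyte's minimum positive value, ``missing`` masks them, and
    ``keep`` leaves them at zero.
    """
    if schema is None:
        schema = default_schema()
    if lod_policy not in ("half_min", "missing", "keep"):
        raise ValueError(f"unknown lod_policy {lod_policy!r}")
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    raw = pd.read_csv(path, sep=sep)
    if raw.empty and raw.columns.empty:
        raise ValueError(f"unreadable or empty table: {path}")

    cols = list(raw.columns)
    if "sample_id" in cols:
        raw = raw.set_index("sample_id")
    else:
        raw = raw.set_index(cols[0])
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample_ids: {dupes}")

    group = raw.pop("group").astype(str) if "group" in raw.columns else \
        pd.Series("unknown", index=raw.index)

    rename, keep = {}, []
    for c in raw.columns:
        canon = normalize_analyte_name(str(c), schema)
        if canon is not None:
            rename[c] = canon
            keep.append(c)
    if not keep:
        raise ValueError("no recognizable analyte columns in table")
    extra_meta = {
        c: raw[c] for c in raw.columns if c not in keep
    }
    data = raw[keep].rename(columns=rename).astype(float)

    if lod_policy == "missing":
        data = data.where(data != 0.0)
    elif lod_policy == "half_min":
        for c in data.columns:
            col = data[c]
            zero = col == 0.0
            if zero.any():
                pos = col[col > 0]
                data.loc[zero, c] = pos.min() / 2.0 if len(pos) else np.nan

    return SampleTable(data=data, group=group,
                       metadata={k: v.to_dict() for k, v in extra_meta.items()})


def write_panel_table(table: SampleTable, path, schema: PanelSchema | None = None):
    """Write a SampleTable as CSV/TSV with analytes in schema order.

    A write-then-read round trip (with ``lod_policy='keep'``) preserves
    finite values bit-exactly via shortest-repr float formatting.
    """
    if schema is None:
        schema = default_schema()
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    ordered = [n for n in schema.metabolite_names if n in table.data.columns]
    ordered += [c for c in table.data.columns if c not in ordered]
    out = table.data[ordered].copy()
    out.insert(0, "group", table.group)
    out.index.name = "sample_id"
    with open(path, "w", newline="") as fh:
        fh.write(sep.join(["sample_id", "group"] + ordered) + "\n")
        for sid, row in out.iterrows():
            cells = [str(sid), str(row["group"])]
            for c in ordered:
                v = row[c]
                cells.append("" if pd.isna(v) else repr(float(v)))
            fh.write(sep.join(cells) + "\n")


def validate_panel(table: SampleTable, schema: PanelSchema | None = None) -> ValidationReport:
    """Check a table against the schema.

    Negative concentrations are errors; columns outside the schema are
    warnings; missingness is counted per analyte.  Problems are
    reported, never raised, and the report is a pure function of the
    input (validation is idempotent).
    """
    if schema is None:
        schema = default_schema()
    report = ValidationReport()
    for c in table.data.columns:
        if c not in schema.class_of:
            report.warnings.append(("", c, "column not in panel schema"))
    neg = table.data < 0
    for sid in table.data.index[neg.any(axis=1)]:
        for c in table.data.columns[neg.loc[sid]]:
            report.errors.append(
                (str(sid), c, f"negative concentration {table.data.at[sid, c]}")
            )
    miss = table.data.isna().sum()
    report.missing_by_analyte = {c: int(m) for c, m in miss.items() if m}
    report.n_missing = int(miss.sum())
    return report


# Flag policy: hypoglutaminemia below half the normal mean; glutamate
# and aspartate flagged above twice-normal / upper-normal respectively.
_HYPOGLN_FRACTION = 0.5
_HYPERGLU_FACTOR = 2.0


def reference_flags(
    table: SampleTable, ranges: ReferenceRanges | None = None
) -> dict[str, set[str]]:
    """Flag each sample against the printed reference levels.

    Flags: ``oxphos_deficiency`` (Lac/Pyr > 25.8, the oxidative-
    phosphorylation deficiency cut-off), ``indeterminate_lac_pyr``
    (Pyr = 0), ``hyperphenylalaninemia`` (Phe above upper normal),
    ``hypoglutaminemia``, ``hyperglutamatemia``, ``hyperaspartatemia``.
    Checks whose analytes are absent are skipped with a warning.
    """
    if ranges is None:
        ranges = ReferenceRanges()
    cols = set(table.data.columns)
    checks = {
        "oxphos_deficiency": {"Lac", "Pyr"},
        "hyperphenylalaninemia": {"Phe"},
        "hypoglutaminemia": {"Gln"},
        "hyperglutamatemia": {"Glu"},
        "hyperaspartatemia": {"Asp"},
    }
    active = {}
    for flag, needed in checks.items():
        if needed <= cols:
            active[flag] = needed
        else:
            warnings.warn(
                f"skipping {flag}: missing analytes {sorted(needed - cols)}"
            )

    flags: dict[str, set[str]] = {}
    for sid, row in table.data.iterrows():
        fs: set[str] = set()
        if "oxphos_deficiency" in active:
            lac, pyr = row.get("Lac"), row.get("Pyr")
            if pd.notna(lac) and pd.notna(pyr):
                if pyr == 0:
                    fs.add("indeterminate_lac_pyr")
                elif lac / pyr > ranges.lac_pyr_upper_normal:
                    fs.add("oxphos_deficiency")
        if "hyperphenylalaninemia" in active:
            phe = row.get("Phe")
            if pd.notna(phe) and phe > ranges.phe_normal_range[1]:
                fs.add("hyperphenylalaninemia")
        if "hypoglutaminemia" in active:
            gln = row.get("Gln")
            if pd.notna(gln) and gln < _HYPOGLN_FRACTION * ranges.gln_normal_mean:
                fs.add("hypoglutaminemia")
        if "hyperglutamatemia" in active:
            glu = row.get("Glu")
            if pd.notna(glu) and glu > _HYPERGLU_FACTOR * ranges.glu_normal:
                fs.add("hyperglutamatemia")
        if "hyperaspartatemia" in active:
            asp = row.get("Asp")
            if pd.notna(asp) and asp > ranges.asp_normal_range[1]:
                fs.add("hyperaspartatemia")
        flags[str(sid)] = fs
    return flags
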