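"""Delimited-text readers/writers for cross, cage, fecundity, and allele tables.

All files are UTF-8 comma-separated with a header row.  Counts are stored
as plain integers; frequencies are never stored, only derived on read.
Lines starting with ``#`` are metadata comments (the writers record the
RNG seed and generating parameters there); readers ignore them.
Generation indexing is 0-based with generation 0 = founders.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import GENOTYPES, DriveParams, Genotype, Sex
from .simulate import CageTrajectory
from .summaries import AlleleClassCounts, CrossRecord, FecundityRecord

__all__ = [
    "read_table",
    "read_cross_table",
    "read_cage_table",
    "read_fecundity_table",
    "read_allele_class_table",
    "write_cross_table",
    "write_cage_table",
    "write_fecundity_table",
    "write_allele_class_table",
    "read_s1_xlsx",
    "SchemaError",
]

SCHEMAS = {
    "cross": ("vial_id", "drive_parent_sex", "n_dsred_pos", "n_total"),
    "cage": ("cage_id", "generation", "n_dsred_pos", "n_total"),
    "fecundity": ("female_id", "genotype_label", "octopamine", "day", "eggs"),
    "allele_class": ("class", "count", "denominator", "denominator_convention"),
}

_TRUTH_PREFIX = "truth_"


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)


def _require_columns(df: pd.DataFrame, schema_name: str) -> None:
    missing = [c for c in SCHEMAS[schema_name] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema_name} table is missing required column(s): {missing}"
        )


def _as_int(df: pd.DataFrame, col: str, schema_name: str) -> np.ndarray:
    out = np.empty(len(df), dtype=np.int64)
    for i, raw in enumerate(df[col]):
        try:
            val = int(str(raw).strip())
        except (TypeError, ValueError):
            raise SchemaError(
                f"{schema_name} table row {i + 1}, column {col!r}: "
                f"expected an integer, got {raw!r}"
            ) from None
        out[i] = val
    return out


def _check_counts(pos, tot, schema_name: str) -> None:
    for i, (p, t) in enumerate(zip(pos, tot)):
        if p < 0 or t < 0:
            raise SchemaError(
                f"{schema_name} table row {i + 1}: negative count"
            )
        if p > t:
            raise SchemaError(
                f"{schema_name} table row {i + 1}: n_dsred_pos ({p}) exceeds "
                f"n_total ({t})"
            )


def read_cross_table(path) -> list[CrossRecord]:
    df = _read_csv(path)
    _require_columns(df, "cross")
    pos = _as_int(df, "n_dsred_pos", "cross")
    tot = _as_int(df, "n_total", "cross")
    _check_counts(pos, tot, "cross")
    records = []
    for i in range(len(df)):
        sex_raw = str(df["drive_parent_sex"].iloc[i]).strip().lower()
        try:
            sex = Sex(sex_raw)
        except ValueError:
            raise SchemaError(
                f"cross table row {i + 1}, column 'drive_parent_sex': "
                f"expected 'female' or 'male', got {sex_raw!r}"
            ) from None
        variant = None
        if "variant_class" in df.columns:
            v = df["variant_class"].iloc[i]
            variant = None if pd.isna(v) else str(v)
        records.append(
            CrossRecord(
                vial_id=str(df["vial_id"].iloc[i]),
                drive_parent_sex=sex,
                n_dsred_pos=int(pos[i]),
                n_total=int(tot[i]),
                variant_class=variant,
            )
        )
    return records


def read_cage_table(path) -> list[CageTrajectory]:
    df = _read_csv(path)
    _require_columns(df, "cage")
    gen = _as_int(df, "generation", "cage")
    pos = _as_int(df, "n_dsred_pos", "cage")
    tot = _as_int(df, "n_total", "cage")
    _check_counts(pos, tot, "cage")
    df = df.assign(generation=gen, n_dsred_pos=pos, n_total=tot)
    truth_cols = [c for c in df.columns if c.startswith(_TRUTH_PREFIX)]
    trajectories = []
    for cage_id, grp in df.groupby("cage_id", sort=True):
        grp = grp.sort_values("generation")
        gens = grp["generation"].to_numpy()
        if not np.array_equal(gens, np.arange(len(gens))):
            raise SchemaError(
                f"cage {cage_id}: generations must be consecutive starting at 0, "
                f"got {gens.tolist()}"
            )
        truth = None
        if truth_cols:
            truth = []
            for _, row in grp.iterrows():
                rec: dict[Genotype, int] = {}
                for col in truth_cols:
                    label = col[len(_TRUTH_PREFIX):]
                    g = Genotype.from_string(f"{label[0]}/{label[1]}")
                    rec[g] = int(row[col])
                truth.append(rec)
        trajectories.append(
            CageTrajectory(
                cage_id=str(cage_id),
                n_dsred_pos=[int(x) for x in grp["n_dsred_pos"]],
                n_total=[int(x) for x in grp["n_total"]],
                truth=truth,
            )
        )
    return trajectories


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def read_fecundity_table(path) -> list[FecundityRecord]:
    df = _read_csv(path)
    _require_columns(df, "fecundity")
    day = _as_int(df, "day", "fecundity")
    eggs = _as_int(df, "eggs", "fecundity")
    records = []
    for i in range(len(df)):
        if eggs[i] < 0:
            raise SchemaError(f"fecundity table row {i + 1}: negative egg count")
        octo_raw = str(df["octopamine"].iloc[i]).strip().lower()
        if octo_raw not in _BOOL:
            raise SchemaError(
                f"fecundity table row {i + 1}, column 'octopamine': "
                f"expected a boolean, got {octo_raw!r}"
            )
        records.append(
            FecundityRecord(
                female_id=str(df["female_id"].iloc[i]),
                genotype_label=str(df["genotype_label"].iloc[i]).strip(),
                octopamine=_BOOL[octo_raw],
                day=int(day[i]),
                eggs=int(eggs[i]),
            )
        )
    return records


def read_allele_class_table(path) -> AlleleClassCounts:
    df = _read_csv(path)
    _require_columns(df, "allele_class")
    count = _as_int(df, "count", "allele_class")
    denom = _as_int(df, "denominator", "allele_class")
    if len(set(denom)) != 1:
        raise SchemaError("allele_class table: denominator must be constant")
    conv = set(str(x).strip() for x in df["denominator_convention"])
    if len(conv) != 1:
        raise SchemaError(
            "allele_class table: denominator_convention must be constant"
        )
    counts = {
        str(cls).strip(): int(n) for cls, n in zip(df["class"], count)
    }
    return AlleleClassCounts(
        counts=counts,
        denominator=int(denom[0]),
        denominator_convention=conv.pop(),
    )


_READERS = {
    "cross": read_cross_table,
    "cage": read_cage_table,
    "fecundity": read_fecundity_table,
    "allele_class": read_allele_class_table,
}


def read_table(path, schema_name: str):
    """Read and validate a delimited table against a named schema."""
    if schema_name not in _READERS:
        raise ValueError(
            f"unknown schema {schema_name!r}; choose from {sorted(_READERS)}"
        )
    return _READERS[schema_name](path)


def _write_header(fh, seed, params: DriveParams | None, extra: dict | None = None):
    from . import __version__

    fh.write(f"# drivecage {__version__}\n")
    fh.write(f"# seed = {seed}\n")
    if params is not None:
        fields = {f.name: getattr(params, f.name)
                  for f in dataclasses.fields(params)}
        fh.write("# params: " + ", ".join(f"{k}={v}" for k, v in fields.items()) + "\n")
    for k, v in (extra or {}).items():
        fh.write(f"# {k} = {v}\n")


def write_cross_table(path, records: list[CrossRecord], seed=None,
                      params: DriveParams | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_header(fh, seed, params)
        cols = ["vial_id", "drive_parent_sex", "n_dsred_pos", "n_total",
                "variant_class"]
        fh.write(",".join(cols) + "\n")
        for r in records:
            fh.write(
                f"{r.vial_id},{r.drive_parent_sex.value},{r.n_dsred_pos},"
                f"{r.n_total},{r.variant_class if r.variant_class else ''}\n"
            )


def write_cage_table(path, trajectories: list[CageTrajectory], seed=None,
                     params: DriveParams | None = None,
                     include_truth: bool = True) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_header(fh, seed, params)
        truth = include_truth and all(t.truth is not None for t in trajectories)
        cols = ["cage_id", "generation", "n_dsred_pos", "n_total"]
        if truth:
            cols += [f"{_TRUTH_PREFIX}{g.a1.value}{g.a2.value}" for g in GENOTYPES]
        fh.write(",".join(cols) + "\n")
        for t in trajectories:
            for gen in range(t.n_generations):
                row = [t.cage_id, str(gen), str(t.n_dsred_pos[gen]),
                       str(t.n_total[gen])]
                if truth:
                    row += [str(t.truth[gen].get(g, 0)) for g in GENOTYPES]
                fh.write(",".join(row) + "\n")


def write_fecundity_table(path, records: list[FecundityRecord], seed=None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_header(fh, seed, None)
        fh.write("female_id,genotype_label,octopamine,day,eggs\n")
        for r in records:
            fh.write(
                f"{r.female_id},{r.genotype_label},"
                f"{'true' if r.octopamine else 'false'},{r.day},{r.eggs}\n"
            )


def write_allele_class_table(path, counts: AlleleClassCounts, seed=None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        _write_header(fh, seed, None)
        fh.write("class,count,denominator,denominator_convention\n")
        for cls, n in counts.counts.items():
            fh.write(
                f"{cls},{n},{counts.denominator},{counts.denominator_convention}\n"
            )


def read_s1_xlsx(path, sheet_name, column_map: dict[str, str],
                 schema_name: str = "cross"):
    """Config-driven import of a deposited XLSX sheet into a package schema.

    ``column_map`` maps required schema column names to the sheet's actual
    column headers (deposited workbooks rarely use machine-friendly names,
    so the mapping is explicit rather than guessed).  The mapped frame is
    round-tripped through the CSV reader so all schema validation applies.
    """
    import tempfile

    df = pd.read_excel(path, sheet_name=sheet_name, engine="openpyxl")
    missing_req = [c for c in SCHEMAS[schema_name] if c not in column_map]
    if missing_req:
        raise SchemaError(
            f"column_map must cover schema columns, missing: {missing_req}"
        )
    missing_src = [v for v in column_map.values() if v not in df.columns]
    if missing_src:
        raise SchemaError(f"sheet lacks mapped column(s): {missing_src}")
    out = df[[column_map[c] for c in SCHEMAS[schema_name]]].copy()
    out.columns = list(SCHEMAS[schema_name])
    with tempfile.NamedTemporaryFile(
        "w", suffix=".csv", delete=False, encoding="utf-8"
    ) as tmp:
        out.to_csv(tmp.name, index=False)
        name = tmp.name
    try:
        return read_table(name, schema_name)
    finally:
        Path(name).unlink(missing_ok=True)
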