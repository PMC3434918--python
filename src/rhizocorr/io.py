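"""Data model and I/O for the plant-level fitness table.

The unit of observation is one plant: a *Medicago truncatula* genotype grown
with one of two rhizobium strain mixes (or uninoculated control) on soil with
or without carvacrol, scored for nodule count (rhizobium fitness proxy) and
fruit count (plant fitness proxy).  The full factorial design is
6 genotypes x (2 mixes + control) x 2 soils x 5 replicates = 180 plants.

Tables are exchanged as UTF-8 comma-separated files with a mandatory header
and fixed column names (see :data:`REQUIRED_COLUMNS`).  Categorical levels
are case-sensitive strings and are never coerced, so distinct genotype labels
cannot silently merge.  Control plants live in the same table as inoculated
plants (``rhizobium_mix == "control"``) and are excluded by downstream
filters, not stored separately.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    OverwriteError,
    ParseError,
    SchemaError,
    ValidationError,
)

REQUIRED_COLUMNS = (
    "plant_id",
    "medicago_genotype",
    "rhizobium_mix",
    "soil_treatment",
    "replicate",
    "nodule_count",
    "fruit_count",
)

#: label of the uninoculated control "mix"
CONTROL_MIX = "control"

#: the two soil environments
SOIL_LEVELS = ("control", "carvacrol")

KEY_COLUMNS = ("medicago_genotype", "rhizobium_mix", "soil_treatment", "replicate")


@dataclass(frozen=True)
class PlantRecord:
    """One plant's factor levels and its two fitness counts."""

    plant_id: str
    medicago_genotype: str
    rhizobium_mix: str
    soil_treatment: str
    replicate: int
    nodule_count: int
    fruit_count: int

    def __post_init__(self):
        if self.nodule_count < 0 or self.fruit_count < 0:
            raise ValidationError(
                f"plant {self.plant_id}: counts must be nonnegative integers"
            )


@dataclass(frozen=True)
class DesignSpec:
    """Dimensions of the balanced factorial design.

    ``g = n_genotypes * n_mixes`` is the number of plant-genotype x
    rhizobium-mix associations per soil environment (12 in the full design).
    """

    n_genotypes: int = 6
    n_mixes: int = 2
    include_control: bool = True
    n_soils: int = 2
    k: int = 5

    def __post_init__(self):
        for name in ("n_genotypes", "n_mixes", "n_soils", "k"):
            if getattr(self, name) < 1:
                raise ValidationError(f"DesignSpec.{name} must be >= 1")

    @property
    def g(self) -> int:
        return self.n_genotypes * self.n_mixes

    @property
    def n_plants(self) -> int:
        mixes = self.n_mixes + (1 if self.include_control else 0)
        return self.n_genotypes * mixes * self.n_soils * self.k


@dataclass(frozen=True)
class BalanceReport:
    """Outcome of :func:`check_balance`.

    ``k`` is inferred from the data (the modal cell count); balance means
    every (genotype, mix, soil) cell — control cells included when present —
    holds exactly ``k`` records.
    """

    balanced: bool
    g: int
    k: int
    n_records: int
    offending_cells: tuple = ()

    def require(self):
        from .errors import UnbalancedDesignError

        if not self.balanced:
            raise UnbalancedDesignError(
                f"design is unbalanced; offending cells: {list(self.offending_cells)}",
                offending_cells=self.offending_cells,
            )


def records_to_frame(records: Iterable[PlantRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[PlantRecord]:
    return [
        PlantRecord(
            plant_id=str(row.plant_id),
            medicago_genotype=str(row.medicago_genotype),
            rhizobium_mix=str(row.rhizobium_mix),
            soil_treatment=str(row.soil_treatment),
            replicate=int(row.replicate),
            nodule_count=int(row.nodule_count),
            fruit_count=int(row.fruit_count),
        )
        for row in df.itertuples(index=False)
    ]


def _check_columns(df: pd.DataFrame):
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def _parse_int_column(df: pd.DataFrame, column: str, minimum: int | None) -> pd.Series:
    raw = df[column]
    values = pd.to_numeric(raw, errors="coerce")
    bad = values.isna() | (values != np.floor(values))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"column {column!r}, data row {row + 1}: "
            f"{raw.iloc[row]!r} is not an integer"
        )
    values = values.astype(int)
    if minimum is not None and (values < minimum).any():
        row = int(np.flatnonzero((values < minimum).to_numpy())[0])
        raise ParseError(
            f"column {column!r}, data row {row + 1}: "
            f"{int(values.iloc[row])} is below the minimum {minimum}"
        )
    return values


def validate_table(df: pd.DataFrame, *, allow_contamination: bool = False) -> pd.DataFrame:
    """Validate a raw table and return a typed copy.

    Counts must be nonnegative integers, the factor key
    (genotype, mix, soil, replicate) must be unique, and control-mix plants
    must carry zero nodules unless ``allow_contamination`` is set (control
    roots were inspected for nodules; a nodulated control means contamination).
    """
    _check_columns(df)
    out = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    for col in ("plant_id", "medicago_genotype", "rhizobium_mix", "soil_treatment"):
        out[col] = out[col].astype(str)
    out["replicate"] = _parse_int_column(out, "replicate", minimum=1)
    out["nodule_count"] = _parse_int_column(out, "nodule_count", minimum=0)
    out["fruit_count"] = _parse_int_column(out, "fruit_count", minimum=0)

    dup = out.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = tuple(out.iloc[row][list(KEY_COLUMNS)])
        raise ValidationError(f"duplicate (genotype, mix, soil, replicate) key {key}")

    controls = out["rhizobium_mix"] == CONTROL_MIX
    nodulated = controls & (out["nodule_count"] > 0)
    if nodulated.any() and not allow_contamination:
        ids = out.loc[nodulated, "plant_id"].tolist()
        raise ValidationError(
            "uninoculated control plant(s) with nodules "
            f"(contamination?): {ids}; pass allow_contamination=True to keep them"
        )
    return out.reset_index(drop=True)


def read_table(path, *, allow_contamination: bool = False, **csv_options) -> pd.DataFrame:
    """Read and validate a plant-level CSV table.

    Returns a typed :class:`pandas.DataFrame` with exactly the required
    columns.  An empty file with a header yields an empty frame.
    """
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, **csv_options)
    if len(df) == 0:
        warnings.warn(f"{path} contains a header but no records", stacklevel=2)
    return validate_table(df, allow_contamination=allow_contamination)


def write_table(df: pd.DataFrame, path, *, force: bool = False) -> pathlib.Path:
    """Write a plant table as CSV; refuses to overwrite unless ``force``."""
    path = pathlib.Path(path)
    if path.exists() and not force:
        raise OverwriteError(f"{path} exists; pass force=True to overwrite")
    _check_columns(df)
    df.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False)
    return path


def check_balance(df: pd.DataFrame, design: DesignSpec | None = None) -> BalanceReport:
    """Report whether every factor cell holds the same number of replicates.

    ``k`` is the modal cell count observed in the data (balance is a property
    of equal cell sizes, not of any particular ``k``).  ``g`` counts the
    inoculated genotype x mix associations per environment.  Row order is
    irrelevant.  Downstream moment estimation refuses unbalanced input via
    :meth:`BalanceReport.require`.
    """
    _check_columns(df)
    if len(df) == 0:
        return BalanceReport(balanced=True, g=0, k=0, n_records=0)

    genotypes = sorted(df["medicago_genotype"].unique())
    mixes = sorted(m for m in df["rhizobium_mix"].unique())
    soils = sorted(df["soil_treatment"].unique())
    inoc_mixes = [m for m in mixes if m != CONTROL_MIX]

    counts = df.groupby(
        ["medicago_genotype", "rhizobium_mix", "soil_treatment"], sort=True
    ).size()
    values, freqs = np.unique(counts.to_numpy(), return_counts=True)
    k = int(values[np.argmax(freqs)])

    offending = []
    for geno in genotypes:
        for mix in mixes:
            for soil in soils:
                n = int(counts.get((geno, mix, soil), 0))
                if n != k:
                    offending.append((geno, mix, soil, n))

    g = len(genotypes) * len(inoc_mixes)
    if design is not None:
        if len(genotypes) != design.n_genotypes or len(inoc_mixes) != design.n_mixes:
            offending.append(
                ("levels", f"{len(genotypes)} genotypes x {len(inoc_mixes)} mixes", "", 0)
            )
    return BalanceReport(
        balanced=not offending,
        g=g,
        k=k,
        n_records=int(len(df)),
        offending_cells=tuple(offending),
    )


# ---------------------------------------------------------------------------
# result tables


def anova_table_frame(table) -> pd.DataFrame:
    """Render an AnovaTable as a Source/df/SS/F/P frame."""
    rows = [
        {"source": r.source, "df": r.df, "ss": r.ss, "f": r.f, "p": r.p}
        for r in table.rows
    ]
    return pd.DataFrame(rows, columns=["source", "df", "ss", "f", "p"])


def correlation_table_frame(results: Sequence) -> pd.DataFrame:
    """Render per-environment correlation results as a tidy table.

    Columns: environment, n, r_G, se_rG, r_E, se_rE — one row per soil
    environment.  Undefined correlations (negative moment variances) appear
    as empty cells.
    """
    rows = []
    for res in results:
        rows.append(
            {
                "environment": res.environment,
                "n": res.n,
                "r_G": res.r_G.value if res.r_G.defined else np.nan,
                "se_rG": res.se_rG if res.se_rG is not None else np.nan,
                "r_E": res.r_E.value if res.r_E.defined else np.nan,
                "se_rE": res.se_rE if res.se_rE is not None else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["environment", "n", "r_G", "se_rG", "r_E", "se_rE"]
    )


def write_results(
    anova_tables: Mapping[str, object],
    correlation_results: Sequence,
    outdir,
    *,
    force: bool = False,
) -> dict:
    """Write ANOVA and correlation tables as CSV plus a JSON report.

    One ``anova_<response>.csv`` per response, one ``correlations.csv``
    (environment, n, r_G, se_rG, r_E, se_rE) and one ``report.json`` holding
    the same content machine-readably, jackknife replicates included.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    report = {"anova": {}, "correlations": []}
    for label, table in anova_tables.items():
        path = outdir / f"anova_{label}.csv"
        if path.exists() and not force:
            raise OverwriteError(f"{path} exists; pass force=True to overwrite")
        frame = anova_table_frame(table)
        frame.to_csv(path, index=False)
        written[f"anova_{label}"] = path
        report["anova"][label] = {
            "response": table.response_label,
            "r_squared": table.r_squared,
            "rows": frame.to_dict(orient="records"),
        }

    corr_path = outdir / "correlations.csv"
    if corr_path.exists() and not force:
        raise OverwriteError(f"{corr_path} exists; pass force=True to overwrite")
    correlation_table_frame(correlation_results).to_csv(corr_path, index=False)
    written["correlations"] = corr_path
    for res in correlation_results:
        report["correlations"].append(res.to_dict())

    json_path = outdir / "report.json"
    if json_path.exists() and not force:
        raise OverwriteError(f"{json_path} exists; pass force=True to overwrite")
    json_path.write_text(json.dumps(report, indent=2, default=_json_default))
    written["report"] = json_path
    return written


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
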