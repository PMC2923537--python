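"""Readers, writers and validated containers for every file the pipeline touches.

All tables are plain tab-separated text with header rows.  Identifiers are
opaque strings; missing values are not permitted in the expression matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("hybridcor")

GROUPS = ("flint", "dent")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class ExpressionMatrix:
    """Probe x sample log2 intensities with sample and probe annotations.

    ``values`` is a probe-by-sample DataFrame of finite log2 intensities.
    ``samples`` is indexed by sample_id with columns line_id, group
    ('flint'/'dent') and replicate.  ``probes`` is indexed by probe_id with an
    integer is_spikein flag.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DataError(f"duplicate probe id {dup!r} in expression matrix")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DataError(f"duplicate sample id {dup!r} in expression matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise DataError("non-finite intensity in expression matrix")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise DataError(f"samples missing from sample sheet: {sorted(missing)[:5]}")
        bad_group = set(self.samples["group"].unique()) - set(GROUPS)
        if bad_group:
            raise DataError(f"unknown group label(s) {sorted(bad_group)}; expected {GROUPS}")
        missing_probes = set(self.values.index) - set(self.probes.index)
        if missing_probes:
            raise DataError(f"probes missing from probe sheet: {sorted(missing_probes)[:5]}")

    # ---- convenience views -------------------------------------------------

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def is_spikein(self) -> pd.Series:
        return self.probes.loc[self.probe_ids, "is_spikein"].astype(bool)

    def spikein_values(self) -> np.ndarray:
        """All intensities of spike-in probes, flattened."""
        return self.values.loc[self.is_spikein()].to_numpy().ravel()

    def gene_values(self) -> pd.DataFrame:
        """The matrix restricted to non-spike-in (gene-oriented) probes."""
        return self.values.loc[~self.is_spikein()]

    def sample_lines(self) -> pd.Series:
        """line_id per sample column, in column order."""
        return self.samples.loc[self.sample_ids, "line_id"]

    def line_groups(self) -> pd.Series:
        """group per line_id (one row per line)."""
        sheet = self.samples.drop_duplicates("line_id").set_index("line_id")
        return sheet["group"]

    def line_means(self) -> pd.DataFrame:
        """Probe x line matrix of replicate-mean log2 intensities."""
        lines = self.sample_lines().to_numpy()
        return self.values.T.groupby(lines).mean().T


@dataclass
class FactorialDesign:
    """Hybrid -> (flint parent, dent parent) mapping of the factorial."""

    table: pd.DataFrame  # columns: hybrid_id, flint_parent, dent_parent

    def __post_init__(self) -> None:
        req = {"hybrid_id", "flint_parent", "dent_parent"}
        if not req <= set(self.table.columns):
            raise DataError(f"design table needs columns {sorted(req)}")
        if self.table["hybrid_id"].duplicated().any():
            dup = self.table.loc[self.table["hybrid_id"].duplicated(), "hybrid_id"].iloc[0]
            raise DataError(f"duplicate hybrid id {dup!r} in design")

    @property
    def hybrid_ids(self) -> pd.Index:
        return pd.Index(self.table["hybrid_id"])

    def __len__(self) -> int:
        return len(self.table)

    def parent_pairs(self) -> list[tuple[str, str, str]]:
        return list(
            self.table[["hybrid_id", "flint_parent", "dent_parent"]].itertuples(index=False)
        )


@dataclass
class TraitTable:
    """Per-hybrid phenotypes: PY (Mg/ha), PD (%), optionally HY, HD.

    ``line_perse`` optionally carries per-line per-se trait values
    (line_id, yield_perse, gdmc_perse) for heterosis computation.
    """

    table: pd.DataFrame  # indexed by hybrid_id; columns PY, PD [, HY, HD]
    line_perse: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for col in ("PY", "PD"):
            if col not in self.table.columns:
                raise DataError(f"trait table missing column {col}")
        if self.table.index.duplicated().any():
            raise DataError("duplicate hybrid id in trait table")
        if (self.table["PY"] <= 0).any():
            raise DataError("PY must be positive (Mg/ha)")
        pd_vals = self.table["PD"]
        if ((pd_vals <= 0) | (pd_vals >= 100)).any():
            raise DataError("PD must lie in (0, 100) percent")


CategoryMap = dict  # category name -> set of probe ids


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", **kw)
    df[df.columns[0]] = df[df.columns[0]].astype(str)
    return df


def read_expression(matrix_path, sample_sheet_path, probe_sheet_path) -> ExpressionMatrix:
    """Load a probe x sample matrix plus its sample and probe sheets."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            bad = values[col][~values[col].apply(lambda v: isinstance(v, (int, float)))]
            row = bad.index[0] if len(bad) else "?"
            raise DataError(
                f"{matrix_path}: non-numeric intensity in column {col!r}, row {row!r}"
            )
    samples = _read_tsv(sample_sheet_path).set_index("sample_id")
    probes = _read_tsv(probe_sheet_path).set_index("probe_id")
    probes.index = probes.index.astype(str)
    em = ExpressionMatrix(values=values, samples=samples, probes=probes)
    logger.info("read expression matrix: %d probes x %d samples", *values.shape)
    return em


def write_expression(em: ExpressionMatrix, matrix_path, sample_sheet_path, probe_sheet_path) -> None:
    em.values.rename_axis("probe_id").to_csv(matrix_path, sep="\t", float_format="%.10g")
    em.samples.rename_axis("sample_id").to_csv(sample_sheet_path, sep="\t")
    em.probes.rename_axis("probe_id").to_csv(probe_sheet_path, sep="\t")


def read_design(path) -> FactorialDesign:
    return FactorialDesign(_read_tsv(path, dtype=str))


def write_design(design: FactorialDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_traits(path, line_perse_path=None) -> TraitTable:
    table = _read_tsv(path).set_index("hybrid_id")
    perse = None
    if line_perse_path is not None:
        perse = _read_tsv(line_perse_path).set_index("line_id")
    return TraitTable(table=table, line_perse=perse)


def write_traits(traits: TraitTable, path, line_perse_path=None) -> None:
    traits.table.rename_axis("hybrid_id").to_csv(path, sep="\t", float_format="%.10g")
    if line_perse_path is not None and traits.line_perse is not None:
        traits.line_perse.rename_axis("line_id").to_csv(
            line_perse_path, sep="\t", float_format="%.10g"
        )


def read_gmt(path) -> CategoryMap:
    """Read a GMT file: category, description, then member ids, tab-separated."""
    cats: CategoryMap = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name = fields[0]
            cats[name] = set(fields[2:])
    logger.info("read GMT %s: %d categories", path, len(cats))
    return cats


def write_gmt(cats: CategoryMap, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in cats.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
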