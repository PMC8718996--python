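"""Behavioral cohort tables and multi-site batch correction.

Each row of a cohort table is one subject (e.g. an outbred rat) measured on
``p`` continuous behavioral assays — total drug consumption, escalation of
intake, progressive-ratio break point, extinction responding, reinstatement
lever presses, and so on — at one of several study sites.  Sites introduce
location-shift batch effects: the same assay run in two laboratories yields
systematically offset values.  Because downstream analysis clusters subjects
by Euclidean distance, an uncorrected site offset masquerades as biological
structure.  The correction used here is within-site z-scoring: every measure
is centered and scaled to unit sample standard deviation *separately per
site*, which removes location-scale site effects exactly while preserving
within-site ordering.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BehavioralTable",
    "SchemaError",
    "CohortValidationError",
    "ZeroVarianceError",
    "load_behavioral_table",
    "zscore_by_site",
]

#: tolerance used when checking the mean-0 / sd-1 invariant of standardized tables
STANDARDIZATION_TOL = 1e-9


class SchemaError(ValueError):
    """A declared column is missing or the column mapping is inconsistent."""


class CohortValidationError(ValueError):
    """The table content violates a cohort invariant (duplicates, bad cells)."""


class ZeroVarianceError(CohortValidationError):
    """A measure is constant within a site, so it cannot be z-scored."""


@dataclass
class BehavioralTable:
    """Subjects x measures table with site/sex metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain the columns ``subject_id`` and ``site``, optionally
        ``sex``, plus one numeric column per behavioral measure.
    measures : list of str
        Names of the measure columns, in the order used for distances.
    standardized : bool
        True once the measures have been z-scored within site.
    """

    data: pd.DataFrame
    measures: list[str] = field(default_factory=list)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def p(self) -> int:
        return len(self.measures)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.data["subject_id"].to_numpy()

    @property
    def sites(self) -> np.ndarray:
        return self.data["site"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        """n x p float matrix of the measures, row order preserved."""
        return self.data[self.measures].to_numpy(dtype=float)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for col in ("subject_id", "site"):
            if col not in self.data.columns:
                raise SchemaError(f"required column {col!r} is missing")
        missing = [m for m in self.measures if m not in self.data.columns]
        if missing:
            raise SchemaError(f"declared measure columns missing: {missing}")
        ids = self.data["subject_id"]
        dup = ids[ids.duplicated()].unique()
        if len(dup):
            raise CohortValidationError(
                f"duplicate subject_id values: {sorted(map(str, dup))}"
            )
        if self.data["site"].isna().any():
            rows = self.data.index[self.data["site"].isna()].tolist()
            raise CohortValidationError(f"missing site label in rows {rows}")
        vals = self.data[self.measures]
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise CohortValidationError(
                f"non-finite value in measure {self.measures[c]!r}, "
                f"row {r} (subject {ids.iloc[r]!r})"
            )
        if self.standardized:
            for (site, m), grp in _site_measure_groups(self):
                mu, sd = grp.mean(), grp.std(ddof=1)
                if abs(mu) > STANDARDIZATION_TOL or abs(sd - 1) > STANDARDIZATION_TOL:
                    raise CohortValidationError(
                        f"table flagged standardized but measure {m!r} at site "
                        f"{site!r} has mean {mu:.3g}, sd {sd:.3g}"
                    )

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the table as CSV with a provenance comment line."""
        with open(path, "w", encoding="utf-8") as fh:
            state = "standardized(within-site z-score)" if self.standardized else "raw"
            fh.write(
                f"# sbmpheno behavioral table: n={self.n} p={self.p} {state}\n"
            )
            self.data.to_csv(fh, index=False)


def _site_measure_groups(table: BehavioralTable):
    for site, sub in table.data.groupby("site", sort=False, observed=True):
        for m in table.measures:
            yield (site, m), sub[m].astype(float)


DEFAULT_SCHEMA = {"subject_id": "subject_id", "site": "site", "sex": "sex"}


def load_behavioral_table(path, schema: dict | None = None, sep: str | None = None) -> BehavioralTable:
    """Read a cohort CSV/TSV and return a validated raw :class:`BehavioralTable`.

    Parameters
    ----------
    path : path-like or file-like
        Delimited text file with a header row; lines starting with ``#`` are
        treated as comments.
    schema : dict, optional
        Column mapping with keys ``subject_id``, ``site``, optional ``sex``,
        and ``measures`` (list of measure column names).  When ``measures``
        is omitted, every column not named as metadata is taken as a measure.
    sep : str, optional
        Field separator; inferred from the filename (``.tsv`` -> tab) when
        omitted.

    Raises
    ------
    SchemaError
        If a declared column is absent.
    CohortValidationError
        On non-numeric measure cells (reported with row and column),
        duplicate subject IDs, or missing site labels.
    """
    schema = dict(schema or {})
    id_col = schema.get("subject_id", "subject_id")
    site_col = schema.get("site", "site")
    sex_col = schema.get("sex", "sex")
    if sep is None:
        name = getattr(path, "name", str(path))
        sep = "\t" if str(name).endswith((".tsv", ".tab")) else ","
    standardized = False
    if not hasattr(path, "read"):
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        # provenance comment written by BehavioralTable.to_csv
        if first.startswith("#") and "standardized" in first:
            standardized = True
    raw = pd.read_csv(path, sep=sep, comment="#", dtype=str,
                      skipinitialspace=True, encoding="utf-8")
    raw.columns = [c.strip() for c in raw.columns]

    for col in (id_col, site_col):
        if col not in raw.columns:
            raise SchemaError(f"required column {col!r} not found in header")

    measures = schema.get("measures")
    if measures is None:
        meta = {id_col, site_col, sex_col}
        measures = [c for c in raw.columns if c not in meta]
    else:
        missing = [m for m in measures if m not in raw.columns]
        if missing:
            raise SchemaError(f"declared measure columns missing: {missing}")
    if not measures:
        raise SchemaError("no measure columns found")

    data = pd.DataFrame({"subject_id": raw[id_col].astype(str),
                         "site": raw[site_col].astype(str)})
    if sex_col in raw.columns:
        data["sex"] = raw[sex_col].astype(str)
    for m in measures:
        parsed = pd.to_numeric(raw[m], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            r = int(bad.idxmax())
            raise CohortValidationError(
                f"non-numeric value {raw[m].iloc[r]!r} in column {m!r}, "
                f"row {r} (subject {data['subject_id'].iloc[r]!r})"
            )
        data[m] = parsed.astype(float)
    return BehavioralTable(data=data, measures=list(measures),
                           standardized=standardized)


def zscore_by_site(table: BehavioralTable) -> BehavioralTable:
    """Standardize every measure to mean 0, sample sd 1 within each site.

    Uses the n-1 (sample) standard deviation.  Location-shift batch effects
    between sites are removed exactly: adding any constant to a measure
    within one site leaves the output unchanged.

    Raises
    ------
    ZeroVarianceError
        If a measure is constant within some site (the error names both).
    CohortValidationError
        If any site has fewer than two subjects.
    """
    if table.standardized:
        warnings.warn("table is already flagged standardized; re-standardizing",
                      stacklevel=2)
    counts = table.data.groupby("site", observed=True).size()
    small = counts[counts < 2]
    if len(small):
        raise CohortValidationError(
            f"sites with fewer than 2 subjects cannot be standardized: "
            f"{sorted(map(str, small.index))}"
        )
    for (site, m), grp in _site_measure_groups(table):
        if grp.std(ddof=1) == 0:
            raise ZeroVarianceError(
                f"measure {m!r} is constant within site {site!r}"
            )
    out = table.data.copy()
    for m in table.measures:
        g = out.groupby("site", observed=True)[m]
        out[m] = (out[m] - g.transform("mean")) / g.transform("std", ddof=1)
    return BehavioralTable(data=out, measures=list(table.measures),
                           standardized=True)
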