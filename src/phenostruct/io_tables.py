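"""Reading, validating and writing craniometric measurement tables.

The universal data structure of the package is :class:`CraniometricTable`:
individuals x variables of linear cranial measurements (mm) with series,
region and sex labels and an explicit missingness mask.  Variables are the
23 standard Howells linear measurements (codes ``GOL`` ... ``OCC``).

The canonical on-disk dialect is UTF-8 CSV with header
``individual_id,series,region,sex,GOL,...``; an empty cell means missing.
XLSX workbooks (e.g. supplementary spreadsheets of craniometric studies)
are read through the same validation path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 23 Howells linear craniometric variables used throughout.
HOWELLS_VARIABLES: tuple[str, ...] = (
    "GOL", "NOL", "BBH", "XCB", "XFB", "AUB", "ASB", "NPH", "NLH", "OBH",
    "OBB", "JUB", "NLB", "ZMB", "FMB", "NAS", "EKB", "IML", "XML", "WMH",
    "FRC", "PAC", "OCC",
)

_ID_ALIASES = {"individual_id", "id", "individual", "specimen", "specimen_id"}
_SERIES_ALIASES = {"series", "population", "group", "sample"}
_REGION_ALIASES = {"region", "regional_affiliation", "affiliation"}
_SEX_ALIASES = {"sex", "gender"}

SEX_CODES = ("M", "F", "U")


class FormatError(ValueError):
    """The file does not conform to the craniometric table dialect."""


class ValidationError(ValueError):
    """The file parsed but its contents violate a table invariant."""


@dataclass
class CraniometricTable:
    """Individuals x variables measurement matrix with series/sex labels.

    Parameters
    ----------
    individual_id : array of str
        Opaque per-row identifiers.
    series : array of str
        Series (population sample) label per individual.
    region : array of str
        Regional / chronological affiliation per individual.
    sex : array of str
        One of ``M``, ``F``, ``U`` per individual.
    values : (n, t) float array
        Measurements in mm; entries under the mask are undefined.
    mask : (n, t) bool array
        True where the measurement is missing.
    variables : ordered list of variable codes (subset of the 23 Howells codes).
    """

    individual_id: np.ndarray
    series: np.ndarray
    region: np.ndarray
    sex: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.series = np.asarray(self.series, dtype=object)
        self.region = np.asarray(self.region, dtype=object)
        self.sex = np.asarray(self.sex, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.variables = list(self.variables)
        self.validate()

    # -- basic queries -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_id)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def series_labels(self) -> list[str]:
        """Unique series labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.series:
            seen.setdefault(s)
        return list(seen)

    def subset(self, rows: np.ndarray) -> "CraniometricTable":
        """Row subset (boolean or index array), preserving variable order."""
        return CraniometricTable(
            individual_id=self.individual_id[rows],
            series=self.series[rows],
            region=self.region[rows],
            sex=self.sex[rows],
            values=self.values[rows],
            mask=self.mask[rows],
            variables=self.variables,
        )

    def select_series(self, labels) -> "CraniometricTable":
        labels = {labels} if isinstance(labels, str) else set(labels)
        keep = np.array([s in labels for s in self.series])
        if not keep.any():
            raise ValidationError(f"no individuals in series {sorted(labels)}")
        return self.subset(keep)

    def series_values(self, label: str) -> np.ndarray:
        """Measurement matrix of one series (rows of that series only)."""
        return self.values[self.series == label]

    def copy(self) -> "CraniometricTable":
        return CraniometricTable(
            individual_id=self.individual_id.copy(),
            series=self.series.copy(),
            region=self.region.copy(),
            sex=self.sex.copy(),
            values=self.values.copy(),
            mask=self.mask.copy(),
            variables=list(self.variables),
        )

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if len(self.variables) != len(set(self.variables)):
            dup = sorted({v for v in self.variables if self.variables.count(v) > 1})
            raise FormatError(f"duplicate variable codes: {dup}")
        unknown = [v for v in self.variables if v not in HOWELLS_VARIABLES]
        if unknown:
            raise FormatError(f"unrecognized variable codes: {unknown}")
        n, t = self.values.shape
        if self.mask.shape != (n, t):
            raise ValidationError("mask shape differs from values shape")
        if t != len(self.variables):
            raise ValidationError("variable list length differs from value columns")
        for arr, name in ((self.individual_id, "individual_id"),
                          (self.series, "series"), (self.region, "region"),
                          (self.sex, "sex")):
            if len(arr) != n:
                raise ValidationError(f"{name} length differs from row count")
        bad_sex = sorted({s for s in self.sex if s not in SEX_CODES})
        if bad_sex:
            raise ValidationError(f"sex codes outside {{M,F,U}}: {bad_sex}")
        observed = self.values[~self.mask]
        if observed.size and not (np.isfinite(observed).all() and (observed > 0).all()):
            raise ValidationError("non-missing measurements must be finite and > 0")
        all_missing = self.mask.all(axis=1)
        if all_missing.any():
            who = self.individual_id[all_missing][0]
            raise ValidationError(f"individual {who!r} has all variables missing")


@dataclass
class SeriesSummary:
    """Per-series census: counts by sex and percent missing cells.

    ``missing_pct`` is computed over the full n_i x t cell grid (t = number
    of variables in the table), before any imputation.
    """

    series: str
    region: str
    n: int
    males: int
    females: int
    unknown: int
    missing_cells: int
    missing_pct: float


def normalize_sex(code: object) -> str:
    """Map arbitrary sex annotations onto {M, F, U}."""
    s = str(code).strip().upper()
    if s in {"M", "MALE", "H"}:
        return "M"
    if s in {"F", "FEMALE"}:
        return "F"
    if s not in {"U", "", "NA", "NAN", "NONE", "?", "UNKNOWN", "INDET"}:
        logger.warning("unparseable sex code %r mapped to U", code)
    return "U"


def _find_column(columns: list[str], aliases: set[str], what: str) -> str:
    matches = [c for c in columns if c.strip().lower() in aliases]
    if not matches:
        raise FormatError(f"no {what} column found (looked for {sorted(aliases)})")
    return matches[0]


def table_from_frame(df: pd.DataFrame) -> CraniometricTable:
    """Build a validated table from a raw DataFrame (CSV or XLSX contents)."""
    columns = [str(c) for c in df.columns]
    df.columns = columns
    id_col = _find_column(columns, _ID_ALIASES, "individual-id")
    series_col = _find_column(columns, _SERIES_ALIASES, "series")
    sex_col = _find_column(columns, _SEX_ALIASES, "sex")
    try:
        region_col = _find_column(columns, _REGION_ALIASES, "region")
        region = df[region_col].fillna("").astype(str).to_numpy(dtype=object)
    except FormatError:
        region = np.array([""] * len(df), dtype=object)

    # pandas mangles duplicated headers to "GOL.1" etc.; treat as format error
    import re
    for c in columns:
        m = re.fullmatch(r"(.+)\.\d+", c.strip())
        if m and m.group(1).strip().upper() in HOWELLS_VARIABLES:
            raise FormatError(f"duplicated variable column {m.group(1).upper()!r}")
    upper = [c.strip().upper() for c in columns]
    var_cols = [columns[i] for i, u in enumerate(upper) if u in HOWELLS_VARIABLES]
    var_codes = [c.strip().upper() for c in var_cols]
    if len(var_codes) != len(set(var_codes)):
        dup = sorted({v for v in var_codes if var_codes.count(v) > 1})
        raise FormatError(f"duplicated variable columns: {dup}")
    if len(var_codes) < 2:
        raise FormatError("fewer than 2 recognized variable columns")
    meta = {id_col, series_col, sex_col} | set(var_cols)
    dropped = [c for c in columns if c not in meta
               and c.strip().lower() not in _REGION_ALIASES]
    if dropped:
        logger.warning("dropping unrecognized columns: %s", dropped)

    raw = df[var_cols].apply(pd.to_numeric, errors="coerce")
    values = raw.to_numpy(dtype=float)
    mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    return CraniometricTable(
        individual_id=df[id_col].astype(str).to_numpy(dtype=object),
        series=df[series_col].astype(str).to_numpy(dtype=object),
        region=region,
        sex=np.array([normalize_sex(s) for s in df[sex_col]], dtype=object),
        values=values,
        mask=mask,
        variables=var_codes,
    )


def read_table(path, dialect: str | None = None, sheet=0) -> CraniometricTable:
    """Read a craniometric table from CSV (canonical) or XLSX.

    ``dialect`` is inferred from the file extension when omitted.
    """
    path = str(path)
    if dialect is None:
        dialect = "xlsx" if path.lower().endswith((".xlsx", ".xls")) else "csv"
    if dialect == "csv":
        df = pd.read_csv(path, dtype=str)
        # re-parse variable columns as numbers inside table_from_frame
    elif dialect == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return table_from_frame(df)


def write_table(table: CraniometricTable, path) -> None:
    """Write the canonical CSV dialect (empty string = missing cell)."""
    cells = np.empty(table.values.shape, dtype=object)
    for i in range(table.values.shape[0]):
        for j in range(table.values.shape[1]):
            cells[i, j] = "" if table.mask[i, j] else repr(float(table.values[i, j]))
    df = pd.DataFrame(cells, columns=table.variables)
    df.insert(0, "sex", table.sex)
    df.insert(0, "region", table.region)
    df.insert(0, "series", table.series)
    df.insert(0, "individual_id", table.individual_id)
    df.to_csv(path, index=False)


def summarize_series(table: CraniometricTable) -> list[SeriesSummary]:
    """One :class:`SeriesSummary` per series, in order of first appearance.

    The missing percentage uses the full cell grid: 100 * missing / (n_i * t).
    """
    out = []
    for label in table.series_labels():
        rows = table.series == label
        n = int(rows.sum())
        sex = table.sex[rows]
        miss = int(table.mask[rows].sum())
        region = table.region[rows][0]
        out.append(SeriesSummary(
            series=label,
            region=region,
            n=n,
            males=int((sex == "M").sum()),
            females=int((sex == "F").sum()),
            unknown=int((sex == "U").sum()),
            missing_cells=miss,
            missing_pct=100.0 * miss / (n * table.n_variables),
        ))
    return out


def summaries_to_frame(summaries: list[SeriesSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def write_matrix_csv(matrix: np.ndarray, labels: list[str], path) -> None:
    """Square labeled matrix (e.g. pairwise Fst) as CSV."""
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path)


def read_matrix_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
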