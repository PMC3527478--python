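"""Reading, validating and aligning fingerprint matrices, sample metadata and
soil chemistry tables.

A community fingerprint (e.g. a DGGE gel lane) is stored as a samples x bands
table of non-negative intensities.  On load, rows are by default rescaled to
relative abundances (sum 1).  Metadata carries the site, sampling date,
replicate index and soil texture class per sample; chemistry may be keyed
either per sample or per (site, date), in which case it broadcasts to all
replicates of that date.

All readers accept UTF-8 comma- or tab-delimited text with a mandatory header
row and '.' decimal separator; lines starting with '#' are treated as
provenance comments and skipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, FormatError, ValidationError

TEXTURE_CLASSES = ("sandy", "clayey")

_METADATA_COLUMNS = ("sample_id", "site", "date", "replicate", "texture")
_CHEMISTRY_VARIABLES = ("pH", "nh4", "no3", "om", "clay", "moisture")

_MONTH_ONLY = re.compile(r"^\d{4}-\d{1,2}$")


@dataclass
class FingerprintMatrix:
    """Samples x bands relative-abundance table.

    ``data`` is indexed by sample id with band ids as columns.  ``normalized``
    records whether rows were rescaled to sum 1 on load; downstream statistics
    renormalize internally, so the flag is provenance, not a contract.
    """

    data: pd.DataFrame
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate band ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("fingerprint matrix contains missing values")
        if (values < 0).any():
            raise ValidationError("band intensities must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def band_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def normalize(self) -> "FingerprintMatrix":
        """Return a copy with each row rescaled to relative abundances."""
        sums = self.data.sum(axis=1)
        zero = sums[sums == 0]
        if len(zero):
            raise ValidationError(
                f"cannot normalize all-zero sample rows: {list(zero.index)}"
            )
        return FingerprintMatrix(self.data.div(sums, axis=0), normalized=True)


@dataclass
class AlignedDataset:
    """Inner join of fingerprint, metadata and (optionally) chemistry tables."""

    fingerprint: FingerprintMatrix
    metadata: pd.DataFrame
    chemistry: pd.DataFrame | None
    dropped: dict[str, list[str]] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.fingerprint.sample_ids


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=None, engine="python", comment="#")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse delimited table {path}: {exc}") from exc


def read_fingerprint(path, normalize: bool = True) -> FingerprintMatrix:
    """Read a band table: first column sample id, remaining columns numeric.

    With ``normalize`` (the default) each row is rescaled to sum 1; all-zero
    rows are rejected because they have no relative abundances.
    """
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise FormatError("fingerprint table needs a sample id column and at least one band")
    raw = raw.set_index(raw.columns[0])
    raw.index = raw.index.astype(str)
    try:
        data = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric band intensity in {path}: {exc}") from exc
    fp = FingerprintMatrix(data, normalized=False)
    return fp.normalize() if normalize else fp


def write_fingerprint(fp: FingerprintMatrix, path, provenance: dict | None = None) -> None:
    """Write the matrix as labelled CSV, with optional '#' provenance header."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        out = fp.data.copy()
        out.index.name = "sample_id"
        out.to_csv(fh, lineterminator="\n")


def _parse_dates(column: pd.Series) -> pd.Series:
    """Parse ISO dates; a month-only value like '2009-04' maps to the 15th."""
    as_str = column.astype(str).str.strip()
    padded = as_str.where(~as_str.str.match(_MONTH_ONLY), as_str + "-15")
    try:
        return pd.to_datetime(padded, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable sampling date: {exc}") from exc


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (sample_id, site, date, replicate, texture).

    Returns a frame indexed by sample id, sorted by (site, date, replicate),
    with ``date`` as day-precision timestamps.
    """
    raw = _read_table(path)
    missing = [c for c in _METADATA_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    md = raw.loc[:, list(_METADATA_COLUMNS)].copy()
    md["sample_id"] = md["sample_id"].astype(str)
    if md["sample_id"].duplicated().any():
        dupes = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in metadata: {dupes}")
    md["date"] = _parse_dates(md["date"])
    md["replicate"] = md["replicate"].astype(int)
    md["texture"] = md["texture"].astype(str).str.strip().str.lower()
    bad = sorted(set(md["texture"]) - set(TEXTURE_CLASSES))
    if bad:
        raise ValidationError(
            f"unknown texture class(es) {bad}; expected one of {TEXTURE_CLASSES}"
        )
    md = md.set_index("sample_id").sort_values(["site", "date", "replicate"])
    return md


def read_chemistry(path) -> pd.DataFrame:
    """Read a chemistry table keyed by sample_id or by (site, date).

    Recognized variables: pH, nh4 (mg/kg), no3 (mg/kg), om (%), clay (%),
    moisture (%).  Missing cells are allowed and propagate downstream as NaN
    (pairwise-complete handling).
    """
    raw = _read_table(path)
    if "sample_id" in raw.columns:
        chem = raw.set_index(raw["sample_id"].astype(str)).drop(columns=["sample_id"])
    elif {"site", "date"}.issubset(raw.columns):
        chem = raw.copy()
        chem["date"] = _parse_dates(chem["date"])
    else:
        raise FormatError("chemistry table must have a sample_id column or site+date columns")
    present = [v for v in _CHEMISTRY_VARIABLES if v in chem.columns]
    if not present:
        raise FormatError(
            f"chemistry table has none of the recognized variables {_CHEMISTRY_VARIABLES}"
        )
    values = chem[present].apply(pd.to_numeric, errors="coerce")
    _validate_chemistry(values)
    chem[present] = values
    return chem


def _validate_chemistry(values: pd.DataFrame) -> None:
    checks = {
        "pH": (0.0, 14.0),
        "om": (0.0, 100.0),
        "clay": (0.0, 100.0),
        "moisture": (0.0, 100.0),
        "nh4": (0.0, np.inf),
        "no3": (0.0, np.inf),
    }
    for var, (lo, hi) in checks.items():
        if var in values.columns:
            col = values[var].dropna()
            if ((col < lo) | (col > hi)).any():
                raise ValidationError(f"{var} values outside [{lo}, {hi}]")


def align(
    fp: FingerprintMatrix,
    md: pd.DataFrame,
    chem: pd.DataFrame | None = None,
) -> AlignedDataset:
    """Inner-join the three tables on the sample key.

    Chemistry keyed per (site, date) broadcasts to every replicate of that
    date.  Samples present in one table but not another are dropped and
    reported in ``dropped``; an empty intersection raises.
    """
    fp_ids = set(fp.sample_ids)
    md_ids = set(md.index)
    common = fp_ids & md_ids
    if not common:
        raise AlignmentError("fingerprint and metadata share no sample ids")
    order = [s for s in fp.sample_ids if s in common]
    dropped = {
        "fingerprint_only": sorted(fp_ids - md_ids),
        "metadata_only": sorted(md_ids - fp_ids),
    }
    fp_aligned = FingerprintMatrix(fp.data.loc[order], normalized=fp.normalized)
    md_aligned = md.loc[order]

    chem_aligned = None
    if chem is not None:
        if "site" in chem.columns and "date" in chem.columns:
            vars_ = [c for c in chem.columns if c not in ("site", "date")]
            keyed = chem.set_index(["site", "date"])[vars_]
            if keyed.index.has_duplicates:
                keyed = keyed.groupby(level=["site", "date"]).mean()
            lookup = pd.MultiIndex.from_frame(md_aligned[["site", "date"]])
            chem_aligned = keyed.reindex(lookup)
            chem_aligned.index = md_aligned.index
        else:
            chem_ids = set(chem.index)
            if not (set(order) & chem_ids):
                raise AlignmentError("chemistry shares no sample ids with the joined data")
            dropped["chemistry_only"] = sorted(chem_ids - set(order))
            chem_aligned = chem.reindex(order)
        if chem_aligned.isna().all(axis=1).all():
            raise AlignmentError("no chemistry values align with the joined samples")
    return AlignedDataset(fp_aligned, md_aligned, chem_aligned, dropped)
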