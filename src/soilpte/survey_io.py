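"""Survey data model, CSV I/O, validation and descriptive statistics.

A survey is a samples x elements table of total concentrations (mg/kg) with
projected planar coordinates and soil pH. The eight potentially toxic
elements (PTEs) assessed by default are As, Cd, Cr, Cu, Hg, Ni, Pb and Zn.
Reference tables (regional background values, screening values, Hakanson
toxicity coefficients, reference doses, slope factors and method detection
limits) ship with the package and can be overridden from user CSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical element order used throughout the package
ELEMENTS: tuple[str, ...] = ("As", "Cd", "Cr", "Cu", "Hg", "Ni", "Pb", "Zn")

#: non-element columns expected in a survey CSV
META_COLUMNS: tuple[str, ...] = ("sample_id", "x", "y", "pH")


class SurveyError(ValueError):
    """Raised for schema, parse or validation failures on survey tables."""


@dataclass(frozen=True)
class SurveyTable:
    """Validated samples x elements concentration table.

    Attributes
    ----------
    data : pandas.DataFrame
        One row per sample with columns ``sample_id, x, y, pH`` followed by
        one concentration column (mg/kg) per element. Row order preserved.
    elements : tuple of str
        Element columns, in canonical order.
    """

    data: pd.DataFrame
    elements: tuple[str, ...] = ELEMENTS

    def __post_init__(self) -> None:
        missing = [c for c in (*META_COLUMNS, *self.elements) if c not in self.data.columns]
        if missing:
            raise SurveyError(f"survey table missing column(s): {missing}")
        ids = self.data["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SurveyError(f"duplicate sample_id: {dup!r}")
        conc = self.data[list(self.elements)].to_numpy(dtype=float)
        if not np.isfinite(conc).all():
            raise SurveyError("non-finite concentration in survey table")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def conc(self) -> pd.DataFrame:
        """Concentration block (samples x elements), mg/kg."""
        return self.data[list(self.elements)]

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of projected x/y coordinates in metres."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:  # value equality for round-trips
        if not isinstance(other, SurveyTable):
            return NotImplemented
        return self.elements == other.elements and self.data.reset_index(drop=True).equals(
            other.data.reset_index(drop=True)
        )


@dataclass(frozen=True)
class ReferenceData:
    """Per-element reference values used by the assessment chain.

    ``background`` and ``screening`` are mg/kg; ``toxicity`` the unitless
    Hakanson coefficients; ``rfd``/``sf`` map element -> route -> value with
    routes ``ingestion``, ``dermal``, ``inhalation`` (plus
    ``inhalation_lifetime`` for RfD); ``mdl`` the method detection limits in
    reporting units (mg/kg).
    """

    background: Mapping[str, float]
    screening: Mapping[str, float]
    toxicity: Mapping[str, float]
    rfd: Mapping[str, Mapping[str, float]]
    sf: Mapping[str, Mapping[str, float]]
    mdl: Mapping[str, float]

    def require(self, table: str, element: str) -> float:
        values = getattr(self, table)
        if element not in values:
            raise KeyError(f"no {table} value for element {element!r}")
        return values[element]


def load_reference(elements_csv: str | Path | None = None,
                   rfd_sf_csv: str | Path | None = None) -> ReferenceData:
    """Load the packaged reference tables, optionally overridden by CSVs.

    Override files must use the same schema as the packaged
    ``reference_elements.csv`` / ``rfd_sf.csv`` (documented in their headers).
    """
    elems = _read_packaged("reference_elements.csv", elements_csv).set_index("element")
    tox = _read_packaged("rfd_sf.csv", rfd_sf_csv).set_index("element")
    rfd: dict[str, dict[str, float]] = {}
    sf: dict[str, dict[str, float]] = {}
    for el, row in tox.iterrows():
        rfd[el] = {route: float(row[f"rfd_{route}"])
                   for route in ("ingestion", "dermal", "inhalation", "inhalation_lifetime")
                   if f"rfd_{route}" in row and pd.notna(row[f"rfd_{route}"])}
        sf[el] = {route: float(row[f"sf_{route}"])
                  for route in ("ingestion", "dermal", "inhalation")
                  if f"sf_{route}" in row and pd.notna(row[f"sf_{route}"])}
    sf = {el: routes for el, routes in sf.items() if routes}
    return ReferenceData(
        background=elems["background_mgkg"].astype(float).to_dict(),
        screening=elems["screening_mgkg"].astype(float).to_dict(),
        toxicity=elems["toxicity_coeff"].astype(float).to_dict(),
        rfd=rfd,
        sf=sf,
        mdl=elems["mdl_mgkg"].astype(float).to_dict(),
    )


def _read_packaged(name: str, override: str | Path | None) -> pd.DataFrame:
    if override is not None:
        return pd.read_csv(override, comment="#")
    with resources.as_file(resources.files("soilpte") / "data" / name) as p:
        return pd.read_csv(p, comment="#")


def load_study_summary() -> pd.DataFrame:
    """Packaged descriptive statistics of the 304-sample survey.

    Index = variable (8 elements + pH); columns min/mean/max/median/sd/cv.
    """
    return _read_packaged("study_summary.csv", None).set_index("variable")


def read_survey(path: str | Path, elements: Sequence[str] = ELEMENTS) -> SurveyTable:
    """Read a survey CSV (comma-separated, UTF-8, header row).

    Required columns: ``sample_id,x,y,pH`` plus one column per element.
    Extra columns are ignored with a warning. Raises :class:`SurveyError`
    naming the missing column, the unparsable row, or the duplicated id.
    """
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    for col in (*META_COLUMNS, *elements):
        if col not in df.columns:
            raise SurveyError(f"missing required column {col!r} in {path}")
    extra = [c for c in df.columns if c not in (*META_COLUMNS, *elements)]
    if extra:
        logger.warning("ignoring extra column(s) %s in %s", extra, path)
    numeric = ["x", "y", "pH", *elements]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            raise SurveyError(
                f"non-numeric value in column {col!r} at row {int(bad.idxmax())}"
            )
        df[col] = parsed.astype(float)
    return SurveyTable(df[[*META_COLUMNS, *elements]].copy(), tuple(elements))


def write_survey(table: SurveyTable, path: str | Path) -> None:
    """Write a survey back to CSV; ``read_survey(write_survey(t)) == t``.

    Floats are written in shortest round-tripping form, so re-reading
    reproduces the table bit-for-bit.
    """
    table.data.to_csv(path, index=False,
                      float_format=lambda v: repr(float(v)))


@dataclass
class ValidationReport:
    """Counts of censored / exceeding / nonpositive values per element."""

    below_mdl: dict[str, int] = field(default_factory=dict)
    above_screening: dict[str, int] = field(default_factory=dict)
    nonpositive: dict[str, int] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return not (any(self.above_screening.values()) or any(self.nonpositive.values()))

    def to_json(self) -> str:
        return json.dumps(
            {"below_mdl": self.below_mdl,
             "above_screening": self.above_screening,
             "nonpositive": self.nonpositive},
            indent=2,
        )


def validate_survey(table: SurveyTable, ref: ReferenceData) -> ValidationReport:
    """Screen a survey against detection limits and screening values.

    A concentration ``c <= MDL`` counts as below-or-at the detection limit
    (the uncertainty model treats equality as censored); ``c > screening``
    counts as a screening exceedance.
    """
    report = ValidationReport()
    for el in table.elements:
        c = table.conc[el].to_numpy(dtype=float)
        report.below_mdl[el] = int((c <= ref.require("mdl", el)).sum())
        report.above_screening[el] = int((c > ref.require("screening", el)).sum())
        report.nonpositive[el] = int((c <= 0).sum())
    return report


def replace_censored(table: SurveyTable, ref: ReferenceData) -> tuple[SurveyTable, pd.DataFrame]:
    """Replace concentrations at or below the MDL by MDL/2.

    Returns the substituted table and a boolean flag frame marking the
    censored cells. Downstream index and dose computations use the
    substituted values; the PMF uncertainty model uses the flags.
    """
    df = table.data.copy()
    flags = pd.DataFrame(False, index=df.index, columns=list(table.elements))
    for el in table.elements:
        mdl = ref.require("mdl", el)
        mask = df[el].to_numpy(dtype=float) <= mdl
        flags[el] = mask
        if mask.any():
            logger.warning("%d %s value(s) at/below MDL replaced by MDL/2", mask.sum(), el)
            df.loc[mask, el] = mdl / 2.0
    return SurveyTable(df, table.elements), flags


def summarize(table: SurveyTable) -> pd.DataFrame:
    """Per-element min/mean/max/median/sd/cv (sd is the n-1 sample SD).

    Raises :class:`SurveyError` for fewer than two samples.
    """
    if table.n_samples < 2:
        raise SurveyError("summarize requires at least 2 samples")
    conc = table.conc
    stats = pd.DataFrame(
        {
            "min": conc.min(),
            "mean": conc.mean(),
            "max": conc.max(),
            "median": conc.median(),
            "sd": conc.std(ddof=1),
        }
    )
    stats["cv"] = stats["sd"] / stats["mean"]
    bad = stats.index[(stats["min"] > stats["median"]) | (stats["median"] > stats["max"])]
    if len(bad):  # cannot happen for finite data; guards future refactors
        raise AssertionError(f"ordering violated for {list(bad)}")
    return stats


def summary_to_json(stats: pd.DataFrame) -> str:
    return json.dumps({el: {k: float(v) for k, v in row.items()}
                       for el, row in stats.iterrows()}, indent=2)
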