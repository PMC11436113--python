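"""Pollution indices and Hakanson potential ecological risk.

Implements the classical screening chain for soil surveys:

* single-factor pollution index  PI = C / S  (C measured, S background);
* Nemerow composite index  NPI = sqrt((PI_ave^2 + PI_max^2) / 2);
* per-element ecological risk coefficient  Er = Tr * C / Cn  with the
  Hakanson toxic-response coefficient Tr;
* potential ecological risk index  RI = sum_i Er_i over the element set;

plus the conventional grade classifications for each. All indices are
linear in concentration, so the index of the mean concentration equals the
mean per-sample index.

Grade bins are closed on the left at their lower breakpoint except the
first (so PI = 2 is "moderately contaminated"); the tables in common use
print overlapping bounds and this is the only total, monotone convention
consistent with the strict inequalities they do state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .survey_io import ReferenceData, SurveyTable

PI_GRADES = ("uncontaminated", "lightly contaminated",
             "moderately contaminated", "strongly contaminated")
NPI_GRADES = ("clean", "warning limit", "slight pollution",
              "moderate pollution", "heavy pollution")
ER_GRADES = ("slight", "moderate", "considerable", "high", "serious")
RI_GRADES = ("slight", "moderate", "high", "significantly high")

_PI_BREAKS = (1.0, 2.0, 3.0)
_NPI_BREAKS = (0.7, 1.0, 2.0, 3.0)
_ER_BREAKS = (40.0, 80.0, 160.0, 320.0)
_RI_BREAKS = (150.0, 300.0, 600.0)


def _classify(x, breaks: Sequence[float], grades: Sequence[str]):
    """Left-closed step classification: grade i for breaks[i-1] <= x < breaks[i]."""
    idx = np.searchsorted(np.asarray(breaks), np.asarray(x, dtype=float), side="right")
    if np.ndim(x):
        return np.asarray(grades, dtype=object)[idx]
    return grades[int(idx)]


def single_factor_index(c, background: float):
    """PI = C / S. Accepts scalars or arrays; background must be positive."""
    if background <= 0:
        raise ValueError("background value must be positive")
    return np.asarray(c, dtype=float) / background if np.ndim(c) else float(c) / background


def classify_pi(pi):
    return _classify(pi, _PI_BREAKS, PI_GRADES)


def nemerow_index(pis) -> float:
    """NPI = sqrt((mean(PI)^2 + max(PI)^2) / 2) over the element set."""
    pis = np.asarray(pis, dtype=float)
    if pis.size == 0:
        raise ValueError("empty PI vector")
    return float(np.sqrt((pis.mean() ** 2 + pis.max() ** 2) / 2.0))


def classify_npi(npi):
    # the conventional table states "<= 0.7 clean", so the first NPI
    # breakpoint is right-closed, unlike every other bin edge
    out = _classify(npi, _NPI_BREAKS, NPI_GRADES)
    at_limit = np.asarray(npi, dtype=float) == _NPI_BREAKS[0]
    if np.ndim(npi):
        out[at_limit] = NPI_GRADES[0]
        return out
    return NPI_GRADES[0] if at_limit else out


def ecological_coefficient(c, background: float, tr: float):
    """Er = Tr * C / Cn, the toxicity-weighted single-factor index."""
    if tr is None:
        raise ValueError("toxicity coefficient missing")
    return tr * single_factor_index(c, background)


def classify_er(er):
    return _classify(er, _ER_BREAKS, ER_GRADES)


def ecological_index(ers) -> float:
    """RI = sum of the per-element Er values."""
    return float(np.sum(np.asarray(ers, dtype=float)))


def classify_ri(ri):
    return _classify(ri, _RI_BREAKS, RI_GRADES)


@dataclass(frozen=True)
class IndexResult:
    """Per-sample / per-element indices with grade labels.

    ``pi`` and ``er`` are samples x elements frames; ``npi`` and ``ri``
    per-sample series; ``*_grade`` the matching labels.
    """

    pi: pd.DataFrame
    npi: pd.Series
    er: pd.DataFrame
    ri: pd.Series
    pi_grade: pd.DataFrame
    npi_grade: pd.Series
    er_grade: pd.DataFrame
    ri_grade: pd.Series

    def to_tidy(self) -> pd.DataFrame:
        """Long-format (sample_id, element, index, value, grade) table."""
        rows = []
        for name, values, grades in (("PI", self.pi, self.pi_grade),
                                     ("Er", self.er, self.er_grade)):
            long = values.stack().rename("value").reset_index()
            long.columns = ["sample_id", "element", "value"]
            long["index"] = name
            long["grade"] = grades.stack().to_numpy()
            rows.append(long)
        for name, values, grades in (("NPI", self.npi, self.npi_grade),
                                     ("RI", self.ri, self.ri_grade)):
            long = values.rename("value").reset_index()
            long.columns = ["sample_id", "value"]
            long["element"] = ""
            long["index"] = name
            long["grade"] = grades.to_numpy()
            rows.append(long)
        return pd.concat(rows, ignore_index=True)[
            ["sample_id", "element", "index", "value", "grade"]
        ]


def assess(table: SurveyTable, ref: ReferenceData) -> IndexResult:
    """Compute PI, NPI, Er and RI for every sample of a survey."""
    ids = table.data["sample_id"]
    pi = pd.DataFrame(index=ids, columns=list(table.elements), dtype=float)
    er = pi.copy()
    for el in table.elements:
        c = table.conc[el].to_numpy(dtype=float)
        pi[el] = single_factor_index(c, ref.require("background", el))
        er[el] = ecological_coefficient(c, ref.require("background", el),
                                        ref.require("toxicity", el))
    npi = pd.Series(np.sqrt((pi.mean(axis=1) ** 2 + pi.max(axis=1) ** 2) / 2.0),
                    index=ids, name="NPI")
    ri = pd.Series(er.sum(axis=1), index=ids, name="RI")
    return IndexResult(
        pi=pi, npi=npi, er=er, ri=ri,
        pi_grade=pi.apply(lambda col: classify_pi(col.to_numpy())),
        npi_grade=pd.Series(classify_npi(npi.to_numpy()), index=ids, name="NPI_grade"),
        er_grade=er.apply(lambda col: classify_er(col.to_numpy())),
        ri_grade=pd.Series(classify_ri(ri.to_numpy()), index=ids, name="RI_grade"),
    )


def tabulate_grades(table: SurveyTable, ref: ReferenceData) -> dict[str, pd.DataFrame]:
    """Fraction of samples in each PI grade and each Er grade, per element.

    Each returned frame is elements x grades with rows summing to 1.
    """
    result = assess(table, ref)
    out = {}
    for key, grades, labels in (("PI", result.pi_grade, PI_GRADES),
                                ("Er", result.er_grade, ER_GRADES)):
        frac = pd.DataFrame(0.0, index=list(table.elements), columns=list(labels))
        for el in table.elements:
            counts = grades[el].value_counts(normalize=True)
            for label, p in counts.items():
                frac.loc[el, label] = p
        out[key] = frac
    return out
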