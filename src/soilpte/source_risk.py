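"""Allocate ecological and health risk across apportioned sources.

Given the column-stochastic matrix F (sources x elements) of each source's
fractional contribution to each element's mass — typically
``ContributionTable.fractions()`` from the PMF stage — a per-element risk
vector is distributed over sources by

    R_j = sum_i F[j, i] * r_i,        D_j = R_j / sum_j R_j,

for r the per-element mean ecological risk coefficient Er, hazard quotient
HQ, or carcinogenic risk CR. Because every element's fractions sum to 1,
the source totals exchange summation order with the direct aggregate
(sum_j R_j equals RI, HI or TCR computed from the same r), and each D
vector is a probability vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_TOL = 1e-6


@dataclass(frozen=True)
class SourceRiskResult:
    """Per-source risk totals and fractional allocations."""

    risk: pd.Series        # R_j per source (same units as the input risk)
    allocation: pd.Series  # D_j, sums to 1


def _check_fractions(F: pd.DataFrame) -> pd.DataFrame:
    colsum = F.sum(axis=0)
    if not np.allclose(colsum, 1.0, atol=_TOL):
        bad = colsum[(colsum - 1.0).abs() > _TOL].index.tolist()
        raise ValueError(f"source fractions must sum to 1 per element; off for {bad}")
    if (F.to_numpy() < -_TOL).any():
        raise ValueError("source fractions must be nonnegative")
    return F


def allocate(F: pd.DataFrame, risk: pd.Series) -> SourceRiskResult:
    """Distribute a per-element risk vector over sources.

    ``F`` is sources x elements with columns summing to 1; ``risk`` maps a
    subset of F's elements to nonnegative per-element risk values (elements
    absent from ``risk`` — e.g. those without slope factors — are ignored).
    """
    F = _check_fractions(F)
    risk = risk.dropna()
    if (risk < 0).any():
        raise ValueError("risk values must be nonnegative")
    missing = [e for e in risk.index if e not in F.columns]
    if missing:
        raise KeyError(f"elements missing from source fractions: {missing}")
    sub = F[list(risk.index)]
    rj = pd.Series(sub.to_numpy() @ risk.to_numpy(), index=F.index, name="risk")
    total = rj.sum()
    if total <= 0:
        raise ValueError("total risk is zero; allocation undefined")
    return SourceRiskResult(risk=rj, allocation=(rj / total).rename("allocation"))


def source_ecological_risk(F: pd.DataFrame, er: pd.Series) -> SourceRiskResult:
    """Source-resolved potential ecological risk: RI_j and D_j,RI.

    ``er`` is the per-element mean ecological risk coefficient; sum_j RI_j
    equals the aggregate RI at the same concentrations.
    """
    return allocate(F, er)


def source_health_risk(F: pd.DataFrame, hq: pd.Series,
                       cr: pd.Series | None = None
                       ) -> tuple[SourceRiskResult, SourceRiskResult | None]:
    """Source-resolved HQ (and CR where slope factors exist) for one group.

    ``hq`` per-element hazard quotients; ``cr`` per-element carcinogenic
    risks restricted to elements with slope factors (may be None). Returns
    ``(hq_result, cr_result_or_None)``.
    """
    hq_res = allocate(F, hq)
    cr_res = allocate(F, cr) if cr is not None else None
    return hq_res, cr_res


def allocation_table(F: pd.DataFrame, risks: dict[str, pd.Series]) -> pd.DataFrame:
    """Sankey-style long table (source, element, risk measure, share).

    ``risks`` maps a measure name (e.g. "RI", "HI_child") to its
    per-element vector; each row gives the share of the total measure
    carried by one (source, element) cell.
    """
    rows = []
    for name, risk in risks.items():
        F_checked = _check_fractions(F)
        risk = risk.dropna()
        total = float((F_checked[list(risk.index)].to_numpy() @ risk.to_numpy()).sum())
        for src in F.index:
            for el in risk.index:
                rows.append((name, src, el,
                             float(F_checked.loc[src, el] * risk[el] / total)))
    return pd.DataFrame(rows, columns=["measure", "source", "element", "share"])
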