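"""Orchestration: configuration, staged runs, and IDW interpolation.

``run_pipeline`` chains the assessment stages — validation, descriptive
statistics, contamination indices, ecological risk, health risk,
multivariate diagnostics, PMF factor scan and fit, source-oriented risk
allocation, and optional inverse-distance-weighted concentration grids —
writing every artifact as CSV/JSON with run metadata. A run is a pure
function of (input data, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from . import __version__
from .survey_io import (ELEMENTS, ReferenceData, SurveyTable, load_reference,
                        read_survey, replace_censored, summarize, validate_survey)
from . import contamination, health_risk, multivariate, pmf, source_risk, synthetic

logger = logging.getLogger(__name__)

ALL_STAGES = ("validate", "summary", "indices", "ecorisk", "healthrisk",
              "mva", "pmf", "sourcerisk", "idw")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    Exactly one of ``input_csv`` (survey CSV path) or ``synthetic_n``
    (sample count drawn from the default four-source scenario) must be set.
    """

    input_csv: str | None = None
    synthetic_n: int | None = None
    seed: int = 0
    output_dir: str = "soilpte_out"
    elements: Sequence[str] = ELEMENTS
    stages: Sequence[str] = ALL_STAGES
    # pmf settings
    pmf_factors: int = 4
    pmf_scan_range: tuple[int, int] = (2, 7)
    pmf_starts: int = 20
    pmf_error_fraction: float = 0.1
    pmf_robust_cutoff: float = 4.0
    pmf_max_iter: int = 5000
    # idw settings
    idw_power: float = 2.0
    idw_neighbors: int = 12
    idw_resolution: int = 50
    # reference overrides
    reference_elements_csv: str | None = None
    rfd_sf_csv: str | None = None

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic_n is None):
            raise ValueError("set exactly one of input_csv or synthetic_n")
        for name in ("pmf_factors", "pmf_starts", "idw_power",
                     "idw_neighbors", "idw_resolution"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pmf_scan_range" in raw:
            raw["pmf_scan_range"] = tuple(raw["pmf_scan_range"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps({k: list(v) if isinstance(v, tuple) else v
                           for k, v in asdict(self).items()}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def idw_interpolate(points: np.ndarray, values: np.ndarray,
                    grid_x: np.ndarray, grid_y: np.ndarray,
                    power: float = 2.0, k: int = 12) -> np.ndarray:
    """Inverse-distance-weighted interpolation onto a rectangular grid.

    Each node takes sum(w_i v_i)/sum(w_i) with w_i = d_i^-power over its k
    nearest sample points; a node coincident with a sample returns that
    sample's value exactly. Returns an array of shape (len(grid_y),
    len(grid_x)). The surface is a convex combination of the data, hence
    bounded by [min(values), max(values)].
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(points) == 0:
        raise ValueError("empty point set")
    if power <= 0:
        raise ValueError("power must be positive")
    k = min(k, len(points))
    tree = cKDTree(points)
    gx, gy = np.meshgrid(grid_x, grid_y)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    dist, idx = tree.query(nodes, k=k)
    dist = np.atleast_2d(dist.T).T if k == 1 else dist
    idx = np.atleast_2d(idx.T).T if k == 1 else idx
    out = np.empty(len(nodes))
    exact = dist[:, 0] == 0.0
    out[exact] = values[idx[exact, 0]]
    with np.errstate(divide="ignore"):
        w = dist[~exact] ** (-power)
    out[~exact] = (w * values[idx[~exact]]).sum(axis=1) / w.sum(axis=1)
    return out.reshape(gx.shape)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return a report dict of artifacts.

    Stage failures abort with the stage name; artifacts already written are
    kept. Identical (config, seed) yields byte-identical numeric outputs.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = load_reference(cfg.reference_elements_csv, cfg.rfd_sf_csv)
    truth = None
    if cfg.input_csv is not None:
        table = read_survey(cfg.input_csv, cfg.elements)
    else:
        scenario = synthetic.default_hailun_scenario()
        table, truth = synthetic.generate_survey(scenario, cfg.synthetic_n, cfg.seed)
        table.data.to_csv(out / "survey.csv", index=False)

    report: dict = {"config_digest": cfg.digest(), "seed": cfg.seed,
                    "version": __version__, "n_samples": table.n_samples,
                    "stages": {}}
    stage = "start"
    try:
        clean, censored_flags = replace_censored(table, ref)
        mean_conc = clean.conc.mean()
        hazard_res = None
        contrib = None

        for stage in [s for s in ALL_STAGES if s in cfg.stages]:
            t0 = time.perf_counter()
            artifacts: list[str] = []
            if stage == "validate":
                rep = validate_survey(table, ref)
                (out / "validation.json").write_text(rep.to_json())
                artifacts.append("validation.json")
            elif stage == "summary":
                stats = summarize(clean)
                _write_csv(stats, out / "summary.csv")
                artifacts.append("summary.csv")
            elif stage == "indices":
                res = contamination.assess(clean, ref)
                _write_csv(res.to_tidy(), out / "indices.csv", index=False)
                artifacts.append("indices.csv")
            elif stage == "ecorisk":
                res = contamination.assess(clean, ref)
                mean_er = res.er.mean()
                eco = pd.DataFrame({"mean_er": mean_er,
                                    "grade": contamination.classify_er(mean_er.to_numpy())})
                _write_csv(eco, out / "ecorisk.csv")
                ri = contamination.ecological_index(mean_er)
                (out / "ecorisk.json").write_text(json.dumps(
                    {"RI_mean": ri, "grade": contamination.classify_ri(ri)}, indent=2))
                artifacts += ["ecorisk.csv", "ecorisk.json"]
            elif stage == "healthrisk":
                hazard_res = health_risk.hazard(mean_conc, health_risk.DEFAULT_EXPOSURE, ref)
                carc = health_risk.carcinogenic(mean_conc, health_risk.DEFAULT_EXPOSURE, ref)
                _write_csv(hazard_res.hq, out / "healthrisk_hq.csv", index=False)
                _write_csv(carc.cr, out / "healthrisk_cr.csv", index=False)
                (out / "healthrisk.json").write_text(json.dumps({
                    "HI": hazard_res.hi.to_dict(),
                    "TCR": carc.tcr.to_dict(),
                    "classification_nc": hazard_res.classification,
                    "classification_ca": carc.classification}, indent=2))
                artifacts += ["healthrisk_hq.csv", "healthrisk_cr.csv", "healthrisk.json"]
            elif stage == "mva":
                R, pvals = multivariate.pearson_matrix(clean)
                _write_csv(R, out / "correlation.csv")
                chi2, df, pval = multivariate.bartlett_sphericity(R, clean.n_samples)
                overall, msa = multivariate.kmo(R)
                pres = multivariate.pca(clean)
                _write_csv(pres.loadings, out / "pca_loadings.csv")
                (out / "mva.json").write_text(json.dumps({
                    "kmo": overall, "bartlett_chi2": chi2, "bartlett_df": df,
                    "bartlett_p": pval,
                    "eigenvalues": pres.eigenvalues.tolist(),
                    "variance_pct": pres.variance_pct.tolist(),
                    "retained": pres.retained}, indent=2))
                artifacts += ["correlation.csv", "pca_loadings.csv", "mva.json"]
            elif stage == "pmf":
                U = pmf.uncertainty_matrix(clean, ref.mdl, cfg.pmf_error_fraction)
                scan = pmf.scan_factors(clean.conc, U.u, *cfg.pmf_scan_range,
                                        n_starts=max(2, cfg.pmf_starts // 4),
                                        seed=cfg.seed, max_iter=cfg.pmf_max_iter)
                _write_csv(scan, out / "pmf_scan.csv", index=False)
                sol = pmf.fit_pmf(clean.conc, U.u, cfg.pmf_factors,
                                  n_starts=cfg.pmf_starts, seed=cfg.seed,
                                  max_iter=cfg.pmf_max_iter,
                                  robust_cutoff=cfg.pmf_robust_cutoff,
                                  elements=clean.elements)
                contrib = pmf.contribution_table(sol, force=True)
                _write_csv(pd.DataFrame(sol.g, columns=contrib.pct.index),
                           out / "pmf_g.csv", index=False)
                _write_csv(pd.DataFrame(sol.f, index=contrib.pct.index,
                                        columns=list(clean.elements)), out / "pmf_f.csv")
                _write_csv(contrib.pct, out / "pmf_contributions.csv")
                (out / "pmf.json").write_text(json.dumps({
                    "q_true": sol.q_true, "q_robust": sol.q_robust,
                    "q_expected": sol.q_expected, "converged": sol.converged,
                    "iterations": sol.iterations, "n_starts": sol.n_starts,
                    "best_start_seed": sol.best_start_seed, "seed": cfg.seed,
                    "share_pct": contrib.share.to_dict()}, indent=2))
                artifacts += ["pmf_scan.csv", "pmf_g.csv", "pmf_f.csv",
                              "pmf_contributions.csv", "pmf.json"]
            elif stage == "sourcerisk":
                if contrib is None:
                    logger.warning("sourcerisk skipped: pmf stage not run")
                    continue
                res = contamination.assess(clean, ref)
                F = contrib.fractions()
                eco = source_risk.source_ecological_risk(F, res.er.mean())
                hz = hazard_res or health_risk.hazard(mean_conc, health_risk.DEFAULT_EXPOSURE, ref)
                carc = health_risk.carcinogenic(mean_conc, health_risk.DEFAULT_EXPOSURE, ref)
                rows = {"RI": eco.allocation}
                for grp in ("adult", "child"):
                    hq_res, cr_res = source_risk.source_health_risk(
                        F, health_risk.hq_by_element(hz, grp),
                        health_risk.cr_by_element(carc, grp))
                    rows[f"HI_{grp}"] = hq_res.allocation
                    rows[f"TCR_{grp}"] = cr_res.allocation
                _write_csv(pd.DataFrame(rows), out / "source_risk.csv")
                artifacts.append("source_risk.csv")
            elif stage == "idw":
                coords = clean.coords
                xs = np.linspace(coords[:, 0].min(), coords[:, 0].max(), cfg.idw_resolution)
                ys = np.linspace(coords[:, 1].min(), coords[:, 1].max(), cfg.idw_resolution)
                for el in clean.elements:
                    grid = idw_interpolate(coords, clean.conc[el].to_numpy(),
                                           xs, ys, cfg.idw_power, cfg.idw_neighbors)
                    gx, gy = np.meshgrid(xs, ys)
                    _write_csv(pd.DataFrame({"x": gx.ravel(), "y": gy.ravel(),
                                             "value": grid.ravel()}),
                               out / f"idw_{el}.csv", index=False)
                    artifacts.append(f"idw_{el}.csv")
            elapsed = time.perf_counter() - t0
            logger.info("stage %-11s n=%d elapsed=%.2fs -> %s",
                        stage, table.n_samples, elapsed, artifacts)
            report["stages"][stage] = {"artifacts": artifacts, "elapsed_s": elapsed}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "run_metadata.json").write_text(json.dumps(report, indent=2))
    return report
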