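"""End-to-end drivers for the two selection-response assessments.

The first-stage (GCA1) assessment estimates the long-term ratio rho from
multi-year data (either first-stage trials of several years, "MY", or
all stages of all cycles, "CYC"), fits the current year's apparent
genomic variance, splits it by rho, re-solves the current-year model
with fixed components, and simulates selection probabilities from the
resulting (D, C) pair.  The second-stage (GCA2) assessment does a
single-stage two-year fit per cycle on the entries common to the first
two trial years and simulates from that fit directly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .markers import KinshipMatrix
from .pipelines import (CurrentYearResult, Stage2Result, adjust_and_refit,
                        assemble_dataset, fit_current_year_apparent,
                        fit_gca2_cycle, fit_stage1_year, fit_stage2,
                        select_common_entries)
from .simulate import (SelectionProbabilityTable, build_omega, factor_omega,
                       selection_probabilities)
from . import io as sio

__all__ = ["RunConfig", "GCA1Assessment", "GCA2Assessment",
           "run_gca1_assessment", "run_gca2_assessment"]


@dataclass
class RunConfig:
    """Settings of an assessment run (mirrors the YAML config schema)."""

    mode: str = "MY"                 # MY | CYC (rho-estimation dataset)
    rho_years: list | None = None    # years entering the rho estimate
    current_year: object = None      # year of the single-year assessment
    year_effect: str = "random"      # random | fixed year main effect
    weights: str = "diag_of_inv"     # Smith-weight variant for stage 2
    cycles: list | None = None       # cycles for the second-stage assessment
    S: int = 100_000                 # simulation replicates
    seed: int = 42
    m_list: tuple = (1, 5, 10, 15, 20)
    n_grid: list | None = None       # defaults to 1%..100% of N
    minimize: bool = False
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def manifest(self) -> dict:
        cfg = asdict(self)
        blob = json.dumps(cfg, sort_keys=True, default=str).encode()
        return {"config": cfg,
                "config_sha256": hashlib.sha256(blob).hexdigest()}


@dataclass
class GCA1Assessment:
    """All artifacts of the first-stage assessment."""

    config: RunConfig
    stage1: list
    stage2: Stage2Result
    apparent: object
    current: CurrentYearResult
    probabilities: SelectionProbabilityTable
    timings: dict = field(default_factory=dict)

    @property
    def rho(self) -> float:
        return self.stage2.rho

    def report(self) -> dict:
        adj = self.current.adjustment
        return {
            "mode": self.config.mode,
            "rho": self.stage2.rho,
            "se_rho": self.stage2.se_rho,
            "sigma2_g_longterm": self.stage2.sigma2_g,
            "sigma2_gy_longterm": self.stage2.sigma2_gy,
            "sigma2_g_tilde": adj.sigma2_g_tilde,
            "sigma2_g_adj": adj.sigma2_g_adj,
            "sigma2_gy_adj": adj.sigma2_gy_adj,
            "corr_value": self.probabilities.corr_value,
            "corr_rank": self.probabilities.corr_rank,
            "S": self.probabilities.S,
            "seed": self.probabilities.seed,
            "factorization": self.probabilities.method,
            "timings_s": self.timings,
            **self.config.manifest(),
        }


@dataclass
class GCA2Assessment:
    """Per-cycle artifacts of the second-stage assessment."""

    config: RunConfig
    cycles: dict   # cycle -> (Stage2Result, SelectionProbabilityTable)

    def report(self) -> dict:
        out = {"mode": "GCA2", **self.config.manifest(), "cycles": {}}
        for cyc, (fit, probs) in self.cycles.items():
            out["cycles"][str(cyc)] = {
                "sigma2_g": fit.sigma2_g,
                "sigma2_gy": fit.sigma2_gy,
                "rho": fit.rho,
                "n_entries": probs.n_entries,
                "corr_value": probs.corr_value,
                "corr_rank": probs.corr_rank,
                "mc_se_at_half": float(np.sqrt(0.25 / probs.S)),
                "S": probs.S,
            }
        return out


def run_gca1_assessment(plots: pd.DataFrame, K: KinshipMatrix,
                        config: RunConfig) -> GCA1Assessment:
    """Execute the full first-stage pipeline on one dataset."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    rho_data = assemble_dataset(plots, config.mode, years=config.rho_years)
    current_year = config.current_year
    if current_year is None:
        raise ValueError("config.current_year is required")
    cur_mask = plots["year"] == current_year
    if "is_check" in plots.columns:
        cur_mask &= ~plots["is_check"]
    current = plots.loc[cur_mask]
    if len(current) == 0:
        raise ValueError(f"no plots for current year {current_year!r}")
    rho_data = rho_data.loc[rho_data["year"] != current_year]
    timings["assemble"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stage1 = []
    for yr in sorted(rho_data["year"].unique()):
        stage1.append(fit_stage1_year(rho_data, yr, weights=config.weights))
    means = pd.concat([s.means for s in stage1], ignore_index=True)
    timings["stage1"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stage2 = fit_stage2(means, K, year_effect=config.year_effect)
    timings["stage2"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    apparent = fit_current_year_apparent(current, K)
    refit = adjust_and_refit(current, K, apparent, stage2.rho)
    timings["current_year"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    omega = build_omega(K, refit.adjustment.sigma2_g_adj, refit.pev_matrix())
    factor = factor_omega(omega)
    probs = selection_probabilities(
        factor, config.S, config.seed, n_grid=config.n_grid,
        m_list=config.m_list, minimize=config.minimize)
    timings["simulation"] = time.perf_counter() - t0

    result = GCA1Assessment(config, stage1, stage2, apparent, refit,
                            probs, timings)
    if config.out_dir:
        _persist_gca1(result, K)
    return result


def run_gca2_assessment(plots: pd.DataFrame, K: KinshipMatrix,
                        config: RunConfig) -> GCA2Assessment:
    """Execute the per-cycle second-stage pipeline."""
    cycles = config.cycles
    if not cycles:
        raise ValueError("config.cycles is required for the second-stage assessment")
    out: dict = {}
    for cyc in cycles:
        common = select_common_entries(plots, cyc)
        fit = fit_gca2_cycle(common, K, year_effect=config.year_effect)
        if fit.sigma2_g <= 0:
            raise ValueError(f"cycle {cyc!r}: genomic variance at zero; "
                             "nothing to simulate")
        C = fit.fit.prediction_error_matrix("gbv")
        omega = build_omega(K, fit.sigma2_g, C)
        factor = factor_omega(omega)
        probs = selection_probabilities(
            factor, config.S, config.seed, n_grid=config.n_grid,
            m_list=config.m_list, minimize=config.minimize)
        out[cyc] = (fit, probs)
    result = GCA2Assessment(config, out)
    if config.out_dir:
        _persist_gca2(result)
    return result


def _persist_gca1(result: GCA1Assessment, K: KinshipMatrix) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.write_json(result.report(), out / "gca1_report.json")
    for s in result.stage1:
        s.means.to_csv(out / f"stage1_means_{s.year}.csv", index=False)
    sio.write_fit_report(result.stage2.fit, out / "stage2_fit.json",
                         extra={"rho": result.stage2.rho,
                                "se_rho": result.stage2.se_rho})
    sio.write_fit_report(result.apparent, out / "current_year_apparent.json")
    result.current.pev_matrix().to_csv(out / "C_current_year.csv",
                                       index_label="entry")
    result.current.gblups().rename("gblup").to_csv(out / "gblups_current_year.csv",
                                                   index_label="entry")
    result.probabilities.to_csv(out / "selection_probabilities.csv")


def _persist_gca2(result: GCA2Assessment) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.write_json(result.report(), out / "gca2_report.json")
    for cyc, (fit, probs) in result.cycles.items():
        sio.write_fit_report(fit.fit, out / f"gca2_fit_cycle{cyc}.json",
                             extra={"rho": fit.rho, "se_rho": fit.se_rho})
        probs.to_csv(out / f"selection_probabilities_cycle{cyc}.csv")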