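"""Genomic-prediction analysis workflows for multi-environment trials.

Four workflows are assembled from the mixed-model engine:

* **Stage 1** (per year, plot level): entry effects fixed, design factors
  random, location-specific residual variances; yields adjusted entry
  means (EBLUEs, avoiding double shrinkage) plus Smith-style precision
  weights from their covariance matrix.
* **Stage 2** (entry-year means): year + genomic main effect (GBV, with
  kinship covariance) + GBV-by-year (block-diagonal per-year kinship,
  common variance), residual fixed at the Smith weights.  Gives the
  long-term ratio ``rho = sigma2_g / (sigma2_g + sigma2_gy)``.
* **Current-year** (single-stage, plot level): the apparent genomic
  variance ``sigma2_g_tilde`` absorbs both GBV and GBV-by-year; the
  rho-adjustment splits it and a one-pass rerun with both kinship terms
  sharing the entry incidence matrix yields the shrunken GBLUPs and
  their prediction-error matrix C for the selection simulation.
* **GCA2** (two-year, single-stage): entries common to the first and
  second trial years of a cycle, nuisance terms nested within years with
  year-specific variances, year-location residual variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import KinshipMatrix
from .model import MixedModel, MixedModelResults, RandomTerm, Residual
from .varcomp import VarianceComponents, rho_from_components, se_rho_delta

__all__ = [
    "Stage1Result", "Stage2Result", "RhoAdjustment", "CurrentYearResult",
    "fit_stage1_year", "fit_stage2", "assemble_dataset",
    "fit_current_year_apparent", "adjust_and_refit",
    "select_common_entries", "fit_gca2_cycle",
]

#: random design terms of the plot-level model, in fitting order
_PLOT_TERMS = ("tester", "location", "entry:tester", "entry:location",
               "trial", "rep", "block")


def _with_nesting_labels(plots: pd.DataFrame) -> pd.DataFrame:
    """Disambiguate nested factor labels (block within rep within trial ...)."""
    df = plots.copy()
    df["trial"] = (df["location"].astype(str) + "/" + df["trial"].astype(str))
    df["rep"] = df["trial"] + "/r" + df["rep"].astype(str)
    df["block"] = df["rep"] + "/" + df["block"].astype(str)
    return df


@dataclass
class Stage1Result:
    """Adjusted entry means (EBLUEs) of one year with Smith weights."""

    year: object
    means: pd.DataFrame          # entry, year, adjusted_mean, weight
    fit: MixedModelResults
    dropped_entries: list


@dataclass
class Stage2Result:
    """Multi-year genomic fit: components, rho and its delta-method SE."""

    fit: MixedModelResults
    sigma2_g: float
    sigma2_gy: float
    rho: float
    se_rho: float | None

    @property
    def vc(self) -> VarianceComponents:
        return self.fit.vc


@dataclass
class RhoAdjustment:
    """Split of the apparent genomic variance by the long-term ratio rho.

    sigma2_g_adj + sigma2_gy_adj == sigma2_g_tilde exactly.
    """

    sigma2_g_tilde: float
    rho: float
    sigma2_g_adj: float
    sigma2_gy_adj: float

    @classmethod
    def from_rho(cls, sigma2_g_tilde: float, rho: float) -> "RhoAdjustment":
        if not (0.0 < rho <= 1.0):
            raise ValueError("rho must lie in (0, 1]")
        if sigma2_g_tilde < 0:
            raise ValueError("apparent variance must be >= 0")
        g = rho * sigma2_g_tilde
        return cls(sigma2_g_tilde, rho, g, sigma2_g_tilde - g)


@dataclass
class CurrentYearResult:
    """Rerun of the current-year model with fixed, rho-split components."""

    adjustment: RhoAdjustment
    fit: MixedModelResults

    def gblups(self) -> pd.Series:
        return self.fit.blups("gbv")

    def pev_matrix(self) -> pd.DataFrame:
        return self.fit.prediction_error_matrix("gbv")


def fit_stage1_year(plots: pd.DataFrame, year, weights: str = "diag_of_inv",
                    **fit_kw) -> Stage1Result:
    """Per-year plot-level analysis with fixed entry effects.

    Fits yield = mean + entry (fixed) + tester + location + entry.tester +
    entry.location + trial + rep + block (random, iid) with
    location-specific residual variances, and returns generalized
    least-squares adjusted entry means with precision weights.

    ``weights`` selects the Smith-weight variant: ``"diag_of_inv"`` takes
    the diagonal of the inverse EBLUE covariance matrix (default),
    ``"inv_of_diag"`` the reciprocal diagonal.
    """
    if weights not in ("diag_of_inv", "inv_of_diag"):
        raise ValueError("weights must be 'diag_of_inv' or 'inv_of_diag'")
    df = plots.loc[plots["year"] == year]
    if len(df) == 0:
        raise ValueError(f"no plots for year {year!r}")
    df = _with_nesting_labels(df)
    multi_loc = df["location"].nunique() > 1
    terms = []
    for t in _PLOT_TERMS:
        if t == "entry:location" and not multi_loc:
            continue
        if t == "location" and not multi_loc:
            continue
        if t == "tester" and df["tester"].nunique() < 2:
            continue
        if t == "entry:tester" and df["tester"].nunique() < 2:
            continue
        if t == "trial" and df["trial"].nunique() < 2:
            continue
        factors = tuple(t.split(":"))
        terms.append(RandomTerm(factors, name=t))
    model = MixedModel(df, "yield", fixed=["entry"], random=terms,
                       residual=Residual(groups="location") if multi_loc
                       else Residual())
    fit = model.fit(**fit_kw)

    entries = sorted(df["entry"].unique())
    dropped = [nm[len("entry["):-1] for nm in model.dropped_fixed
               if nm.startswith("entry[")]
    kept = [e for e in entries if e not in set(dropped)]
    # adjusted mean of entry e = intercept + its treatment-coded effect
    contrast = np.zeros((len(kept), model.p))
    contrast[:, model.x_names.index("(Intercept)")] = 1.0
    for i, e in enumerate(kept):
        nm = f"entry[{e}]"
        if nm in model.x_names:
            contrast[i, model.x_names.index(nm)] = 1.0
    means_vec = contrast @ fit.fe_params.to_numpy()
    vcov = contrast @ fit.fe_cov.to_numpy() @ contrast.T
    if weights == "diag_of_inv":
        w = np.diag(np.linalg.inv(vcov)).copy()
    else:
        w = 1.0 / np.diag(vcov)
    if (w <= 0).any():
        raise ValueError("non-positive Smith weight; stage-1 fit is degenerate")
    means = pd.DataFrame({"entry": kept, "year": year,
                          "adjusted_mean": means_vec, "weight": w})
    return Stage1Result(year, means, fit, dropped)


def fit_stage2(means: pd.DataFrame, K: KinshipMatrix,
               year_effect: str = "random", **fit_kw) -> Stage2Result:
    """Genomic model on adjusted entry-year means.

    mean = mu + year + GBV + GBV-by-year + e, where GBV has covariance
    ``K sigma2_g``, GBV-by-year is block-diagonal over years with blocks
    ``K_j sigma2_gy`` (common variance), and the residual is fixed at
    ``diag(1 / weight)`` (Smith weighting, no free residual parameter).
    """
    if means["year"].nunique() < 2:
        raise ValueError("rho is unidentifiable from a single year; "
                         "use the current-year workflow instead")
    if year_effect not in ("random", "fixed"):
        raise ValueError("year_effect must be 'random' or 'fixed'")
    random = []
    fixed = []
    if year_effect == "random":
        random.append(RandomTerm("year", name="year"))
    else:
        fixed.append("year")
    random += [
        RandomTerm("entry", kinship=K, name="gbv"),
        RandomTerm("entry", kinship=K, kinship_by="year", name="gbv_x_year"),
    ]
    model = MixedModel(means, "adjusted_mean", fixed=fixed, random=random,
                       residual=Residual(weights="weight"))
    fit = model.fit(**fit_kw)
    s2g = fit.vc["gbv"]
    s2gy = fit.vc["gbv_x_year"]
    rho = rho_from_components(s2g, s2gy)
    se = None
    try:
        cov = fit.vc.covariance_block(["gbv", "gbv_x_year"])
        se = se_rho_delta(s2g, s2gy, cov)
    except (KeyError, ValueError):
        pass
    return Stage2Result(fit, s2g, s2gy, rho, se)


def assemble_dataset(plots: pd.DataFrame, mode: str, years=None,
                     stages=("GCA1",)) -> pd.DataFrame:
    """Select the analysis dataset for rho estimation.

    ``mode="MY"`` keeps only first-stage (GCA1) records of the given
    years; ``mode="CYC"`` keeps all stages of all cycles.  Check entries
    are removed in both.
    """
    df = plots.loc[~plots.get("is_check", pd.Series(False, index=plots.index))]
    if mode == "MY":
        df = df.loc[df["stage"].isin(stages)]
        if years is not None:
            df = df.loc[df["year"].isin(list(years))]
    elif mode == "CYC":
        if years is not None:
            df = df.loc[df["year"].isin(list(years))]
    else:
        raise ValueError("mode must be 'MY' or 'CYC'")
    if len(df) == 0:
        raise ValueError(f"empty dataset after {mode} selection")
    return df.reset_index(drop=True)


def fit_current_year_apparent(plots: pd.DataFrame, K: KinshipMatrix,
                              **fit_kw) -> MixedModelResults:
    """Single-stage, single-year fit of the apparent genomic variance.

    The plot-level model with the fixed entry effect replaced by a random
    GBV with covariance ``K sigma2_g_tilde``; the estimate absorbs both
    the genomic main effect and its within-year interaction.
    """
    if plots["year"].nunique() != 1:
        raise ValueError("current-year model expects a single year of data")
    df = _with_nesting_labels(plots)
    multi_loc = df["location"].nunique() > 1
    terms = [RandomTerm("entry", kinship=K, name="gbv")]
    for t in _PLOT_TERMS:
        if t in ("location", "entry:location") and not multi_loc:
            continue
        if t in ("tester", "entry:tester") and df["tester"].nunique() < 2:
            continue
        if t == "trial" and df["trial"].nunique() < 2:
            continue
        terms.append(RandomTerm(tuple(t.split(":")), name=t))
    model = MixedModel(df, "yield", fixed=[], random=terms,
                       residual=Residual(groups="location") if multi_loc
                       else Residual())
    return model.fit(**fit_kw)


def adjust_and_refit(plots: pd.DataFrame, K: KinshipMatrix,
                     apparent: MixedModelResults, rho: float) -> CurrentYearResult:
    """Split the apparent variance by rho and re-solve with fixed components.

    The apparent GBV term is replaced by two kinship-structured terms —
    the GBV main effect at ``rho * sigma2_g_tilde`` and a GBV-by-year
    effect at ``(1 - rho) * sigma2_g_tilde`` — sharing the same entry
    incidence matrix.  All variance components are held fixed at their
    prespecified values (a single pass of the mixed model equations, no
    REML update), and the GBLUPs of the main effect with their
    prediction-error matrix are returned for the simulation.
    """
    s2_tilde = apparent.vc["gbv"]
    adj = RhoAdjustment.from_rho(s2_tilde, rho)
    df = _with_nesting_labels(plots)
    terms = [RandomTerm("entry", kinship=K, name="gbv"),
             RandomTerm("entry", kinship=K, name="gbv_x_year")]
    components = {"gbv": adj.sigma2_g_adj, "gbv_x_year": adj.sigma2_gy_adj}
    for name in apparent.vc.names:
        if name == "gbv":
            continue
        components[name] = apparent.vc[name]
        if not name.startswith("residual"):
            terms.append(RandomTerm(tuple(name.split(":")), name=name))
    multi_loc = df["location"].nunique() > 1
    model = MixedModel(df, "yield", fixed=[], random=terms,
                       residual=Residual(groups="location") if multi_loc
                       else Residual())
    fit = model.solve(components)
    return CurrentYearResult(adj, fit)


def select_common_entries(plots: pd.DataFrame, cycle) -> pd.DataFrame:
    """GCA1+GCA2 records of one cycle restricted to entries tested in both."""
    df = plots.loc[~plots.get("is_check", pd.Series(False, index=plots.index))]
    df = df.loc[df["cycle"] == cycle]
    s1 = set(df.loc[df["stage"] == "GCA1", "entry"])
    s2 = set(df.loc[df["stage"] == "GCA2", "entry"])
    if not s1 or not s2:
        raise ValueError(f"cycle {cycle!r} lacks GCA1 or GCA2 records")
    common = s1 & s2
    if not common:
        raise ValueError(f"no entries common to GCA1 and GCA2 in cycle {cycle!r}")
    out = df.loc[df["stage"].isin(["GCA1", "GCA2"]) & df["entry"].isin(common)]
    return out.reset_index(drop=True)


def fit_gca2_cycle(plots: pd.DataFrame, K: KinshipMatrix,
                   year_effect: str = "random", **fit_kw) -> Stage2Result:
    """Single-stage two-year fit for the second-stage selection assessment.

    Nuisance design terms are nested within years with year-specific
    variances; the residual variance is year-location specific.  The GBV
    main effect (``K sigma2_g``) and GBV-by-year (block-diagonal
    ``K_j sigma2_gy``) have the same structures as the multi-year model.
    """
    if plots["year"].nunique() != 2:
        raise ValueError("the two-year workflow expects exactly two years")
    df = _with_nesting_labels(plots)
    df["year_location"] = df["year"].astype(str) + "/" + df["location"].astype(str)
    random = []
    fixed = []
    if year_effect == "random":
        random.append(RandomTerm("year", name="year"))
    else:
        fixed.append("year")
    random += [RandomTerm("entry", kinship=K, name="gbv"),
               RandomTerm("entry", kinship=K, kinship_by="year", name="gbv_x_year")]
    for t in _PLOT_TERMS:
        if t in ("tester", "entry:tester") and df["tester"].nunique() < 2:
            continue
        if t in ("location", "entry:location") and df["location"].nunique() < 2:
            continue
        if t == "trial" and df.groupby("year")["trial"].nunique().max() < 2:
            continue
        random.append(RandomTerm(tuple(t.split(":")), by="year", name=t))
    model = MixedModel(df, "yield", fixed=fixed, random=random,
                       residual=Residual(groups="year_location"))
    fit = model.fit(**fit_kw)
    s2g = fit.vc["gbv"]
    s2gy = fit.vc["gbv_x_year"]
    rho = rho_from_components(s2g, s2gy) if s2g + s2gy > 0 else np.nan
    se = None
    try:
        cov = fit.vc.covariance_block(["gbv", "gbv_x_year"])
        se = se_rho_delta(s2g, s2gy, cov)
    except (KeyError, ValueError):
        pass
    return Stage2Result(fit, s2g, s2gy, rho, se)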