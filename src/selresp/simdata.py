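"""Synthetic multi-environment-trial data for a testcross breeding program.

Emulates the data structure of a two-tester hybrid breeding program:
entries (testcrosses) evaluated in yield trials laid out as resolvable
incomplete-block designs (alpha-design-like: replicates subdivided into
random incomplete blocks) at several locations, over years, with
truncation selection between successive trial stages of a cycle
(first-, second- and third-year general combining ability trials,
GCA1-GCA3).

True genomic breeding values are marker-derived: ``u_g = Qc v`` with
``v ~ N(0, sigma2_g / c)`` under the VanRaden centring/scaling, so that
``var(u_g) = K sigma2_g`` exactly matches the GBLUP model assumption.
GBV-by-year effects are drawn ``MVN(0, K sigma2_gy)`` independently per
year.  Plot yields add iid Gaussian effects for year, location, tester,
entry-by-tester, entry-by-location, trial, replicate and incomplete
block, plus a location-specific residual.

The incomplete-block layout assigns plots to equally sized blocks at
random; true alpha-array construction is out of scope (block effects are
iid, so layout optimality does not change model correctness).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markers import KinshipMatrix, MarkerMatrix, impute_missing, vanraden_kinship

__all__ = ["SimConfig", "TruthRecord", "SimulatedData",
           "generate_markers", "generate_true_effects", "generate_phenotypes",
           "simulate_met", "simulate_program"]


@dataclass
class SimConfig:
    """Parameters of the synthetic breeding-program generator.

    Trait units are arbitrary yield units (think dt/ha); variances are in
    squared trait units.  Defaults mirror a hybrid rye-style testcross
    program: two testers, two replicates, alpha-design-like incomplete
    blocks, strong year effects, and genomic main-effect /
    genomic-by-year variances of roughly 2 : 1.4.
    """

    # population / program structure
    n_entries_per_cycle: tuple = (300, 90, 30)   # cohort sizes GCA1 -> GCA3
    n_cycles: int = 3
    n_years: int = 4            # years of the single-stage MET (simulate_met)
    n_locations: int = 4
    n_trials_per_location: int = 2   # entries split evenly across trials
    n_reps: int = 2
    n_blocks_per_rep: int = 10
    n_testers: int = 2
    n_checks: int = 0           # check entries present in every trial
    sparse_coverage: float = 1.0  # fraction of entries tested per location
    selection_fractions: tuple = (0.3, 1.0 / 3.0)  # GCA1->2, GCA2->3
    selection_criterion: str = "true_gbv"          # or "phenotype"

    # markers
    n_markers: int = 1000
    allele_freq_range: tuple = (0.05, 0.95)
    missing_rate: float = 0.0
    n_families: int | None = None  # entries per family share one parental gamete

    # variance components (trait units squared)
    mu: float = 100.0
    sigma2_g: float = 2.0
    sigma2_gy: float = 1.4
    sigma2_y: float = 20.0
    sigma2_l: float = 8.0
    sigma2_t: float = 0.5
    sigma2_gt: float = 0.2
    sigma2_gl: float = 0.4
    sigma2_ls: float = 1.0
    sigma2_lsr: float = 0.8
    sigma2_lsrb: float = 0.6
    residual_variances: tuple = (4.0, 5.5, 3.5, 6.0)  # cycled over locations

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_gy", "sigma2_y", "sigma2_l", "sigma2_t",
                     "sigma2_gt", "sigma2_gl", "sigma2_ls", "sigma2_lsr",
                     "sigma2_lsrb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v <= 0 for v in self.residual_variances):
            raise ValueError("residual variances must be positive")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must lie strictly inside (0, 1)")
        if not all(0.0 < f <= 1.0 for f in self.selection_fractions):
            raise ValueError("selection fractions must lie in (0, 1]")
        if not (0.0 < self.sparse_coverage <= 1.0):
            raise ValueError("sparse_coverage must lie in (0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    def residual_variance(self, loc_index: int) -> float:
        rv = self.residual_variances
        return float(rv[loc_index % len(rv)])

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class TruthRecord:
    """Simulated truth: GBVs, GBV-by-year effects and marker effects."""

    true_gbv: pd.Series                # indexed by entry
    true_gby: pd.DataFrame             # entries x years
    marker_effects: np.ndarray
    kinship: KinshipMatrix = field(repr=False, default=None)


@dataclass
class SimulatedData:
    """Bundle of one simulated dataset."""

    config: SimConfig
    markers: MarkerMatrix
    truth: TruthRecord
    plots: pd.DataFrame

    @property
    def kinship(self) -> KinshipMatrix:
        return self.truth.kinship


def _rng(config_or_seed) -> np.random.Generator:
    if isinstance(config_or_seed, np.random.Generator):
        return config_or_seed
    if isinstance(config_or_seed, SimConfig):
        return np.random.default_rng(config_or_seed.seed)
    return np.random.default_rng(config_or_seed)


def generate_markers(config: SimConfig, n_entries: int | None = None,
                     entry_ids=None, rng=None) -> MarkerMatrix:
    """Draw biallelic dosages per marker as Binomial(2, p_j), p_j ~ U(range).

    With ``n_families`` set, consecutive entries are grouped into families
    that share a common parental gamete per marker, which induces
    within-family kinship (and between-cohort relatedness when cohorts
    share families).
    """
    rng = _rng(rng if rng is not None else config)
    if entry_ids is None:
        n = n_entries if n_entries is not None else config.n_entries_per_cycle[0]
        entry_ids = [f"E{i + 1:04d}" for i in range(n)]
    n = len(entry_ids)
    if n < 2:
        raise ValueError("need at least two entries")
    p_markers = config.n_markers
    if p_markers < 1:
        raise ValueError("need at least one marker")
    p = rng.uniform(*config.allele_freq_range, size=p_markers)
    if config.n_families:
        fam = np.arange(n) * config.n_families // n
        shared = rng.binomial(1, p, size=(config.n_families, p_markers)).astype(float)
        own = rng.binomial(1, p, size=(n, p_markers)).astype(float)
        dos = shared[fam] + own
    else:
        dos = rng.binomial(2, p, size=(n, p_markers)).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dos.shape) < config.missing_rate
        dos[mask] = np.nan
    marker_ids = [f"M{j + 1:05d}" for j in range(p_markers)]
    return MarkerMatrix(entry_ids, dos, marker_ids)


def generate_true_effects(markers: MarkerMatrix, config: SimConfig,
                          years=None, rng=None) -> TruthRecord:
    """Marker-derived true GBVs and kinship-structured GBV-by-year effects.

    ``u_g = Qc v`` with ``v ~ N(0, sigma2_g / c)`` (VanRaden centring and
    scaling constant c), so ``var(u_g) = K sigma2_g``; per-year effects
    are ``MVN(0, K sigma2_gy)``, independent across years.
    """
    if markers.n_markers == 0:
        raise ValueError("no markers to derive genetic effects from")
    rng = _rng(rng if rng is not None else config)
    clean = impute_missing(markers) if np.isnan(markers.dosages).any() else markers
    K = vanraden_kinship(clean)
    p = clean.dosages.mean(axis=0) / 2.0
    c = 2.0 * float(np.sum(p * (1.0 - p)))
    qc = clean.dosages - 2.0 * p
    # draws are taken regardless of the variance and scaled by its square
    # root, so runs with matched seeds but different variances share the
    # same underlying random stream (zero variance still gives exact zeros)
    v = rng.standard_normal(markers.n_markers) * np.sqrt(config.sigma2_g / c)
    gbv = pd.Series(qc @ v, index=markers.entry_ids, name="true_gbv")

    if years is None:
        years = list(range(1, config.n_years + 1))
    L = K.factor()
    gby = {}
    for yr in years:
        gby[yr] = (L @ rng.standard_normal(L.shape[1])) * np.sqrt(config.sigma2_gy)
    gby_df = pd.DataFrame(gby, index=markers.entry_ids)
    return TruthRecord(gbv, gby_df, v, K)


def _year_layout(entries, year, stage, cycle, config: SimConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Plot rows for one cohort-year: locations x trials x reps x blocks."""
    entries = list(entries)
    rows = []
    n_trials = max(1, min(config.n_trials_per_location, len(entries)))
    for li in range(config.n_locations):
        loc = f"L{li + 1}"
        if config.sparse_coverage < 1.0:
            n_keep = max(2, int(round(config.sparse_coverage * len(entries))))
            loc_entries = list(rng.choice(entries, size=n_keep, replace=False))
        else:
            loc_entries = entries
        perm = rng.permutation(len(loc_entries))
        trial_of = np.array([i * n_trials // len(loc_entries) for i in range(len(loc_entries))])
        for ti in range(n_trials):
            trial_entries = [loc_entries[j] for j in perm[trial_of == ti]]
            if not trial_entries:
                continue
            trial = f"T{ti + 1}"
            plots = [(e, f"X{k + 1}") for e in trial_entries
                     for k in range(config.n_testers)]
            n_blocks = max(1, min(config.n_blocks_per_rep, len(plots)))
            for rep in range(1, config.n_reps + 1):
                order = rng.permutation(len(plots))
                for pos, pi in enumerate(order):
                    e, tester = plots[pi]
                    block = pos * n_blocks // len(plots) + 1
                    rows.append((cycle, stage, year, loc, trial, rep,
                                 f"B{block}", tester, e))
    return pd.DataFrame(rows, columns=["cycle", "stage", "year", "location",
                                       "trial", "rep", "block", "tester", "entry"])


def generate_phenotypes(truth: TruthRecord, config: SimConfig,
                        layout: pd.DataFrame | None = None,
                        check_entries=(), rng=None) -> pd.DataFrame:
    """Add plot yields to a trial layout.

    y = mu + year + location + tester + gbv + gby + entry.tester +
        entry.location + trial + rep + block + residual,
    with every nuisance effect iid Gaussian at its configured variance,
    drawn independently per year (trials are analyzed year-wise), and a
    location-specific residual standard deviation.
    """
    rng = _rng(rng if rng is not None else config)
    if layout is None:
        entries = list(truth.true_gbv.index)
        parts = [_year_layout(entries, yr, "GCA1", 1, config, rng)
                 for yr in truth.true_gby.columns]
        layout = pd.concat(parts, ignore_index=True)
    plots = layout.copy()

    def draw(var: float) -> float:
        return rng.standard_normal() * np.sqrt(var)

    gbv = truth.true_gbv
    y_out = np.empty(len(plots))
    eff_cache: dict[tuple, float] = {}

    def eff(kind, key, var):
        k = (kind, key)
        if k not in eff_cache:
            eff_cache[k] = draw(var)
        return eff_cache[k]

    loc_index = {loc: i for i, loc in
                 enumerate(sorted(plots["location"].unique()))}
    cols = plots[["year", "location", "trial", "rep", "block", "tester",
                  "entry"]].itertuples(index=False, name=None)
    for i, (yr, loc, trial, rep, block, tester, e) in enumerate(cols):
        val = config.mu
        val += eff("y", yr, config.sigma2_y)
        val += eff("l", (yr, loc), config.sigma2_l)
        val += eff("t", (yr, tester), config.sigma2_t)
        val += float(gbv.loc[e])
        val += float(truth.true_gby.loc[e, yr])
        val += eff("gt", (yr, e, tester), config.sigma2_gt)
        val += eff("gl", (yr, e, loc), config.sigma2_gl)
        val += eff("ls", (yr, loc, trial), config.sigma2_ls)
        val += eff("lsr", (yr, loc, trial, rep), config.sigma2_lsr)
        val += eff("lsrb", (yr, loc, trial, rep, block), config.sigma2_lsrb)
        val += rng.normal(0.0, np.sqrt(config.residual_variance(loc_index[loc])))
        y_out[i] = val
    plots["yield"] = y_out
    plots["is_check"] = plots["entry"].isin(set(check_entries))
    return plots


def simulate_met(config: SimConfig, years=None) -> SimulatedData:
    """One cohort tested every year: a fully connected multi-environment trial.

    This is the design used for parameter-recovery checks: the same
    entries appear in all years, so the genomic main-effect and
    genomic-by-year variances are well separated by the data themselves
    rather than only through cross-cohort kinship.
    """
    rng = _rng(config)
    n = config.n_entries_per_cycle[0]
    markers = generate_markers(config, n_entries=n + config.n_checks, rng=rng)
    if years is None:
        years = list(range(1, config.n_years + 1))
    truth = generate_true_effects(markers, config, years=years, rng=rng)
    checks = markers.entry_ids[n:]
    parts = [_year_layout(markers.entry_ids, yr, "GCA1", 1, config, rng)
             for yr in years]
    layout = pd.concat(parts, ignore_index=True)
    plots = generate_phenotypes(truth, config, layout=layout,
                                check_entries=checks, rng=rng)
    return SimulatedData(config, markers, truth, plots)


def _select(entries, truth: TruthRecord, plots: pd.DataFrame, fraction: float,
            criterion: str) -> list:
    n_keep = int(round(fraction * len(entries)))
    if n_keep < 2:
        raise ValueError("selection fraction leaves fewer than two entries")
    if criterion == "true_gbv":
        scores = truth.true_gbv.loc[entries]
    elif criterion == "phenotype":
        scores = (plots[plots["entry"].isin(entries)]
                  .groupby("entry")["yield"].mean().reindex(entries))
    else:
        raise ValueError(f"unknown selection criterion {criterion!r}")
    return list(scores.sort_values(ascending=False).index[:n_keep])


def simulate_program(config: SimConfig) -> SimulatedData:
    """Multi-cycle program: new GCA1 cohorts, truncation selection to GCA2/GCA3.

    Cycle c starts in year c; its GCA1/GCA2/GCA3 trials run in years c,
    c+1, c+2.  Selection between stages keeps the top fraction by the
    configured criterion (true GBV by default, so tests control truth).
    Entry counts therefore strictly decrease along a cycle.
    """
    rng = _rng(config)
    n1 = config.n_entries_per_cycle[0]
    cohorts = {c: [f"C{c}E{i + 1:04d}" for i in range(n1)]
               for c in range(1, config.n_cycles + 1)}
    checks = [f"CHK{i + 1}" for i in range(config.n_checks)]
    all_entries = [e for c in cohorts.values() for e in c] + checks
    markers = generate_markers(config, entry_ids=all_entries, rng=rng)
    n_years_total = config.n_cycles + len(config.n_entries_per_cycle) - 1
    years = list(range(1, n_years_total + 1))
    truth = generate_true_effects(markers, config, years=years, rng=rng)

    stage_names = [f"GCA{k + 1}" for k in range(len(config.n_entries_per_cycle))]
    frames = []
    for c in range(1, config.n_cycles + 1):
        entries = cohorts[c]
        for k, stage in enumerate(stage_names):
            year = c + k
            if year > years[-1]:
                break
            layout = _year_layout(entries + checks, year, stage, c, config, rng)
            stage_plots = generate_phenotypes(truth, config, layout=layout,
                                              check_entries=checks, rng=rng)
            frames.append(stage_plots)
            if k < len(config.selection_fractions):
                entries = _select(entries, truth, stage_plots,
                                  config.selection_fractions[k],
                                  config.selection_criterion)
    plots = pd.concat(frames, ignore_index=True)
    return SimulatedData(config, markers, truth, plots)
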