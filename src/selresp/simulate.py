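"""Monte-Carlo assessment of response to genomic selection.

The fitted mixed model gives, for the N candidate entries, the genomic
covariance ``D = K sigma2_g`` and the prediction-error variance matrix
``C = var(ghat - g)`` from the inverse coefficient matrix of the mixed
model equations.  The true breeding values g and their BLUPs ghat are
jointly multivariate normal with zero mean and covariance

    Omega = [[D, M],
             [M, M]],      M = var(ghat) = D - C.

Drawing ``w = Gamma z`` with ``Gamma Gamma' = Omega`` and z standard
normal simulates matched pairs (g, ghat).  For each replicate the top-n
entries by ghat are "selected"; the estimated probability that the
selection captures the m truly best entries (by g) is the proportion of
replicates where the top-m set under g is contained in the top-n set
under ghat.  Mean Pearson correlations of (g, ghat) and of their ranks
are accumulated alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import KinshipMatrix

__all__ = ["Omega", "OmegaFactor", "build_omega", "factor_omega",
           "simulate_draws", "selection_probabilities", "probability_report",
           "SelectionSimulator", "SelectionProbabilityTable"]


@dataclass
class Omega:
    """Joint covariance of (g, ghat) in block form."""

    entry_ids: list
    D: np.ndarray
    C: np.ndarray
    M: np.ndarray

    @property
    def n(self) -> int:
        return len(self.entry_ids)

    def full(self) -> np.ndarray:
        return np.block([[self.D, self.M], [self.M, self.M]])


@dataclass
class OmegaFactor(Omega):
    """Omega together with a factor Gamma, Gamma Gamma' = Omega."""

    gamma: np.ndarray = None
    method: str = ""
    clipped_eigenvalues: int = 0

    def reconstruction_error(self) -> float:
        om = self.full()
        err = np.abs(self.gamma @ self.gamma.T - om).max()
        return float(err / max(np.abs(om).max(), 1e-300))


def build_omega(K: KinshipMatrix, sigma2_g: float, C: pd.DataFrame | np.ndarray,
                entry_ids=None) -> Omega:
    """Assemble Omega from the kinship, genomic variance and PEV matrix.

    ``M = D - C`` is symmetrized; entries of C (when labelled) must match
    the kinship entries.
    """
    if sigma2_g <= 0:
        raise ValueError("sigma2_g must be positive")
    if isinstance(C, pd.DataFrame):
        ids = list(C.index)
        Kv = K.submatrix(ids).values if ids != K.entry_ids else K.values
        Cv = C.to_numpy(dtype=float)
    else:
        ids = entry_ids if entry_ids is not None else list(K.entry_ids)
        Kv = K.submatrix(ids).values if list(ids) != K.entry_ids else K.values
        Cv = np.asarray(C, dtype=float)
    if Cv.shape != Kv.shape:
        raise ValueError("C and K dimensions do not match")
    D = Kv * sigma2_g
    M = D - Cv
    M = 0.5 * (M + M.T)
    return Omega(ids, D, 0.5 * (Cv + Cv.T), M)


def factor_omega(omega: Omega, tol: float = 1e-8) -> OmegaFactor:
    """Factor Omega as Gamma Gamma'.

    Cholesky when Omega is positive-definite; otherwise eigendecompose,
    clip small negative eigenvalues (more negative than ``-tol *
    lambda_max`` is an error, indicating an invalid C) and keep the
    positive part.
    """
    om = omega.full()
    try:
        gamma = np.linalg.cholesky(om)
        method = "cholesky"
        clipped = 0
    except np.linalg.LinAlgError:
        w, u = np.linalg.eigh(om)
        lam_max = max(float(w.max()), 1e-300)
        if w.min() < -tol * lam_max:
            raise np.linalg.LinAlgError(
                f"Omega has eigenvalue {w.min():.3e} below -tol*lambda_max; "
                "the prediction-error matrix C is inconsistent with D")
        clipped = int((w < 0).sum())
        w = np.clip(w, 0.0, None)
        keep = w > 0
        gamma = u[:, keep] * np.sqrt(w[keep])
        method = "svd"
    return OmegaFactor(omega.entry_ids, omega.D, omega.C, omega.M,
                       gamma=gamma, method=method,
                       clipped_eigenvalues=clipped)


def simulate_draws(factor: OmegaFactor, S: int, seed: int, chunk: int = 2000):
    """Yield (g, ghat) arrays of shape (n_entries, chunk) from w = Gamma z.

    Streaming: at most ``chunk`` replicates are materialized at a time.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    rng = np.random.default_rng(seed)
    n = factor.n
    done = 0
    while done < S:
        m = min(chunk, S - done)
        z = rng.standard_normal((factor.gamma.shape[1], m))
        w = factor.gamma @ z
        yield w[:n], w[n:]
        done += m


@dataclass
class SelectionProbabilityTable:
    """Estimated selection-success probabilities and correlation summaries.

    ``table`` is long-format with columns (n, percent_selected, m,
    probability).  Success in one replicate means the ``m`` truly best
    entries (largest g) are all within the ``n`` top-ranked by ghat (or,
    with ``at_least=k``, that at least k of them are).
    """

    table: pd.DataFrame
    n_entries: int
    S: int
    seed: int
    corr_value: float
    corr_rank: float
    method: str = ""
    at_least: int | None = None

    def probability(self, n: int, m: int) -> float:
        row = self.table[(self.table["n"] == n) & (self.table["m"] == m)]
        if len(row) == 0:
            raise KeyError(f"no probability tabulated for n={n}, m={m}")
        return float(row["probability"].iloc[0])

    def mc_standard_error(self, n: int, m: int) -> float:
        p = self.probability(n, m)
        return float(np.sqrt(p * (1.0 - p) / self.S))

    def summary(self) -> str:
        lines = [
            f"Selection-response simulation: N={self.n_entries} entries, "
            f"S={self.S} replicates (seed {self.seed})",
            f"  mean corr(g, ghat):        {self.corr_value:.3f}",
            f"  mean rank correlation:     {self.corr_rank:.3f}",
            "  probability that the top-n by GBLUP contains the m truly best:",
        ]
        wide = self.table.pivot_table(index="percent_selected", columns="m",
                                      values="probability")
        pct = [p for p in (10, 20, 30, 50, 75, 100) if p in wide.index]
        lines.append(wide.loc[pct].to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, ax=None):
        """Line plot of probability vs percent selected, one curve per m."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for m, sub in self.table.groupby("m"):
            ax.plot(sub["percent_selected"], sub["probability"],
                    label=f"m = {m}")
        ax.set_xlabel("selected entries (% of N)")
        ax.set_ylabel("probability all m truly best are selected")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(frameon=False)
        return ax


def selection_probabilities(factor: OmegaFactor, S: int, seed: int,
                            n_grid=None, m_list=(1, 5, 10, 15, 20),
                            minimize: bool = False, at_least: int | None = None,
                            chunk: int = 2000) -> SelectionProbabilityTable:
    """Monte-Carlo selection probabilities over a grid of (n, m).

    ``n_grid`` defaults to 1%..100% of N in 1% steps (as counts, at least
    1).  ``m_list`` entries larger than N are dropped.  ``minimize``
    inverts the ranking for traits where small values are good.
    ``at_least=k`` relaxes success to capturing at least k of the m truly
    best; default requires all m.
    """
    n_entries = factor.n
    if n_entries < 2:
        raise ValueError("need at least two entries")
    m_list = sorted({int(m) for m in m_list if 1 <= m <= n_entries})
    if n_grid is None:
        pct = np.arange(1, 101)
        n_grid = sorted({max(1, int(round(p * n_entries / 100.0))) for p in pct})
    else:
        n_grid = sorted({int(n) for n in n_grid})
        if any(n < 1 or n > n_entries for n in n_grid):
            raise ValueError("n_grid values must lie in 1..N")
    max_m = max(m_list) if m_list else 0

    # For each replicate and each m, the statistic is the k-th smallest
    # ghat-rank among the m truly best by g (k = at_least or m); success
    # for a window n means that statistic is <= n.  Accumulate its
    # distribution, then read probabilities off the empirical CDF.
    stat_counts = {m: np.zeros(n_entries + 1, dtype=np.int64) for m in m_list}
    sum_corr = 0.0
    sum_rank_corr = 0.0
    for g, ghat in simulate_draws(factor, S, seed, chunk=chunk):
        if minimize:
            g, ghat = -g, -ghat
        s = g.shape[1]
        order_ghat = np.argsort(-ghat, axis=0, kind="stable")
        ranks = np.empty_like(order_ghat)
        cols = np.arange(s)[None, :]
        ranks[order_ghat, cols] = np.arange(1, n_entries + 1)[:, None]
        top_g = np.argsort(-g, axis=0, kind="stable")[:max_m]
        r_of_best = np.take_along_axis(ranks, top_g, axis=0)
        for m in m_list:
            k = m if at_least is None else min(at_least, m)
            if k == m:
                stat = r_of_best[:m].max(axis=0)
            else:
                stat = np.partition(r_of_best[:m], k - 1, axis=0)[k - 1]
            np.add.at(stat_counts[m], stat, 1)

        gc = g - g.mean(axis=0)
        hc = ghat - ghat.mean(axis=0)
        denom = np.sqrt((gc**2).sum(axis=0) * (hc**2).sum(axis=0))
        sum_corr += float(((gc * hc).sum(axis=0) / denom).sum())
        rg = np.argsort(np.argsort(g, axis=0, kind="stable"), axis=0).astype(float)
        rh = np.argsort(np.argsort(ghat, axis=0, kind="stable"), axis=0).astype(float)
        rgc = rg - rg.mean(axis=0)
        rhc = rh - rh.mean(axis=0)
        rden = np.sqrt((rgc**2).sum(axis=0) * (rhc**2).sum(axis=0))
        sum_rank_corr += float(((rgc * rhc).sum(axis=0) / rden).sum())

    rows = []
    for m in m_list:
        cdf = np.cumsum(stat_counts[m]) / float(S)
        for n in n_grid:
            p = cdf[n] if n >= (at_least or m) else 0.0
            rows.append((n, 100.0 * n / n_entries, m, float(p)))
    table = pd.DataFrame(rows, columns=["n", "percent_selected", "m", "probability"])
    return SelectionProbabilityTable(
        table=table, n_entries=n_entries, S=S, seed=seed,
        corr_value=sum_corr / S, corr_rank=sum_rank_corr / S,
        method=factor.method, at_least=at_least)


def probability_report(table: SelectionProbabilityTable, csv_path=None,
                       fig_path=None) -> pd.DataFrame:
    """Long-format report (percent_selected, m, probability); optional files."""
    out = table.table[["percent_selected", "m", "probability"]].copy()
    if csv_path is not None:
        out.to_csv(csv_path, index=False)
    if fig_path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        ax = table.plot()
        ax.figure.savefig(fig_path, dpi=120, bbox_inches="tight")
        import matplotlib.pyplot as plt
        plt.close(ax.figure)
    return out


class SelectionSimulator:
    """Convenience front-end: build Omega from a fit, factor it, simulate.

    Parameters
    ----------
    K : KinshipMatrix
    sigma2_g : float
        Genomic main-effect variance used for D = K sigma2_g.
    C : DataFrame
        Prediction-error matrix of the GBLUPs (labelled by entry).
    """

    def __init__(self, K: KinshipMatrix, sigma2_g: float, C: pd.DataFrame):
        self.omega = build_omega(K, sigma2_g, C)
        self.factor = factor_omega(self.omega)

    def run(self, S: int = 100_000, seed: int = 42, **kw) -> SelectionProbabilityTable:
        return selection_probabilities(self.factor, S, seed, **kw)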