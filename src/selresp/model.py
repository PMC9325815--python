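"""Linear mixed models for genomic prediction, statsmodels-style.

``MixedModel`` is built from a tidy data frame plus a model description
(fixed factors, random terms with iid or kinship-structured covariance,
and a residual structure).  ``fit()`` maximizes the residual likelihood
(REML) and returns a :class:`MixedModelResults` carrying fixed-effect
estimates (BLUEs), random-effect predictions (BLUPs), the prediction
error variance matrix ``C = var(ghat - g)`` for kinship terms, variance
components with their average-information covariance, and a ``summary()``
table.  ``solve()`` performs a single pass of Henderson's mixed model
equations at user-supplied (plug-in) variance components without
re-estimating anything, which is the "rerun with only one iteration"
contract used by the current-year adjustment.

Internals
---------
Every kinship-structured random effect ``u ~ N(0, K sigma2)`` is
reparameterized through an eigen-factor ``L`` with ``L L' = K`` as
``u = L a``, ``a ~ N(0, I sigma2)``.  This handles singular K without
forming ``K^{-1}`` and makes every G block in Henderson's equations a
multiple of the identity, so the coefficient matrix is

    C_coef = W' R^{-1} W + diag(0_p, 1/sigma2_k ...),   W = [X, Z L, ...]

REML quantities follow from the standard identities
``-2 l_R = log|R| + log|G| + log|C_coef| + y'Py + (n - p) log 2 pi`` and,
for each transformed term, ``tr(P Z_k Z_k') = (r_k sigma2_k -
tr(Cinv_kk)) / sigma2_k^2`` with ``Cinv`` the inverse coefficient matrix.
Estimation uses EM warm-start steps followed by average-information (AI)
updates with step halving and active-set handling of the zero boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.linalg import lapack

from .markers import KinshipMatrix
from .varcomp import VarianceComponents

__all__ = ["RandomTerm", "Residual", "MixedModel", "MixedModelResults", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message + "\n" + "\n".join(map(str, trace)))
        self.trace = trace


@dataclass
class RandomTerm:
    """One random term of the model.

    Parameters
    ----------
    factors : str or tuple of str
        Column(s) whose observed combinations define the effect levels.
    kinship : KinshipMatrix, optional
        Covariance ``K sigma2`` across the levels of a single factor whose
        values are entry ids of ``kinship``.
    by : str, optional
        Grouping column giving each group its own variance (iid terms
        only); used for year-nested effects with year-specific variances.
    kinship_by : str, optional
        Grouping column; the term covariance is block-diagonal over groups
        with blocks ``K_j sigma2`` (common variance), ``K_j`` the kinship
        sub-block of the entries observed in group j.  This is the
        GBV-by-year structure.
    name : str, optional
        Label for reports; defaults to the factor names joined by ':'.
    """

    factors: tuple
    kinship: KinshipMatrix | None = None
    by: str | None = None
    kinship_by: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.factors, str):
            self.factors = (self.factors,)
        else:
            self.factors = tuple(self.factors)
        if self.name is None:
            self.name = ":".join(self.factors)
        if self.kinship is not None and len(self.factors) != 1:
            raise ValueError("kinship terms must have a single factor (the entry column)")
        if self.by is not None and (self.kinship is not None or self.kinship_by):
            raise ValueError("'by' (group-specific variances) applies to iid terms only")
        if self.kinship_by is not None and self.kinship is None:
            raise ValueError("kinship_by requires a kinship matrix")


@dataclass
class Residual:
    """Residual structure: homogeneous, group-specific diagonal, or fixed weights.

    ``groups`` names a column whose levels get separate residual variances
    (e.g. location, or a year-location composite).  ``weights`` names a
    column of known precisions w_i, giving the fixed plug-in residual
    ``R = diag(1 / w_i)`` with no free parameter (Smith weighting).
    """

    groups: str | None = None
    weights: str | None = None

    def __post_init__(self) -> None:
        if self.groups is not None and self.weights is not None:
            raise ValueError("residual structure is either grouped or fixed-weight, not both")


@dataclass
class _ParamBlock:
    name: str
    sl: slice              # columns of W
    r: int                 # number of (transformed) columns
    kind: str              # "iid" | "kinship"
    levels: list           # original effect level labels
    L: np.ndarray | None   # back-transform for kinship blocks (n_levels x r)
    term: str              # parent term name
    subs: list | None = None  # [(local_slice, L_g, levels_g)] for block-diagonal kinship


@dataclass
class _Eval:
    theta: np.ndarray
    neg2ll: float
    b: np.ndarray
    cinv: np.ndarray
    cf: np.ndarray                # Cholesky factor of the coefficient matrix
    resid: np.ndarray
    scores: np.ndarray            # d(-2 l)/d sigma2, all params (NaN for weight-fixed)
    term_uu: np.ndarray
    term_tr: np.ndarray


def _combo_codes(data: pd.DataFrame, factors: tuple) -> tuple[np.ndarray, list]:
    if len(factors) == 1:
        codes, levels = pd.factorize(data[factors[0]], sort=True)
        return codes, list(levels)
    keys = pd.MultiIndex.from_frame(data[list(factors)].astype(str))
    codes, levels = pd.factorize(keys, sort=True)
    return codes, ["/".join(map(str, lv)) for lv in levels]


class MixedModel:
    """Gaussian linear mixed model with iid and kinship-structured random terms.

    Parameters
    ----------
    data : DataFrame
        One row per observation; factor columns plus the response.
    response : str
        Response column (e.g. plot yield or an adjusted entry mean).
    fixed : sequence of str
        Fixed-effect factor columns (treatment coding, intercept always
        included).  Aliased columns are dropped deterministically in
        column order and recorded on the results object.
    random : sequence of RandomTerm
    residual : Residual
    """

    def __init__(self, data: pd.DataFrame, response: str, fixed=(), random=(),
                 residual: Residual | None = None):
        self.data = data.loc[data[response].notna()].reset_index(drop=True)
        if len(self.data) == 0:
            raise ValueError("no non-missing observations")
        self.response = response
        self.fixed = list(fixed)
        self.random = list(random)
        self.residual = residual or Residual()
        self._build()

    # ---------------------------------------------------------------- build
    def _build(self) -> None:
        data = self.data
        n = len(data)
        self.y = data[self.response].to_numpy(dtype=float)

        # fixed part: intercept + treatment-coded dummies
        x_cols = [np.ones(n)]
        x_names = ["(Intercept)"]
        for fac in self.fixed:
            codes, levels = _combo_codes(data, (fac,))
            if (codes < 0).any():
                raise ValueError(f"missing values in fixed factor {fac!r}")
            for j, lev in enumerate(levels[1:], start=1):
                x_cols.append((codes == j).astype(float))
                x_names.append(f"{fac}[{lev}]")
        X = np.column_stack(x_cols)

        # deterministic alias handling: greedy rank check in column order
        q, r, piv = sla.qr(X, mode="economic", pivoting=True)
        tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        rank = int((np.abs(np.diag(r)) > tol).sum())
        if rank == 0:
            raise ValueError("fixed-effect design has rank 0")
        self.dropped_fixed: list[str] = []
        if rank < X.shape[1]:
            keep_mask = np.zeros(X.shape[1], dtype=bool)
            basis = np.empty((n, 0))
            for j in range(X.shape[1]):
                cand = np.column_stack([basis, X[:, j]])
                if np.linalg.matrix_rank(cand, tol=tol) > basis.shape[1]:
                    keep_mask[j] = True
                    basis = cand
            self.dropped_fixed = [nm for nm, k in zip(x_names, keep_mask) if not k]
            X = X[:, keep_mask]
            x_names = [nm for nm, k in zip(x_names, keep_mask) if k]
        self.x_names = x_names
        self.p = X.shape[1]

        # random part: expand terms into parameter blocks of transformed columns
        blocks: list[_ParamBlock] = []
        w_parts: list[np.ndarray] = [X]
        offset = self.p
        seen = set()
        for term in self.random:
            if term.name in seen:
                raise ValueError(f"duplicate random term name {term.name!r}")
            seen.add(term.name)
            for blk_name, cols, kind, levels, L, subs in self._expand_term(term):
                r_k = cols.shape[1]
                if r_k == 0:
                    raise ValueError(f"random term {blk_name!r} has no levels")
                blocks.append(_ParamBlock(blk_name, slice(offset, offset + r_k),
                                          r_k, kind, levels, L, term.name, subs))
                w_parts.append(cols)
                offset += r_k
        self.blocks = blocks
        self.W = np.ascontiguousarray(np.column_stack(w_parts)) if len(w_parts) > 1 else X
        self.d = self.W.shape[1]

        # map parent term -> list of its parameter blocks (by-groups expand)
        self.term_blocks: dict[str, list[_ParamBlock]] = {}
        for blk in blocks:
            self.term_blocks.setdefault(blk.term, []).append(blk)

        # residual structure
        res = self.residual
        if res.weights is not None:
            w = data[res.weights].to_numpy(dtype=float)
            if (w <= 0).any():
                raise ValueError("residual weights must be positive")
            self.res_groups: list[tuple[str, np.ndarray]] = []
            self.res_w = w
            self.const_logdet_r = -float(np.log(w).sum())
        else:
            self.res_w = None
            self.const_logdet_r = 0.0
            if res.groups is None:
                self.res_groups = [("residual", np.arange(n))]
            else:
                codes, levels = _combo_codes(data, (res.groups,))
                self.res_groups = [(f"residual[{lev}]", np.flatnonzero(codes == j))
                                   for j, lev in enumerate(levels)]

        # parameter naming: term blocks first, then residual groups
        self.param_names = [b.name for b in blocks] + [g for g, _ in self.res_groups]
        self.n_term_params = len(blocks)

        # precompute per-residual-group cross-products
        self._A: list[np.ndarray] = []
        self._a: list[np.ndarray] = []
        self._s: list[float] = []
        self._ng: list[int] = []
        if self.res_w is not None:
            sw = np.sqrt(self.res_w)
            Ws = self.W * sw[:, None]
            self._A.append(Ws.T @ Ws)
            self._a.append(self.W.T @ (self.res_w * self.y))
            self._s.append(float(self.y @ (self.res_w * self.y)))
            self._ng.append(n)
        else:
            for _, rows in self.res_groups:
                Wg = self.W[rows]
                self._A.append(Wg.T @ Wg)
                self._a.append(Wg.T @ self.y[rows])
                self._s.append(float(self.y[rows] @ self.y[rows]))
                self._ng.append(len(rows))
        self.n = n

    def _expand_term(self, term: RandomTerm):
        """Yield (name, columns, kind, level_labels, L, subs) parameter blocks.

        A term usually maps to one variance parameter.  ``by`` terms expand
        into one parameter per group (group-specific variances), while
        ``kinship_by`` terms stay a single parameter whose covariance is
        block-diagonal over groups (``subs`` records the per-group factors
        for the back-transform to the original effect scale).
        """
        data = self.data
        n = len(data)
        if term.kinship is not None and term.kinship_by is None:
            K = term.kinship
            fac = term.factors[0]
            observed = pd.unique(data[fac])
            order = [e for e in K.entry_ids if e in set(observed)]
            if len(order) != len(observed):
                missing = sorted(set(observed) - set(K.entry_ids))[:5]
                raise KeyError(f"entries absent from kinship matrix for term "
                               f"{term.name!r}: {missing} ...")
            L = K.factor(tuple(order))
            pos = {e: i for i, e in enumerate(order)}
            row_idx = data[fac].map(pos).to_numpy()
            yield term.name, L[row_idx, :], "kinship", order, L, None
        elif term.kinship_by is not None:
            K = term.kinship
            fac = term.factors[0]
            gcodes, glevels = _combo_codes(data, (term.kinship_by,))
            col_parts, subs, levels = [], [], []
            off = 0
            for j, glev in enumerate(glevels):
                rows = np.flatnonzero(gcodes == j)
                observed = set(pd.unique(data[fac].iloc[rows]))
                order = [e for e in K.entry_ids if e in observed]
                L = K.factor(tuple(order))
                pos = {e: i for i, e in enumerate(order)}
                cols = np.zeros((n, L.shape[1]))
                cols[rows] = L[data[fac].iloc[rows].map(pos).to_numpy(), :]
                col_parts.append(cols)
                lev_g = [(e, glev) for e in order]
                subs.append((slice(off, off + L.shape[1]), L, lev_g))
                levels.extend(lev_g)
                off += L.shape[1]
            yield term.name, np.column_stack(col_parts), "kinship", levels, None, subs
        elif term.by is not None:
            gcodes, glevels = _combo_codes(data, (term.by,))
            codes, levels = _combo_codes(data, term.factors)
            for j, glev in enumerate(glevels):
                rows = np.flatnonzero(gcodes == j)
                sub_levels = np.unique(codes[rows])
                remap = {lv: i for i, lv in enumerate(sub_levels)}
                cols = np.zeros((n, len(sub_levels)))
                cols[rows, [remap[c] for c in codes[rows]]] = 1.0
                yield (f"{term.name}({glev})", cols, "iid",
                       [levels[lv] for lv in sub_levels], None, None)
        else:
            codes, levels = _combo_codes(data, term.factors)
            cols = np.zeros((n, len(levels)))
            cols[np.arange(n), codes] = 1.0
            yield term.name, cols, "iid", levels, None, None

    # ------------------------------------------------------------- numerics
    def _theta_split(self, theta: np.ndarray):
        return theta[: self.n_term_params], theta[self.n_term_params:]

    def _coef_pieces(self, theta: np.ndarray):
        t_theta, r_theta = self._theta_split(theta)
        if self.res_w is not None:
            cg = np.array([1.0])
        else:
            cg = 1.0 / r_theta
        C = np.zeros((self.d, self.d))
        rhs = np.zeros(self.d)
        for Ag, ag, c in zip(self._A, self._a, cg):
            C += c * Ag
            rhs += c * ag
        dvec = np.zeros(self.d)
        for blk, s2 in zip(self.blocks, t_theta):
            dvec[blk.sl] = 1.0 / s2
        C[np.diag_indices_from(C)] += dvec
        return C, rhs, cg

    def _evaluate(self, theta: np.ndarray, want_grad: bool = True) -> _Eval:
        t_theta, r_theta = self._theta_split(theta)
        C, rhs, cg = self._coef_pieces(theta)
        cf, info = lapack.dpotrf(C, lower=1, overwrite_a=1)
        if info != 0:
            raise np.linalg.LinAlgError(
                "singular mixed-model coefficient matrix; check for confounded "
                f"terms among {self.param_names}")
        logdet_c = 2.0 * float(np.log(np.diag(cf)).sum())
        b, _ = lapack.dpotrs(cf, rhs, lower=1)
        ypy = float(sum(s * c for s, c in zip(self._s, cg))) - float(b @ rhs)
        logdet_r = self.const_logdet_r
        if self.res_w is None:
            logdet_r += float(np.dot(self._ng, np.log(r_theta)))
        logdet_g = float(sum(blk.r * np.log(s2) for blk, s2 in zip(self.blocks, t_theta)))
        neg2ll = logdet_r + logdet_g + logdet_c + ypy + (self.n - self.p) * np.log(2.0 * np.pi)

        cinv = None
        scores = np.full(len(theta), np.nan)
        term_uu = np.zeros(self.n_term_params)
        term_tr = np.zeros(self.n_term_params)
        resid = self.y - self.W @ b
        if want_grad:
            ci, info = lapack.dpotri(cf, lower=1)
            if info != 0:
                raise np.linalg.LinAlgError("failed to invert coefficient matrix")
            cinv = np.tril(ci) + np.tril(ci, -1).T
            for k, (blk, s2) in enumerate(zip(self.blocks, t_theta)):
                u = b[blk.sl]
                term_uu[k] = float(u @ u)
                term_tr[k] = float(np.trace(cinv[blk.sl, blk.sl]))
                scores[k] = (blk.r * s2 - term_tr[k] - term_uu[k]) / s2**2
            if self.res_w is None:
                for g, (Ag, ag, sg, ng, s2) in enumerate(
                        zip(self._A, self._a, self._s, self._ng, r_theta)):
                    tr_ca = float(np.sum(cinv * Ag))
                    ee = sg - 2.0 * float(b @ ag) + float(b @ (Ag @ b))
                    scores[self.n_term_params + g] = (ng * s2 - tr_ca - ee) / s2**2
        return _Eval(theta.copy(), neg2ll, b, cinv, cf, resid, scores, term_uu, term_tr)

    def _rinv_vector(self, theta: np.ndarray) -> np.ndarray:
        if self.res_w is not None:
            return self.res_w
        _, r_theta = self._theta_split(theta)
        rinv = np.empty(self.n)
        for (_, rows), s2 in zip(self.res_groups, r_theta):
            rinv[rows] = 1.0 / s2
        return rinv

    def _ai_matrix(self, ev: _Eval, free_idx: np.ndarray) -> np.ndarray:
        """Average-information matrix for the free parameters at ev.theta."""
        t_theta, _ = self._theta_split(ev.theta)
        rinv = self._rinv_vector(ev.theta)
        h = rinv * ev.resid  # P y
        cf = ev.cf

        fvecs = []
        for idx in free_idx:
            if idx < self.n_term_params:
                blk = self.blocks[idx]
                f = self.W[:, blk.sl] @ (ev.b[blk.sl] / t_theta[idx])
            else:
                _, rows = self.res_groups[idx - self.n_term_params]
                f = np.zeros(self.n)
                f[rows] = h[rows]
            fvecs.append(f)
        F = np.column_stack(fvecs) if fvecs else np.empty((self.n, 0))
        RF = rinv[:, None] * F
        U = self.W.T @ RF
        V, _ = lapack.dpotrs(cf, U, lower=1)
        PF = RF - rinv[:, None] * (self.W @ V)
        return 0.5 * (F.T @ PF)

    # ------------------------------------------------------------ fit/solve
    def fit(self, start: dict | None = None, fix: dict | None = None,
            method: str = "ai", maxiter: int = 200, tol: float = 1e-6,
            gtol: float = 1e-4) -> "MixedModelResults":
        """Estimate variance components by REML and solve the MME.

        Parameters
        ----------
        start : dict, optional
            Starting values per parameter name.
        fix : dict, optional
            Components held fixed at the given values (not estimated).
        method : {"ai", "em"}
            AI-REML with EM warm start (default) or pure EM.
        tol : float
            Convergence threshold on the change in -2 log REML-likelihood.
        gtol : float
            Threshold on the max absolute gradient of the log-likelihood
            with respect to log-variances.
        """
        fix = dict(fix or {})
        unknown = set(fix) - set(self.param_names)
        if unknown:
            raise KeyError(f"unknown components in fix: {sorted(unknown)}")
        var_y = float(np.var(self.y)) or 1.0
        lb = 1e-10 * var_y

        theta = self._start_values(var_y)
        for name, val in (start or {}).items():
            theta[self.param_names.index(name)] = max(float(val), lb)
        fixed_idx = np.array([self.param_names.index(k) for k in fix], dtype=int)
        for i, k in zip(fixed_idx, fix):
            theta[i] = max(float(fix[k]), 0.0)
            if theta[i] == 0.0:
                theta[i] = lb  # exact zeros enter through the bound
        free_mask = np.ones(len(theta), dtype=bool)
        free_mask[fixed_idx] = False

        if not free_mask.any():
            ev = self._evaluate(theta)
            return self._results(ev, fix, pinned=set(), converged=True, n_iter=0,
                                 ai_inv=None, lb=lb)

        pinned: set[int] = set()
        trace: list[tuple] = []
        ev = self._evaluate(theta)
        converged = False
        dll = np.inf
        for it in range(1, maxiter + 1):
            act = np.array([i for i in range(len(theta))
                            if free_mask[i] and i not in pinned], dtype=int)
            if act.size == 0:
                converged = True
                break
            new_theta = None
            new_ev = None
            if method != "em" and it > 2:
                ai = self._ai_matrix(ev, act)
                grad = -0.5 * ev.scores[act]
                try:
                    ridge = 1e-12 * max(float(np.abs(ai).max()), 1.0)
                    delta = np.linalg.solve(ai + ridge * np.eye(len(act)), grad)
                except np.linalg.LinAlgError:
                    delta = None
                if delta is not None:
                    step = 1.0
                    for _ in range(10):
                        cand = theta.copy()
                        cand[act] = np.maximum(theta[act] + step * delta, lb)
                        try:
                            cand_ev = self._evaluate(cand)
                        except np.linalg.LinAlgError:
                            step *= 0.5
                            continue
                        if cand_ev.neg2ll <= ev.neg2ll + 1e-9:
                            new_theta, new_ev = cand, cand_ev
                            break
                        step *= 0.5
            if new_theta is None:  # EM warm start, pure EM, or AI fallback
                new_theta = theta.copy()
                new_theta[act] = self._em_step(ev, act)
                new_theta = np.maximum(new_theta, lb)
                new_ev = self._evaluate(new_theta)

            # pin parameters collapsing to the boundary; release if score pulls up
            repin = False
            for i in act:
                if new_theta[i] < 1e-6 * var_y and new_theta[i] <= theta[i]:
                    pinned.add(i)
                    new_theta[i] = lb
                    repin = True
            if repin:
                new_ev = self._evaluate(new_theta)
            for i in sorted(pinned):
                if -0.5 * new_ev.scores[i] > 0:  # likelihood increases off the bound
                    pinned.discard(i)

            dll = ev.neg2ll - new_ev.neg2ll
            theta, ev = new_theta, new_ev
            act = np.array([i for i in range(len(theta))
                            if free_mask[i] and i not in pinned], dtype=int)
            gmax = float(np.max(np.abs(-0.5 * ev.scores[act] * theta[act]))) \
                if act.size else 0.0
            trace.append((it, float(ev.neg2ll), float(dll), gmax))
            if it > 2 and abs(dll) < tol and (gmax < gtol or abs(dll) < 1e-10):
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"REML did not converge in {maxiter} iterations "
                f"(last |d(-2ll)| = {abs(dll):.3g})", trace)

        act = np.array([i for i in range(len(theta))
                        if free_mask[i] and i not in pinned], dtype=int)
        ai_inv = None
        if act.size:
            ai = self._ai_matrix(ev, act)
            try:
                ai_inv = (act, np.linalg.inv(ai))
            except np.linalg.LinAlgError:
                ai_inv = None
        return self._results(ev, fix, pinned={self.param_names[i] for i in pinned},
                             converged=True, n_iter=it, ai_inv=ai_inv, lb=lb)

    def solve(self, components: dict) -> "MixedModelResults":
        """Single MME solve at fully specified plug-in variance components."""
        missing = set(self.param_names) - set(components)
        if missing:
            raise KeyError(f"missing components for solve(): {sorted(missing)}")
        return self.fit(fix={k: components[k] for k in self.param_names})

    def _start_values(self, var_y: float) -> np.ndarray:
        n_parts = self.n_term_params + (len(self.res_groups) if self.res_w is None else 0)
        n_parts = max(n_parts, 1)
        theta = np.empty(len(self.param_names))
        for k, blk in enumerate(self.blocks):
            lev = float(np.mean(np.einsum("ij,ij->i", self.W[:, blk.sl], self.W[:, blk.sl])))
            theta[k] = var_y / n_parts / max(lev, 1e-8)
        theta[self.n_term_params:] = var_y / n_parts if self.res_w is None else 0.0
        return theta[: len(self.param_names)]

    def _em_step(self, ev: _Eval, act: np.ndarray) -> np.ndarray:
        out = np.empty(len(act))
        for j, i in enumerate(act):
            if i < self.n_term_params:
                blk = self.blocks[i]
                out[j] = (ev.term_uu[i] + ev.term_tr[i]) / blk.r
            else:
                g = i - self.n_term_params
                Ag, ag, sg, ng = self._A[g], self._a[g], self._s[g], self._ng[g]
                tr_ca = float(np.sum(ev.cinv * Ag))
                ee = sg - 2.0 * float(ev.b @ ag) + float(ev.b @ (Ag @ ev.b))
                out[j] = (ee + tr_ca) / ng
        return out

    def _results(self, ev: _Eval, fix: dict, pinned: set, converged: bool,
                 n_iter: int, ai_inv, lb: float) -> "MixedModelResults":
        names = self.param_names
        se = np.full(len(names), np.nan)
        ai_df = None
        if ai_inv is not None:
            act, inv = ai_inv
            act_names = [names[i] for i in act]
            se[act] = np.sqrt(np.maximum(np.diag(inv), 0.0))
            ai_df = pd.DataFrame(inv, index=act_names, columns=act_names)
        boundary = set(pinned) | {nm for nm, v in zip(names, ev.theta)
                                  if v <= lb * 10 and nm not in fix}
        vc = VarianceComponents(
            names=list(names),
            values=np.where(ev.theta <= lb * 2, 0.0, ev.theta),
            std_errors=se,
            ai_inverse=ai_df,
            fixed=set(fix),
            boundary=boundary,
        )
        return MixedModelResults(self, ev, vc, converged, n_iter)


class MixedModelResults:
    """Fitted mixed model: BLUEs, BLUPs, PEV matrices, components, REML loglik."""

    def __init__(self, model: MixedModel, ev: _Eval, vc: VarianceComponents,
                 converged: bool, n_iter: int):
        self.model = model
        self._ev = ev
        self.vc = vc
        self.converged = converged
        self.n_iter = n_iter
        self.llf = -0.5 * ev.neg2ll
        self.fe_params = pd.Series(ev.b[: model.p], index=model.x_names)
        if ev.cinv is None:
            ev2 = model._evaluate(ev.theta, want_grad=True)
            self._ev = ev = ev2
        self.fe_cov = pd.DataFrame(ev.cinv[: model.p, : model.p],
                                   index=model.x_names, columns=model.x_names)

    # ------------------------------------------------------------ accessors
    @property
    def neg2llf(self) -> float:
        return self._ev.neg2ll

    def components(self) -> pd.DataFrame:
        return self.vc.as_frame()

    def blups(self, term: str) -> pd.Series:
        """BLUPs of a random term on the original effect scale."""
        blks = self.model.term_blocks.get(term)
        if blks is None:
            raise KeyError(f"unknown random term {term!r}")
        pieces = []
        for blk in blks:
            a = self._ev.b[blk.sl]
            if blk.subs is not None:
                vals = np.concatenate([Lg @ a[sl] for sl, Lg, _ in blk.subs])
            elif blk.L is not None:
                vals = blk.L @ a
            else:
                vals = a
            if blk.levels and isinstance(blk.levels[0], tuple):
                idx = pd.MultiIndex.from_tuples(blk.levels)
            else:
                idx = pd.Index(blk.levels)
            pieces.append(pd.Series(vals, index=idx))
        return pd.concat(pieces) if len(pieces) > 1 else pieces[0]

    def prediction_error_matrix(self, term: str) -> pd.DataFrame:
        """C = var(ghat - g) for a random term (full matrix, original scale).

        For a kinship term this is ``L Cinv_kk L'`` with ``Cinv_kk`` the
        term block of the inverse MME coefficient matrix; needed to build
        the joint covariance of (g, ghat) for the selection simulation.
        """
        blks = self.model.term_blocks.get(term)
        if blks is None:
            raise KeyError(f"unknown random term {term!r}")
        if len(blks) != 1:
            raise ValueError("prediction_error_matrix is defined per parameter block; "
                             f"term {term!r} expands to {[b.name for b in blks]}")
        blk = blks[0]
        cb = self._ev.cinv[blk.sl, blk.sl]
        if blk.subs is not None:
            lbd = np.zeros((len(blk.levels), blk.r))
            row = 0
            for sl, Lg, lev_g in blk.subs:
                lbd[row: row + len(lev_g), sl] = Lg
                row += len(lev_g)
            cb = lbd @ cb @ lbd.T
        elif blk.L is not None:
            cb = blk.L @ cb @ blk.L.T
        if blk.levels and isinstance(blk.levels[0], tuple):
            idx = pd.MultiIndex.from_tuples(blk.levels)
        else:
            idx = pd.Index(blk.levels)
        return pd.DataFrame(0.5 * (cb + cb.T), index=idx, columns=idx)

    def fitted_values(self) -> np.ndarray:
        return self.model.y - self._ev.resid

    @property
    def resid(self) -> np.ndarray:
        return self._ev.resid

    def mme_residual(self) -> float:
        """Relative residual of the mixed-model normal equations at the solution."""
        C, rhs, _ = self.model._coef_pieces(self._ev.theta)
        r = C @ self._ev.b - rhs
        return float(np.linalg.norm(r) / max(np.linalg.norm(rhs), 1e-300))

    def summary(self) -> str:
        lines = [
            "Mixed model (REML)",
            f"  observations: {self.model.n}   fixed-effect columns: {self.model.p}",
            f"  log REML-likelihood: {self.llf:.4f}   "
            f"converged: {self.converged} ({self.n_iter} iterations)",
        ]
        if self.model.dropped_fixed:
            lines.append(f"  aliased fixed columns dropped: {self.model.dropped_fixed}")
        lines.append("\nVariance components:")
        lines.append(self.components().to_string(float_format=lambda v: f"{v:.6g}"))
        fe = pd.DataFrame({"estimate": self.fe_params,
                           "se": np.sqrt(np.diag(self.fe_cov))})
        head = fe if len(fe) <= 12 else fe.head(12)
        lines.append("\nFixed effects:" + ("" if len(fe) <= 12 else " (first 12)"))
        lines.append(head.to_string(float_format=lambda v: f"{v:.6g}"))
        return "\n".join(lines)
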