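"""Henderson mixed-model equations and EM-REML variance-component estimation.

The models handled here all have the form

    y = X b + sum_u Z_u u_u + e,      u_u ~ N(0, s2_u I),   e ~ N(0, s2 I)

with a dense full-rank fixed-effects design ``X`` and sparse incidence
matrices ``Z_u`` for each random term (combining abilities, their
environment interactions, or per-allele marker effects).  Solving the
mixed-model equations with the variance ratios ``lambda_u = s2 / s2_u`` on
the random diagonal blocks yields generalized-least-squares fixed-effect
estimates and ridge-type BLUPs of the random effects.

Variance components are estimated by restricted maximum likelihood via the
classical expectation-maximization iteration

    s2_u <- (u_u' u_u + s2 * trace(C^{uu})) / q_u
    s2   <- y'(y - X b - sum_u Z_u u_u) / (N - rank(X))

where ``C^{uu}`` is the u-th diagonal block of the inverse mixed-model
coefficient matrix.  The restricted log-likelihood is evaluated at every
iterate and is non-decreasing along the EM path, which the implementation
verifies as a self-check.

Two algebraically equivalent solver backends are provided:

* ``direct`` absorbs the fixed effects once and factorizes the (q x q)
  absorbed random-effects system ``Z'MZ + diag(lambda)`` per iteration,
  reading the ``C^{uu}`` traces off its inverse;
* ``cells`` exploits that in field-trial models every random design is
  constant within (hybrid, environment) cells, so the phenotypic
  covariance is ``V = s2 I + P H P'`` with a cell incidence ``P`` and a
  (C x C) cell covariance ``H``.  Woodbury identities then give all MME
  solutions, block traces and the restricted likelihood from (C x C)
  factorizations, which is decisively cheaper whenever the number of
  cells is small relative to the number of random effects (marker models:
  C = number of hybrids, q = number of allele columns).

``method="auto"`` picks between them; both produce identical results to
numerical precision, which the test suite verifies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.linalg.lapack import dpotri

logger = logging.getLogger(__name__)

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "VarianceComponents",
    "MixedModelFit",
    "full_rank_columns",
    "solve_mme",
    "reml_em",
]


@dataclass
class RandomTerm:
    """One random term: label, N x q incidence matrix, and level keys."""

    label: str
    Z: sp.spmatrix
    levels: list

    def __post_init__(self):
        self.Z = sp.csr_matrix(self.Z).astype(float)
        if self.Z.shape[1] != len(self.levels):
            raise ValueError(
                f"term {self.label!r}: {self.Z.shape[1]} columns "
                f"but {len(self.levels)} level keys"
            )

    @property
    def n_levels(self) -> int:
        return self.Z.shape[1]


@dataclass
class ModelSpec:
    """Response, full-rank fixed design, and the list of random terms."""

    y: np.ndarray
    X: np.ndarray
    terms: list[RandomTerm]
    x_columns: list[str] | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise ValueError("X and y have different numbers of rows")
        for t in self.terms:
            if t.Z.shape[0] != n:
                raise ValueError(f"random term {t.label!r} has wrong row count")
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite values in y or X")
        if self.x_columns is None:
            self.x_columns = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def term_labels(self) -> list[str]:
        return [t.label for t in self.terms]


@dataclass
class VarianceComponents:
    """One variance per random term plus the residual, in t2.ha-2."""

    by_term: dict[str, float]
    residual: float

    def __post_init__(self):
        for k, v in self.by_term.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"invalid variance for term {k!r}: {v}")
        if not np.isfinite(self.residual) or self.residual <= 0:
            raise ValueError("residual variance must be strictly positive")

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(dict(self.by_term), self.residual)

    def as_dict(self) -> dict[str, float]:
        d = dict(self.by_term)
        d["residual"] = self.residual
        return d


@dataclass
class MixedModelFit:
    """Solutions, inverse-coefficient-matrix blocks, and the REML trail."""

    spec: ModelSpec
    components: VarianceComponents
    beta: np.ndarray
    effects: dict[str, np.ndarray]
    inv_block_trace: dict[str, float]
    inv_blocks: dict[str, np.ndarray]
    loglik_path: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    at_floor: dict[str, bool] = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1] if self.loglik_path else math.nan

    def fitted_fixed(self) -> np.ndarray:
        return self.spec.X @ self.beta

    def fitted_random(self) -> np.ndarray:
        out = np.zeros(self.spec.n_obs)
        for t in self.spec.terms:
            out += t.Z @ self.effects[t.label]
        return out

    def residuals(self) -> np.ndarray:
        return self.spec.y - self.fitted_fixed() - self.fitted_random()


def full_rank_columns(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a greedy full-rank subset of columns, in the given order.

    Columns are scanned left to right and a column is dropped when it is
    (numerically) in the span of the columns already kept, so the caller
    controls which factor loses levels by ordering the design columns.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
            # one re-orthogonalization pass for numerical safety
            resid -= basis @ (basis.T @ resid)
        else:
            resid = col.astype(float).copy()
        nrm = np.linalg.norm(resid)
        if nrm > tol * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.hstack([basis, (resid / nrm)[:, None]])
    return np.array(keep, dtype=int)


@dataclass
class _Solution:
    beta: np.ndarray
    effects: dict[str, np.ndarray]
    traces: dict[str, float]
    gen_rss: float  # y'(y - Xb - Zu) = e'e + u'(lambda)u
    ee: float  # e'e, the realized residual sum of squares
    m2ll: float
    inv_blocks: dict[str, np.ndarray] | None = None


def _sym_from_lower(a: np.ndarray) -> np.ndarray:
    return np.tril(a) + np.tril(a, -1).T


class _DirectWorkspace:
    """Absorbed (q x q) mixed-model equations; general but O(q^3)/iter."""

    def __init__(self, spec: ModelSpec):
        X, y = spec.X, spec.y
        self.spec = spec
        self.n, self.p = X.shape
        if self.p:
            xtx = X.T @ X
            try:
                self.xtx_cf = sla.cho_factor(xtx, lower=True)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "singular fixed-effects block; reduce X to full rank first"
                ) from exc
            self.logdet_xtx = 2.0 * np.sum(np.log(np.diag(self.xtx_cf[0])))
            self.beta_ols = sla.cho_solve(self.xtx_cf, X.T @ y)
        else:
            self.xtx_cf = None
            self.logdet_xtx = 0.0
            self.beta_ols = np.zeros(0)

        self.q_u = [t.n_levels for t in spec.terms]
        self.q = int(sum(self.q_u))
        self.offsets = np.concatenate([[0], np.cumsum(self.q_u)]).astype(int)
        if self.q:
            Z = sp.hstack([t.Z for t in spec.terms], format="csr")
            self.Z = Z
            ztz = (Z.T @ Z).toarray()
            self.zty = np.asarray(Z.T @ y).ravel()
            self.xtz = X.T @ Z if self.p else np.zeros((0, self.q))
            self.xtz = np.asarray(self.xtz)
        else:
            self.Z = None
            ztz = np.zeros((0, 0))
            self.zty = np.zeros(0)
            self.xtz = np.zeros((self.p, 0))
        self.xty = X.T @ y
        self.yty = float(y @ y)
        if self.p and self.q:
            w0 = sla.cho_solve(self.xtx_cf, self.xtz)
            self.ztmz = ztz - self.xtz.T @ w0
            self.rhs = self.zty - self.xtz.T @ self.beta_ols
        else:
            self.ztmz = ztz
            self.rhs = self.zty.copy()

    def solve(self, components: VarianceComponents, want_blocks: bool = False):
        s2 = components.residual
        lam = np.empty(self.q)
        for i, t in enumerate(self.spec.terms):
            lam[self.offsets[i] : self.offsets[i + 1]] = (
                s2 / components.by_term[t.label]
            )
        if self.q:
            S = self.ztmz.copy()
            S[np.diag_indices_from(S)] += lam
            cf = sla.cho_factor(S, lower=True, overwrite_a=True, check_finite=False)
            u = sla.cho_solve(cf, self.rhs, check_finite=False)
            logdet_s = 2.0 * np.sum(np.log(np.diag(cf[0])))
            sinv_low, info = dpotri(cf[0], lower=True)
            if info != 0:  # pragma: no cover
                raise np.linalg.LinAlgError("dpotri failed on the random block")
            sinv_diag = np.diag(sinv_low)
        else:
            u = np.zeros(0)
            logdet_s = 0.0
            sinv_low = np.zeros((0, 0))
            sinv_diag = np.zeros(0)
        if self.p:
            beta = sla.cho_solve(self.xtx_cf, self.xty - self.xtz @ u)
        else:
            beta = np.zeros(0)

        traces: dict[str, float] = {}
        effects: dict[str, np.ndarray] = {}
        blocks: dict[str, np.ndarray] | None = {} if want_blocks else None
        for i, t in enumerate(self.spec.terms):
            slc = slice(self.offsets[i], self.offsets[i + 1])
            traces[t.label] = float(np.sum(sinv_diag[slc]))
            effects[t.label] = u[slc]
            if want_blocks:
                blocks[t.label] = _sym_from_lower(sinv_low[slc, slc])

        # y'(y - Xb - Zu) via the cancellation-safe sum-of-squares identity
        resid = self.spec.y - self.spec.X @ beta
        if self.q:
            resid = resid - self.Z @ u
        ee = float(resid @ resid)
        gen_rss = ee + float((lam * u) @ u)
        q_term = sum(
            q * math.log(components.by_term[t.label])
            for q, t in zip(self.q_u, self.spec.terms)
        )
        m2ll = (
            (self.n - self.p - self.q) * math.log(s2)
            + q_term
            + logdet_s
            + self.logdet_xtx
            + gen_rss / s2
        )
        return _Solution(beta, effects, traces, gen_rss, ee, m2ll, blocks)


class _CellWorkspace:
    """Woodbury solver on replicate cells: V = s2 I + P H P'.

    Requires every random design row to be constant within cells (rows of
    the stacked Z identical for plots of the same cell), which holds for
    all field-trial models in this package.  All EM-REML quantities are
    derived from (C x C) and (p x p) factorizations:

        V^-1 = s2^-1 (I - P Wt P'),    Wt = (s2 H^-1 + Rc)^-1
        u_u  = s2_u Zc_u' P' V^-1 (y - X beta)
        tr(C^{uu}) = [s2_u q_u - s2_u^2 tr(Z_u' Pv Z_u)] / s2

    with ``Pv`` the REML projection and Rc the diagonal of cell sizes.
    """

    def __init__(self, spec: ModelSpec, cell_codes: np.ndarray):
        X, y = spec.X, spec.y
        self.spec = spec
        self.n, self.p = X.shape
        self.codes = cell_codes
        self.C = int(cell_codes.max()) + 1 if cell_codes.size else 0
        counts = np.bincount(cell_codes, minlength=self.C).astype(float)
        if np.any(counts == 0):  # pragma: no cover
            raise ValueError("empty cells in cell partition")
        self.rc = counts
        self.rs = np.sqrt(counts)

        P = sp.csr_matrix(
            (np.ones(self.n), (np.arange(self.n), cell_codes)), shape=(self.n, self.C)
        )
        # cell-level designs: one representative plot row per cell
        first_row = np.full(self.C, -1, dtype=int)
        for i, c in enumerate(cell_codes):
            if first_row[c] < 0:
                first_row[c] = i
        self.zc = [sp.csr_matrix(t.Z[first_row]) for t in spec.terms]
        self.zc_t = [zc.T.tocsr() for zc in self.zc]
        # Rs-scaled cell Gram matrices Rs (Zc_u Zc_u') Rs, stacked
        sr = self.rs[:, None] * self.rs[None, :]
        self.gsr = np.stack(
            [np.asarray((zc @ zc.T).toarray()) * sr for zc in self.zc]
        ) if spec.terms else np.zeros((0, self.C, self.C))

        self.q_u = [t.n_levels for t in spec.terms]
        self.q = int(sum(self.q_u))
        self.px = np.asarray(P.T @ X)  # C x p
        self.py = np.asarray(P.T @ y).ravel()
        self.xty = X.T @ y
        self.yty = float(y @ y)
        self.zty = [np.asarray(zt @ self.py).ravel() for zt in self.zc_t]
        self.px_s = self.px / self.rs[:, None]  # Rs^-1 P'X
        self.py_s = self.py / self.rs
        # parts of X'V^-1X / X'V^-1y carried by the residual term alone
        self.xtx_m = X.T @ X - self.px_s.T @ self.px_s
        self.xty_m = self.xty - self.px_s.T @ self.py_s
        self.yty_m = self.yty - float(self.py_s @ self.py_s)

    def solve(self, components: VarianceComponents, want_blocks: bool = False):
        s2 = components.residual
        terms = self.spec.terms
        s2_u = np.array([components.by_term[t.label] for t in terms])

        # a = s2 I + Rs H Rs with H = sum_u s2_u Zc_u Zc_u'
        a = np.einsum("u,uij->ij", s2_u, self.gsr, optimize=True)
        a[np.diag_indices_from(a)] += s2
        cf = sla.cho_factor(a, lower=True, overwrite_a=True, check_finite=False)
        logdet_a = 2.0 * np.sum(np.log(np.diag(cf[0])))
        inv_low, info = dpotri(cf[0], lower=True)
        if info != 0:  # pragma: no cover
            raise np.linalg.LinAlgError("dpotri failed on the cell block")
        inv_a = np.tril(inv_low)  # dpotri leaves factor residue above the diagonal
        inv_a += np.tril(inv_low, -1).T  # (s2 I + Hs)^-1, symmetric
        # key identities: P'V^-1P = Rs inv_a Rs,  P'V^-1X = Rs inv_a Rs^-1 P'X
        wpx = inv_a @ self.px_s  # C x p
        F = self.xtx_m / s2 + self.px_s.T @ wpx  # X'V^-1X
        ivy = inv_a @ self.py_s
        xvy = self.xty_m / s2 + self.px_s.T @ ivy
        if self.p:
            f_cf = sla.cho_factor(F, lower=True)
            beta = sla.cho_solve(f_cf, xvy)
            logdet_f = 2.0 * np.sum(np.log(np.diag(f_cf[0])))
        else:
            f_cf = None
            beta = np.zeros(0)
            logdet_f = 0.0

        # cell-level V^-1 residual: c_v = P'V^-1 (y - X beta) = Rs inv_a Rs^-1 pr
        pr_s = self.py_s - self.px_s @ beta
        c_v = self.rs * (inv_a @ pr_s)
        effects: dict[str, np.ndarray] = {}
        for v, zt, t in zip(s2_u, self.zc_t, terms):
            effects[t.label] = v * np.asarray(zt @ c_v).ravel()

        # block traces of the inverse coefficient matrix:
        # tr(Z_u'V^-1 Z_u) = sum(inv_a * Gsr_u) since P'V^-1P = Rs inv_a Rs
        tr_v_all = np.tensordot(self.gsr, inv_a, axes=([1, 2], [0, 1]))
        pvx = self.rs[:, None] * wpx  # P'V^-1X
        traces: dict[str, float] = {}
        blocks: dict[str, np.ndarray] | None = {} if want_blocks else None
        for i, (v, zc, zt, t) in enumerate(zip(s2_u, self.zc, self.zc_t, terms)):
            e_u = np.asarray(zt @ pvx)  # q_u x p = Z_u'V^-1X
            if self.p:
                fe = sla.cho_solve(f_cf, e_u.T)  # p x q_u
                tr_x = float(np.sum(e_u * fe.T))
            else:
                tr_x = 0.0
            tr_pv = float(tr_v_all[i]) - tr_x
            traces[t.label] = (v * t.n_levels - v * v * tr_pv) / s2
            if want_blocks:
                q_mat = inv_a * (self.rs[:, None] * self.rs[None, :])  # P'V^-1P
                zq = np.asarray(zt @ (zt @ q_mat).T)
                if self.p:
                    zq -= e_u @ sla.cho_solve(f_cf, e_u.T)
                blk = -(v * v) * zq
                blk[np.diag_indices_from(blk)] += v
                blocks[t.label] = blk / s2

        # y'(y - Xb - Zu) via the cancellation-safe sum-of-squares identity
        v_cells = np.zeros(self.C)
        pen = 0.0
        for v, zc, t in zip(s2_u, self.zc, terms):
            uu = effects[t.label]
            v_cells += zc @ uu
            pen += (s2 / v) * float(uu @ uu) if v else 0.0
        resid = self.spec.y - self.spec.X @ beta - v_cells[self.codes]
        ee = float(resid @ resid)
        gen_rss = ee + pen
        # -2 restricted log-likelihood, identical in value to the direct path
        # (y'Py = gen_rss / s2 by the MME normal equations)
        logdet_v = (self.n - self.C) * math.log(s2) + logdet_a
        m2ll = logdet_v + logdet_f + gen_rss / s2
        return _Solution(beta, effects, traces, gen_rss, ee, m2ll, blocks)


def _cell_partition(spec: ModelSpec) -> np.ndarray | None:
    """Group plot rows whose stacked random-design rows are identical."""
    if not spec.terms:
        return None
    Z = sp.hstack([t.Z for t in spec.terms], format="csr")
    Z.sum_duplicates()
    Z.sort_indices()
    codes = np.empty(Z.shape[0], dtype=int)
    seen: dict[bytes, int] = {}
    for i in range(Z.shape[0]):
        row = Z.getrow(i)
        key = row.indices.tobytes() + row.data.tobytes()
        codes[i] = seen.setdefault(key, len(seen))
    return codes


def _make_workspace(spec: ModelSpec, method: str = "auto"):
    if method not in ("auto", "direct", "cells"):
        raise ValueError(f"unknown solver method {method!r}")
    if method == "direct" or not spec.terms:
        return _DirectWorkspace(spec)
    codes = _cell_partition(spec)
    n_cells = int(codes.max()) + 1
    q = sum(t.n_levels for t in spec.terms)
    if method == "cells":
        return _CellWorkspace(spec, codes)
    # auto: the direct path factorizes q x q, the cell path C x C
    if n_cells < 0.8 * q and n_cells < spec.n_obs:
        return _CellWorkspace(spec, codes)
    return _DirectWorkspace(spec)


def solve_mme(
    spec: ModelSpec, components: VarianceComponents, method: str = "auto"
) -> MixedModelFit:
    """Solve the mixed-model equations at fixed variance components.

    Returns BLUEs of the fixed effects, BLUPs of every random term, and the
    per-term diagonal blocks of the inverse coefficient matrix (the
    ``W^-1`` blocks used both by the EM traces and by the marker-variance
    recovery formulas).
    """
    for t in spec.terms:
        v = components.by_term.get(t.label)
        if v is None:
            raise ValueError(f"no variance supplied for term {t.label!r}")
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"variance for term {t.label!r} must be finite positive")
    ws = _make_workspace(spec, method)
    sol = ws.solve(components, want_blocks=True)
    return MixedModelFit(
        spec=spec,
        components=components.copy(),
        beta=sol.beta,
        effects=sol.effects,
        inv_block_trace=sol.traces,
        inv_blocks=sol.inv_blocks,
        loglik_path=[-0.5 * sol.m2ll],
        converged=True,
        n_iter=0,
    )


def reml_em(
    spec: ModelSpec,
    init: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    floor_frac: float = 1e-10,
    method: str = "auto",
) -> MixedModelFit:
    """EM-REML estimation of all variance components of `spec`.

    Iterates the EM updates until the relative change of every component
    (including the residual) falls below `tol`, or `max_iter` is reached
    (the fit is then returned with ``converged=False`` and a warning).
    Components are floored at ``floor_frac * var(y)``; a component that
    finishes at the floor is flagged in ``at_floor`` and should be read as
    zero.
    """
    y = np.asarray(spec.y, dtype=float)
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("response is constant; variance components undefined")
    floor = floor_frac * vy
    qn = len(spec.terms)
    if init is None:
        start = vy / (qn + 1)
        init = VarianceComponents({t.label: start for t in spec.terms}, start)
    comp = init.copy()
    for k in list(comp.by_term):
        comp.by_term[k] = max(comp.by_term[k], floor)

    ws = _make_workspace(spec, method)
    denom = ws.n - ws.p
    if denom <= 0:
        raise ValueError("no residual degrees of freedom (N <= rank(X))")

    path: list[float] = []
    converged = False
    rel = math.inf
    it = 0
    for it in range(1, max_iter + 1):
        sol = ws.solve(comp)
        ll = -0.5 * sol.m2ll
        if path and ll < path[-1] - 1e-6 * max(1.0, abs(path[-1])):
            raise RuntimeError(
                f"REML log-likelihood decreased at iteration {it} "
                f"({path[-1]:.8g} -> {ll:.8g}); EM update is inconsistent"
            )
        path.append(ll)

        # true EM updates: s2_u from E[u'u | y]; the residual from
        # E[e'e | y] = e'e + s2 [(p + q) - sum_u lambda_u tr(C^uu)], which
        # keeps the restricted likelihood non-decreasing at every step
        # (the y'Py/(N - p) fixed-point form shares the stationary point
        # but can overshoot early and dent the likelihood)
        s2 = comp.residual
        lam_tr = sum(
            (s2 / comp.by_term[t.label]) * sol.traces[t.label] for t in spec.terms
        )
        q_tot = sum(t.n_levels for t in spec.terms)
        s2_new = (sol.ee + s2 * (ws.p + q_tot - lam_tr)) / ws.n
        s2_new = max(s2_new, floor)
        new = {}
        for t in spec.terms:
            uu = sol.effects[t.label]
            val = (float(uu @ uu) + comp.residual * sol.traces[t.label]) / t.n_levels
            new[t.label] = max(val, floor)

        rel = abs(s2_new - comp.residual) / max(comp.residual, floor)
        for k in new:
            rel = max(rel, abs(new[k] - comp.by_term[k]) / max(comp.by_term[k], floor))
        comp = VarianceComponents(new, s2_new)
        if rel < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "EM-REML did not converge in %d iterations (last relative change %.3g)",
            max_iter,
            rel,
        )

    # final solve at the converged components so solutions/likelihood match
    sol = ws.solve(comp, want_blocks=True)
    path.append(-0.5 * sol.m2ll)
    at_floor = {k: comp.by_term[k] <= floor * (1 + 1e-12) for k in comp.by_term}
    return MixedModelFit(
        spec=spec,
        components=comp,
        beta=sol.beta,
        effects=sol.effects,
        inv_block_trace=sol.traces,
        inv_blocks=sol.inv_blocks,
        loglik_path=path,
        converged=converged,
        n_iter=it,
        at_floor=at_floor,
    )
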