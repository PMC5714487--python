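"""REML engine for Gaussian linear mixed models.

Supports the covariance structures needed by a multi-environment trial
analysis: IID random terms (single variance), correlated random terms with a
known correlation matrix (``Corr``), and an unstructured site-by-site
covariance for a factor nested in sites (``Un``), with a single or per-site
residual variance.  Fixed effects are estimated by GLS at the converged
variance components; Wald tests and AIC-guided backward selection operate on
the resulting fit.

The general path assembles the marginal covariance V densely and maximizes
the restricted likelihood with an analytic gradient (L-BFGS-B on log-variance
/ Cholesky parameters).  Models with exactly one IID random term and a single
residual variance (the genome-scan and QTL-regression models, where the only
random effect is the line) are dispatched to a closed-form Woodbury path that
is orders of magnitude faster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "Iid",
    "Corr",
    "Un",
    "ModelSpec",
    "FitResult",
    "WaldResult",
    "fit_reml",
    "wald_test",
    "backward_select",
    "NotConvergedError",
    "RankDeficientError",
]

VAR_FLOOR = 1e-10


class NotConvergedError(RuntimeError):
    """REML iteration failed to converge."""


class RankDeficientError(ValueError):
    """Fixed-effect design is singular; message names aliased columns."""


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass
class Iid:
    """IID random term over the interaction of ``factors`` (":"-joined).

    ``subset=(col, value)`` restricts the term to rows where df[col]==value,
    giving e.g. a separate rep-row variance per site.
    """

    factors: str
    subset: tuple | None = None
    name: str | None = None

    def label(self) -> str:
        if self.name:
            return self.name
        if self.subset is not None:
            return f"{self.factors}@{self.subset[1]}"
        return self.factors


@dataclass
class Corr:
    """Random term with covariance sigma^2 * K over the levels of ``factor``."""

    factor: str
    corr: np.ndarray = None
    levels: list = None
    name: str | None = None

    def label(self) -> str:
        return self.name or f"{self.factor}|corr"


@dataclass
class Un:
    """Unstructured s x s covariance across ``site`` levels for ``unit``
    nested in site: cov((s,i),(t,i)) = Sigma[s,t], distinct units independent."""

    site: str
    unit: str
    name: str | None = None

    def label(self) -> str:
        return self.name or f"{self.site}.{self.unit}|un"


@dataclass
class ModelSpec:
    """Declarative model description.

    fixed terms are strings: a column name, or ":"-joined names for an
    interaction.  Columns listed in ``categorical`` get treatment (drop-first)
    coding; all others enter numerically.  An intercept is always included.
    """

    response: str
    fixed: list = field(default_factory=list)
    categorical: set = field(default_factory=set)
    random: list = field(default_factory=list)
    residual: str = "single"  # or "by_site"
    residual_by: str | None = None

    def replace_fixed(self, fixed: list) -> "ModelSpec":
        return ModelSpec(
            response=self.response,
            fixed=list(fixed),
            categorical=set(self.categorical),
            random=list(self.random),
            residual=self.residual,
            residual_by=self.residual_by,
        )


@dataclass
class FitResult:
    beta: pd.Series
    cov_beta: np.ndarray
    se: pd.Series
    vc: dict
    loglik: float
    aic: float
    converged: bool
    n_iter: int
    n_obs: int
    term_slices: dict
    spec: ModelSpec
    data: pd.DataFrame | None = None
    removal_path: list = field(default_factory=list)

    def require_converged(self, force: bool = False):
        if not self.converged and not force:
            raise NotConvergedError(
                "REML fit did not converge; pass force=True to use it anyway"
            )


@dataclass
class WaldResult:
    term: str
    statistic: float
    df: int
    stat_per_df: float
    pvalue: float


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _levels(series: pd.Series) -> list:
    return sorted(pd.unique(series.dropna()), key=str)


def _factor_matrix(df, col, categorical, drop_first):
    """Return (matrix, names) for one factor."""
    if col in categorical:
        lv = _levels(df[col])
        use = lv[1:] if drop_first else lv
        codes = df[col].to_numpy()
        mat = np.column_stack([(codes == l).astype(float) for l in use]) if use else np.empty((len(df), 0))
        names = [f"{col}[{l}]" for l in use]
        return mat, names
    vals = pd.to_numeric(df[col]).to_numpy(float)[:, None]
    return vals, [col]


def build_fixed_design(df: pd.DataFrame, spec: ModelSpec):
    """Build X with treatment coding; returns (X, names, term_slices)."""
    mats = [np.ones((len(df), 1))]
    names = ["Intercept"]
    term_slices = {"Intercept": slice(0, 1)}
    pos = 1
    for term in spec.fixed:
        facs = term.split(":")
        m = np.ones((len(df), 1))
        nm = [""]
        for f in facs:
            fm, fn = _factor_matrix(df, f, spec.categorical, drop_first=True)
            m = np.einsum("ij,ik->ijk", m, fm).reshape(len(df), -1)
            nm = [f"{a}:{b}" if a else b for a in nm for b in fn]
        mats.append(m)
        names.extend(nm)
        term_slices[term] = slice(pos, pos + m.shape[1])
        pos += m.shape[1]
    X = np.hstack(mats)
    return X, names, term_slices


def _check_rank(X, names):
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name aliased columns via QR pivoting
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        keep = np.abs(np.diag(R)) > 1e-8 * abs(R[0, 0])
        bad = [names[piv[i]] for i in range(X.shape[1]) if i >= keep.sum() or not keep[i]]
        raise RankDeficientError(f"fixed design is rank deficient; aliased columns: {bad}")


def _group_codes(df, factors, subset=None):
    key = df[factors.split(":")].astype(str).agg("\x1f".join, axis=1)
    if subset is not None:
        col, val = subset
        mask = (df[col] == val).to_numpy()
    else:
        mask = np.ones(len(df), bool)
    codes, uniq = pd.factorize(key[mask], sort=True)
    full = np.full(len(df), -1)
    full[mask] = codes
    return full, len(uniq), mask


def _indicator(codes, q):
    Z = np.zeros((len(codes), q))
    ok = codes >= 0
    Z[np.nonzero(ok)[0], codes[ok]] = 1.0
    return Z


# ---------------------------------------------------------------------------
# general dense-V REML
# ---------------------------------------------------------------------------


class _Term:
    """Precomputed structure for one random term."""

    def __init__(self, kind, label, ZAZ=None, Z=None, n_site=None, n_unit=None):
        self.kind = kind
        self.label = label
        self.ZAZ = ZAZ  # n x n, for iid/corr: Z A Z'
        self.Z = Z  # for UN: n x (s*u), site-major
        self.n_site = n_site
        self.n_unit = n_unit


def _prepare_terms(df, spec):
    terms = []
    for rt in spec.random:
        if isinstance(rt, Iid):
            codes, q, _ = _group_codes(df, rt.factors, rt.subset)
            Z = _indicator(codes, q)
            terms.append(_Term("iid", rt.label(), ZAZ=Z @ Z.T, Z=Z))
        elif isinstance(rt, Corr):
            lv = rt.levels if rt.levels is not None else _levels(df[rt.factor])
            idx = {l: i for i, l in enumerate(lv)}
            codes = df[rt.factor].map(idx).to_numpy()
            Z = _indicator(codes, len(lv))
            K = np.asarray(rt.corr, float)
            if K.shape != (len(lv), len(lv)):
                raise ValueError("correlation matrix does not match factor levels")
            terms.append(_Term("corr", rt.label(), ZAZ=Z @ K @ Z.T, Z=Z))
        elif isinstance(rt, Un):
            sites = _levels(df[rt.site])
            units = _levels(df[rt.unit])
            s, u = len(sites), len(units)
            si = df[rt.site].map({l: i for i, l in enumerate(sites)}).to_numpy()
            ui = df[rt.unit].map({l: i for i, l in enumerate(units)}).to_numpy()
            Z = _indicator(si * u + ui, s * u)
            terms.append(_Term("un", rt.label(), Z=Z, n_site=s, n_unit=u))
        else:
            raise TypeError(f"unknown random term {rt!r}")
    return terms


def _residual_masks(df, spec):
    if spec.residual == "single":
        return [np.ones(len(df), bool)], ["residual"]
    col = spec.residual_by
    lv = _levels(df[col])
    return [(df[col] == l).to_numpy() for l in lv], [f"residual@{l}" for l in lv]


def _unpack_un(theta, s):
    """theta (s + s(s-1)/2,) -> L lower-triangular, log-diag parameterized."""
    L = np.zeros((s, s))
    di = np.diag_indices(s)
    L[di] = np.exp(theta[:s])
    L[np.tril_indices(s, -1)] = theta[s:]
    return L


def _fit_general(df, spec, X, names, term_slices, start=None, max_iter=200):
    y = pd.to_numeric(df[spec.response]).to_numpy(float)
    n, p = X.shape
    terms = _prepare_terms(df, spec)
    masks, rnames = _residual_masks(df, spec)
    vary = max(float(np.var(y)), 1e-6)

    # parameter layout
    layout = []  # (kind, label, slice, extra)
    pos = 0
    theta0 = []
    for t in terms:
        if t.kind in ("iid", "corr"):
            layout.append((t.kind, t.label, slice(pos, pos + 1), t))
            theta0.append(np.log(vary / (len(terms) + 1)))
            pos += 1
        else:
            s = t.n_site
            k = s + s * (s - 1) // 2
            layout.append(("un", t.label, slice(pos, pos + k), t))
            init = np.zeros(k)
            init[:s] = 0.5 * np.log(vary / (len(terms) + 1))
            theta0.extend(init)
            pos += k
    res_sl = slice(pos, pos + len(masks))
    theta0.extend([np.log(vary / 2)] * len(masks))
    pos += len(masks)
    theta0 = np.array(theta0) if start is None else np.asarray(start, float)

    diag_idx = np.arange(n)

    def assemble(theta):
        V = np.zeros((n, n))
        sig = {}
        for kind, label, sl, t in layout:
            if kind in ("iid", "corr"):
                s2 = np.exp(theta[sl][0])
                V += s2 * t.ZAZ
                sig[label] = s2
            else:
                s = t.n_site
                L = _unpack_un(theta[sl], s)
                Sig = L @ L.T
                G = np.kron(Sig, np.eye(t.n_unit))
                V += t.Z @ G @ t.Z.T
                sig[label] = Sig
        rv = np.exp(theta[res_sl])
        dv = np.zeros(n)
        for m, v in zip(masks, rv):
            dv[m] = v
        V[diag_idx, diag_idx] += dv
        for i, rn in enumerate(rnames):
            sig[rn] = rv[i]
        return V, sig

    state = {}

    def nll_grad(theta):
        V, _ = assemble(theta)
        try:
            cF = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        logdetV = 2 * np.sum(np.log(np.diag(cF[0])))
        Vi = linalg.cho_solve(cF, np.eye(n), check_finite=False)
        ViX = Vi @ X
        XtViX = X.T @ ViX
        try:
            cX = linalg.cho_factor(XtViX, check_finite=False)
        except linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        logdetX = 2 * np.sum(np.log(np.diag(cX[0])))
        Viy = Vi @ y
        XtViy = X.T @ Viy
        beta = linalg.cho_solve(cX, XtViy, check_finite=False)
        r = Viy - ViX @ beta  # P y
        quad = float(y @ r)
        ll = -0.5 * (logdetV + logdetX + quad + (n - p) * np.log(2 * np.pi))
        # P = Vi - ViX (XtViX)^-1 ViX'
        P = Vi - ViX @ linalg.cho_solve(cX, ViX.T, check_finite=False)
        g = np.zeros_like(theta)
        for kind, label, sl, t in layout:
            if kind in ("iid", "corr"):
                s2 = np.exp(theta[sl][0])
                tr = float(np.sum(P * t.ZAZ))
                qd = float(r @ t.ZAZ @ r)
                g[sl] = -0.5 * s2 * (tr - qd)
            else:
                s, u = t.n_site, t.n_unit
                L = _unpack_un(theta[sl], s)
                PZ = P @ t.Z
                M = t.Z.T @ PZ  # (s*u) x (s*u)
                T = np.array(
                    [
                        [np.trace(M[a * u : (a + 1) * u, b * u : (b + 1) * u]) for b in range(s)]
                        for a in range(s)
                    ]
                )
                v = t.Z.T @ r
                vb = v.reshape(s, u)
                W = vb @ vb.T
                gt = np.zeros(sl.stop - sl.start)
                k = 0
                for a in range(s):
                    E = np.zeros((s, s))
                    E[a, a] = L[a, a]  # d/d(log L_aa)
                    dS = E @ L.T + L @ E.T
                    gt[k] = -0.5 * (np.sum(dS * T) - np.sum(dS * W))
                    k += 1
                for a in range(1, s):
                    for b in range(a):
                        E = np.zeros((s, s))
                        E[a, b] = 1.0
                        dS = E @ L.T + L @ E.T
                        gt[k] = -0.5 * (np.sum(dS * T) - np.sum(dS * W))
                        k += 1
                g[sl] = gt
        dP = np.diag(P)
        r2 = r**2
        rv = np.exp(theta[res_sl])
        for i, m in enumerate(masks):
            g[res_sl][i] = -0.5 * rv[i] * (float(dP[m].sum()) - float(r2[m].sum()))
        state["beta"] = beta
        state["cov"] = linalg.cho_solve(cX, np.eye(p), check_finite=False)
        state["ll"] = ll
        return -ll, -g

    bounds = [(np.log(VAR_FLOOR), 25.0)] * len(theta0)
    # off-diagonal UN params are unbounded
    for kind, label, sl, t in layout:
        if kind == "un":
            s = t.n_site
            for j in range(sl.start + s, sl.stop):
                bounds[j] = (-1e4, 1e4)
    opt = optimize.minimize(
        nll_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
    )
    nll_grad(opt.x)  # refresh state at optimum
    _, sig = assemble(opt.x)
    sig = {k: _floor_component(v) for k, v in sig.items()}
    n_var = len(opt.x)
    ll = state["ll"]
    converged = bool(opt.success) or np.max(np.abs(opt.jac)) < 1e-3
    beta = pd.Series(state["beta"], index=names)
    cov = state["cov"]
    return FitResult(
        beta=beta,
        cov_beta=cov,
        se=pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=names),
        vc=sig,
        loglik=float(ll),
        aic=float(-2 * ll + 2 * n_var),
        converged=converged,
        n_iter=int(opt.nit),
        n_obs=len(df),
        term_slices=term_slices,
        spec=spec,
        data=df,
    )


def _floor_component(v):
    if np.isscalar(v) or np.ndim(v) == 0:
        return 0.0 if v <= 10 * VAR_FLOOR else float(v)
    v = np.asarray(v, float)
    v[np.abs(v) <= 10 * VAR_FLOOR] = 0.0
    return v


# ---------------------------------------------------------------------------
# fast path: one IID random term + single residual
# ---------------------------------------------------------------------------


def _fit_one_iid(df, spec, X, names, term_slices, max_iter=200):
    y = pd.to_numeric(df[spec.response]).to_numpy(float)
    n, p = X.shape
    rt = spec.random[0]
    codes, q, _ = _group_codes(df, rt.factors)
    order = np.argsort(codes, kind="stable")
    counts = np.bincount(codes, minlength=q).astype(float)
    Xs, ys, cs = X[order], y[order], codes[order]
    # group-sum helper via reduceat
    starts = np.searchsorted(cs, np.arange(q))

    def gsum(M):
        return np.add.reduceat(M, starts, axis=0)

    state = {}

    def nll(theta):
        sg2, se2 = np.exp(theta)
        d = sg2 / (se2 + counts * sg2)  # per group
        GX, Gy = gsum(Xs), gsum(ys[:, None])[:, 0]
        ViX = (Xs - (d[:, None] * GX)[cs]) / se2
        Viy = (ys - (d * Gy)[cs]) / se2
        logdetV = float(np.sum((counts - 1)) * np.log(se2) + np.sum(np.log(se2 + counts * sg2)))
        XtViX = Xs.T @ ViX
        try:
            cX = linalg.cho_factor(XtViX, check_finite=False)
        except linalg.LinAlgError:
            return 1e10
        XtViy = Xs.T @ Viy
        beta = linalg.cho_solve(cX, XtViy, check_finite=False)
        quad = float(ys @ Viy - XtViy @ beta)
        logdetX = 2 * np.sum(np.log(np.diag(cX[0])))
        ll = -0.5 * (logdetV + logdetX + quad + (n - p) * np.log(2 * np.pi))
        state["beta"] = beta
        state["cov"] = linalg.cho_solve(cX, np.eye(p), check_finite=False)
        state["ll"] = ll
        return -ll

    vary = max(float(np.var(y)), 1e-8)
    theta0 = np.log([vary / 2, vary / 2])
    opt = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=[(np.log(VAR_FLOOR), 25)] * 2,
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-9},
    )
    # polish: L-BFGS-B's numerical gradient can stop a hair early
    opt2 = optimize.minimize(
        nll, opt.x, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 400}
    )
    # converged if either optimizer reports success, or the polish could not
    # improve the objective beyond numerical noise
    success = bool(
        opt.success
        or opt2.success
        or abs(opt2.fun - opt.fun) <= 1e-7 * max(1.0, abs(opt.fun))
    )
    if opt2.fun <= opt.fun:
        opt.x, opt.nit = opt2.x, opt.nit + opt2.nit
    opt.success = success
    nll(opt.x)
    sg2, se2 = np.exp(opt.x)
    ll = state["ll"]
    # restore original row order irrelevant: beta/cov invariant
    beta = pd.Series(state["beta"], index=names)
    cov = state["cov"]
    return FitResult(
        beta=beta,
        cov_beta=cov,
        se=pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=names),
        vc={rt.label(): _floor_component(sg2), "residual": _floor_component(se2)},
        loglik=float(ll),
        aic=float(-2 * ll + 4),
        converged=bool(opt.success),
        n_iter=int(opt.nit),
        n_obs=len(df),
        term_slices=term_slices,
        spec=spec,
        data=df,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def fit_reml(spec: ModelSpec, table: pd.DataFrame, max_iter: int = 200) -> FitResult:
    """Fit the mixed model described by ``spec`` to ``table`` by REML.

    Rows with a missing response are dropped (count reported via warning).
    Raises :class:`RankDeficientError` when the fixed design is singular.
    """
    df = table.reset_index(drop=True)
    miss = df[spec.response].isna()
    if miss.any():
        warnings.warn(f"dropping {int(miss.sum())} rows with missing response")
        df = df[~miss].reset_index(drop=True)
    X, names, term_slices = build_fixed_design(df, spec)
    _check_rank(X, names)
    if not spec.random:
        return _fit_ols(df, spec, X, names, term_slices)
    if (
        len(spec.random) == 1
        and isinstance(spec.random[0], Iid)
        and spec.random[0].subset is None
        and spec.residual == "single"
    ):
        return _fit_one_iid(df, spec, X, names, term_slices, max_iter)
    return _fit_general(df, spec, X, names, term_slices, max_iter=max_iter)


def _fit_ols(df, spec, X, names, term_slices):
    y = pd.to_numeric(df[spec.response]).to_numpy(float)
    n, p = X.shape
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    s2 = float(resid @ resid) / max(n - p, 1)
    cov = s2 * np.linalg.inv(XtX)
    # REML log-likelihood of the fixed-effects-only model at sigma^2 = RSS/(n-p)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi) + np.log(s2) + 1) + np.linalg.slogdet(XtX)[1])
    return FitResult(
        beta=pd.Series(beta, index=names),
        cov_beta=cov,
        se=pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)), index=names),
        vc={"residual": s2},
        loglik=float(ll),
        aic=float(-2 * ll + 2),
        converged=True,
        n_iter=0,
        n_obs=n,
        term_slices=term_slices,
        spec=spec,
        data=df,
    )


def wald_test(fit: FitResult, term: str) -> WaldResult:
    """Wald chi-square test of a fixed term in a converged fit."""
    if term not in fit.term_slices:
        raise ValueError(f"term {term!r} not in fitted model")
    sl = fit.term_slices[term]
    b = fit.beta.to_numpy()[sl]
    C = fit.cov_beta[sl, sl]
    df_ = len(b)
    if df_ == 0:
        return WaldResult(term, 0.0, 0, 0.0, 1.0)
    W = float(b @ np.linalg.solve(C, b))
    W = max(W, 0.0)
    p = float(stats.chi2.sf(W, df_)) if W > 0 else 1.0
    return WaldResult(term, W, df_, W / df_, p)


def _removable(fixed: list, protected: set) -> list:
    """Terms droppable under marginality: not protected, and not a strict
    subset of another current term's factor set."""
    sets = {t: frozenset(t.split(":")) for t in fixed}
    out = []
    for t, s in sets.items():
        if t in protected:
            continue
        if any(s < s2 for t2, s2 in sets.items() if t2 != t):
            continue
        out.append(t)
    return out


def backward_select(
    spec: ModelSpec,
    table: pd.DataFrame,
    alpha: float = 0.05,
    protected: set | None = None,
) -> FitResult:
    """Backward elimination of fixed terms by Wald p-value (largest p > alpha
    removed first, marginality respected), comparing initial and final models
    by AIC."""
    protected = set(protected or ())
    fit0 = fit_reml(spec, table)
    fit0.require_converged()
    fit = fit0
    path = []
    while True:
        cand = _removable(fit.spec.fixed, protected)
        worst, worst_p = None, alpha
        for t in cand:
            w = wald_test(fit, t)
            if w.pvalue > worst_p:
                worst, worst_p = t, w.pvalue
        if worst is None:
            break
        newfixed = [t for t in fit.spec.fixed if t != worst]
        path.append((worst, worst_p))
        fit = fit_reml(fit.spec.replace_fixed(newfixed), table)
    final = fit if fit.aic <= fit0.aic or fit is fit0 else fit0
    final.removal_path = path
    return final
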