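"""Genome scans and the QTL-by-site model.

Scans operate on spatially adjusted line means from several sites stacked
long (one record per line x site).  The scan model at a tested position is

    TF = mu + Site + QTL + QTL x Site + line (random) + eps

where QTL is the expected marker dosage at the position.  The line and
residual variances are estimated once under the no-QTL null and held fixed
along the genome (two-stage GLS), and the reported statistic is the joint
Wald -log10 p of the QTL main and interaction coefficients against a
chi-square with s degrees of freedom (s sites).  Composite interval mapping
adds dosages of previously selected QTL (and their site interactions) as
covariates, excluding cofactors near the tested position.  The genome-wide
threshold is a modified Bonferroni correction on the effective number of
independent marker tests computed from per-chromosome eigenvalues of the
marker correlation matrix (Li-Ji).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import mixedmodel as mm
from .genotypes import DosageMatrix

__all__ = [
    "ScanProfile",
    "QtlSet",
    "QtlSiteModel",
    "liji_threshold",
    "sim_scan",
    "cim_scan",
    "select_peaks",
    "fit_qtl_site_model",
    "qtl_records",
]


@dataclass
class ScanProfile:
    table: pd.DataFrame  # chrom, pos_cm, name, neglog10p, effect_<site>...
    sites: list
    threshold: float | None = None


@dataclass
class QtlSet:
    table: pd.DataFrame  # qtl, marker, chrom, pos_cm, neglog10p, interacts

    @property
    def markers(self) -> list:
        return self.table["marker"].tolist()

    def __len__(self):
        return len(self.table)


@dataclass
class QtlSiteModel:
    intercept: float
    site_effects: pd.Series
    qtl_main: dict  # marker -> alpha_q
    qtl_site: dict  # (marker, site) -> beta_qs (treatment coding vs first site)
    epistasis: dict
    per_site_effects: pd.DataFrame  # marker x site total effect alpha + beta
    fit: mm.FitResult
    interacting: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# threshold
# ---------------------------------------------------------------------------


def liji_threshold(dosages: DosageMatrix, alpha: float = 0.05) -> tuple:
    """Effective number of independent tests and the genome-wide
    -log10 p threshold.

    Per chromosome the eigenvalues lambda_i of the marker correlation matrix
    give M_eff = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ];
    chromosome contributions add, and the threshold is -log10(alpha / M_eff).
    """
    if len(dosages.lines) < 2 or dosages.values.shape[1] < 2:
        raise ValueError("need at least 2 lines and 2 markers")
    m_eff = 0.0
    for chrom, sub in dosages.positions.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        X = dosages.values[:, cols]
        sd = X.std(axis=0)
        keep = sd > 1e-12
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant columns on chromosome {chrom}"
            )
        X = X[:, keep]
        if X.shape[1] == 0:
            continue
        if X.shape[1] == 1:
            m_eff += 1.0
            continue
        C = np.corrcoef(X, rowvar=False)
        lam = np.clip(np.linalg.eigvalsh(C), 0, None)
        m_eff += float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return m_eff, float(-np.log10(alpha / m_eff))


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _long_means(means: pd.DataFrame) -> pd.DataFrame:
    need = {"site", "line"}
    if not need.issubset(means.columns):
        raise ValueError("adjusted means need columns site, line, tf_adj (or tf)")
    col = "tf_adj" if "tf_adj" in means.columns else "tf"
    df = means[["site", "line", col]].rename(columns={col: "tf"}).copy()
    return df.sort_values(["line", "site"], kind="stable").reset_index(drop=True)


class _GlsScanEngine:
    """Two-stage GLS scaffolding shared by SIM and CIM.

    Estimates (line, residual) variances under the null model, whitens all
    columns with V^-1/2 (block structure over lines), and then tests each
    position by adding its dosage main + site-interaction columns to the
    fixed design.
    """

    def __init__(self, means: pd.DataFrame, dosages: DosageMatrix):
        df = _long_means(means)
        missing = set(df["line"]) - set(dosages.lines)
        if missing:
            raise ValueError(f"lines without dosage data: {sorted(missing)[:5]} ...")
        self.df = df
        self.sites = sorted(df["site"].unique(), key=str)
        if len(self.sites) < 2:
            raise ValueError("scan needs adjusted means from at least 2 sites")
        self.dosages = dosages
        null = mm.fit_reml(
            mm.ModelSpec(
                response="tf", fixed=["site"], categorical={"site"}, random=[mm.Iid("line")]
            ),
            df,
        )
        null.require_converged()
        self.null = null
        sg2 = max(null.vc.get("line", 0.0), 0.0)
        se2 = max(null.vc.get("residual", 0.0), mm.VAR_FLOOR)
        codes, uniq = pd.factorize(df["line"], sort=True)
        self.line_codes = codes
        counts = np.bincount(codes).astype(float)
        # V^-1/2 within a line block of size m: (I - c/m J)/sqrt(se2),
        # c = 1 - sqrt(se2 / (se2 + m sg2))
        self._c = 1.0 - np.sqrt(se2 / (se2 + counts * sg2))
        self._se = np.sqrt(se2)
        self._counts = counts
        order = np.argsort(codes, kind="stable")
        self._order = order
        self._starts = np.searchsorted(codes[order], np.arange(len(uniq)))
        # line -> row index into dosage matrix
        lidx = {l: i for i, l in enumerate(dosages.lines)}
        self.line_rows = df["line"].map(lidx).to_numpy()
        site_d = pd.get_dummies(df["site"]).astype(float)
        self.site_dummies = site_d[self.sites[1:]].to_numpy()
        Xb = np.column_stack([np.ones(len(df)), self.site_dummies])
        self.Xb_names = ["Intercept"] + [f"site[{s}]" for s in self.sites[1:]]
        self.yw = self.whiten(df["tf"].to_numpy(float))
        self.Xbw = self.whiten(Xb)

    def whiten(self, M: np.ndarray) -> np.ndarray:
        M = M[:, None] if M.ndim == 1 else M
        Ms = M[self._order]
        gm = np.add.reduceat(Ms, self._starts, axis=0) / self._counts[:, None]
        out = np.empty_like(Ms)
        codes_sorted = self.line_codes[self._order]
        out = (Ms - (self._c[:, None] * gm)[codes_sorted]) / self._se
        inv = np.empty_like(self._order)
        inv[self._order] = np.arange(len(self._order))
        res = out[inv]
        return res[:, 0] if res.shape[1] == 1 else res

    def position_columns(self, col_idx: int) -> np.ndarray:
        d = self.dosages.values[:, col_idx][self.line_rows]
        return np.column_stack([d, d[:, None] * self.site_dummies])

    def test_position(self, col_idx: int, extra_w: np.ndarray | None = None):
        """Joint Wald test of (QTL, QTL x Site); returns (neglog10p, per-site
        effects)."""
        Q = self.position_columns(col_idx)
        if np.std(Q[:, 0]) < 1e-10:
            return 0.0, np.full(len(self.sites), np.nan)
        Qw = self.whiten(Q)
        X = np.hstack([self.Xbw, extra_w, Qw]) if extra_w is not None else np.hstack([self.Xbw, Qw])
        XtX = X.T @ X
        Xty = X.T @ self.yw
        try:
            beta = np.linalg.solve(XtX, Xty)
            C = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            return 0.0, np.full(len(self.sites), np.nan)
        k = Qw.shape[1]
        bq = beta[-k:]
        Cq = C[-k:, -k:]
        try:
            W = float(bq @ np.linalg.solve(Cq, bq))
        except np.linalg.LinAlgError:
            return 0.0, np.full(len(self.sites), np.nan)
        p = stats.chi2.sf(max(W, 0.0), k)
        nlp = float(-np.log10(max(p, 1e-300)))
        eff = bq[0] + np.concatenate([[0.0], bq[1:]])
        return nlp, eff


def sim_scan(means: pd.DataFrame, dosages: DosageMatrix, step: float = 1.0) -> ScanProfile:
    """Simple interval mapping over the dosage grid (see module docstring).

    ``step`` is accepted for interface symmetry; the grid is the one carried
    by ``dosages`` (build it with :func:`genotypes.pseudomarker_dosages`).
    """
    return cim_scan(means, dosages, cofactors=None)


def cim_scan(
    means: pd.DataFrame,
    dosages: DosageMatrix,
    cofactors: QtlSet | None,
    window: float = 5.0,
    min_cofactor_distance: float = 50.0,
) -> ScanProfile:
    """Composite interval mapping: the SIM scan with cofactor dosages (and
    their site interactions) as covariates.

    A cofactor on the tested chromosome within ``min_cofactor_distance`` cM
    of the tested position is excluded from the covariate set (so in
    particular any cofactor within ``window`` cM never enters).  With no
    cofactors this reduces exactly to :func:`sim_scan`.
    """
    eng = _GlsScanEngine(means, dosages)
    pos = dosages.positions
    cof = []
    if cofactors is not None and len(cofactors):
        for _, row in cofactors.table.iterrows():
            hit = pos.index[pos["name"] == row["marker"]]
            if len(hit) == 0:
                raise ValueError(f"cofactor marker {row['marker']!r} not in dosage grid")
            j = int(hit[0])
            cof.append((j, pos.loc[j, "chrom"], float(pos.loc[j, "pos_cm"])))
    cof_cols = {j: eng.whiten(eng.position_columns(j)) for j, _, _ in cof}
    excl = max(window, min_cofactor_distance)
    chroms = pos["chrom"].to_numpy()
    cms = pos["pos_cm"].to_numpy(float)
    names = pos["name"].to_numpy()
    nlps = np.empty(len(pos))
    effs = np.empty((len(pos), len(eng.sites)))
    for j in range(len(pos)):
        use = [
            cof_cols[k]
            for k, cchrom, ccm in cof
            if not (cchrom == chroms[j] and abs(ccm - cms[j]) < excl)
        ]
        extra = np.hstack(use) if use else None
        nlps[j], effs[j] = eng.test_position(j, extra)
    tab = pd.DataFrame({"chrom": chroms, "pos_cm": cms, "name": names, "neglog10p": nlps})
    for i, s in enumerate(eng.sites):
        tab[f"effect_{s}"] = effs[:, i]
    return ScanProfile(table=tab, sites=eng.sites)


def select_peaks(profile: ScanProfile, threshold: float, min_sep: float = 10.0) -> QtlSet:
    """Greedy peak selection: local maxima with -log10 p >= threshold,
    admitted by decreasing height with a ``min_sep`` cM exclusion radius on
    the same chromosome; each peak is tagged with its nearest map marker."""
    t = profile.table
    # restrict to local maxima along each chromosome's ordered grid
    is_max = np.ones(len(t), bool)
    for _, sub in t.groupby("chrom", sort=False):
        v = sub["neglog10p"].to_numpy()
        idx = sub.index.to_numpy()
        left = np.r_[-np.inf, v[:-1]]
        right = np.r_[v[1:], -np.inf]
        is_max[idx] = (v >= left) & (v >= right)
    picked = []
    cand = t[is_max & (t["neglog10p"] >= threshold)].sort_values("neglog10p", ascending=False)
    for _, row in cand.iterrows():
        if any(
            p["chrom"] == row["chrom"] and abs(p["pos_cm"] - row["pos_cm"]) < min_sep
            for p in picked
        ):
            continue
        picked.append(row)
    rows = []
    for i, p in enumerate(sorted(picked, key=lambda r: (str(r["chrom"]), r["pos_cm"])), 1):
        # nearest true marker (names that are not autogenerated grid points)
        sub = t[(t["chrom"] == p["chrom"]) & (~t["name"].str.startswith(f"c{p['chrom']}_"))]
        if len(sub) == 0:
            sub = t[t["chrom"] == p["chrom"]]
        k = (sub["pos_cm"] - p["pos_cm"]).abs().idxmin()
        rows.append(
            {
                "qtl": f"Q{i}",
                "marker": t.loc[k, "name"],
                "chrom": p["chrom"],
                "pos_cm": p["pos_cm"],
                "neglog10p": p["neglog10p"],
                "interacts": False,
            }
        )
    return QtlSet(table=pd.DataFrame(rows, columns=["qtl", "marker", "chrom", "pos_cm", "neglog10p", "interacts"]))


# ---------------------------------------------------------------------------
# QTL x Site model
# ---------------------------------------------------------------------------


def qtl_records(means: pd.DataFrame, dosages: DosageMatrix, markers: list) -> pd.DataFrame:
    """Line x site records (line, site, tf) augmented with dosage columns."""
    df = _long_means(means)
    lidx = {l: i for i, l in enumerate(dosages.lines)}
    rows = df["line"].map(lidx).to_numpy()
    for mk in markers:
        df[mk] = dosages.column(mk)[rows]
    return df


def fit_qtl_site_model(
    qtls: QtlSet,
    means: pd.DataFrame,
    dosages: DosageMatrix,
    epistatic_pairs: tuple = (),
    alpha: float = 0.05,
) -> QtlSiteModel:
    """Mixed QTL model with site interactions and backward selection.

    TF = mu + Site + sum_q a_q X_q + sum_q b_qs X_q Site + epistasis +
    line (random); QTL x Site terms are backward-eliminated by Wald p at
    ``alpha`` (marginality respected, QTL main effects protected), then the
    surviving interaction QTL are flagged and per-site total effects
    reported.
    """
    markers = qtls.markers
    df = qtl_records(means, dosages, markers)
    # drop aliased (identical) dosage columns
    kept = []
    for mk in markers:
        if any(np.allclose(df[mk], df[o]) for o in kept):
            warnings.warn(f"QTL marker {mk} aliased with an earlier QTL; dropped")
            continue
        kept.append(mk)
    markers = kept
    epi_cols = []
    for a, b in epistatic_pairs:
        col = f"{a}__x__{b}"
        df[col] = df[a] * df[b]
        epi_cols.append(col)
    fixed = ["site"] + markers + [f"{mk}:site" for mk in markers] + epi_cols
    spec = mm.ModelSpec(
        response="tf", fixed=fixed, categorical={"site"}, random=[mm.Iid("line")]
    )
    protected = {"site"} | set(markers) | set(epi_cols)
    fit = mm.backward_select(spec, df, alpha=alpha, protected=protected)
    sites = sorted(df["site"].unique(), key=str)
    beta = fit.beta
    interacting = [mk for mk in markers if f"{mk}:site" in fit.spec.fixed]
    qtl_site = {}
    per_site = pd.DataFrame(index=markers, columns=sites, dtype=float)
    for mk in markers:
        a = float(beta[mk])
        for s in sites:
            b = float(beta.get(f"{mk}:site[{s}]", 0.0)) if mk in interacting else 0.0
            per_site.loc[mk, s] = a + b
            if mk in interacting and s != sites[0]:
                qtl_site[(mk, s)] = float(beta.get(f"{mk}:site[{s}]", 0.0))
    site_eff = pd.Series(
        {s: float(beta.get(f"site[{s}]", 0.0)) for s in sites}, name="site_effect"
    )
    tab = qtls.table.copy()
    tab["interacts"] = tab["marker"].map(lambda m: m in interacting)
    qtls.table = tab
    return QtlSiteModel(
        intercept=float(beta["Intercept"]),
        site_effects=site_eff,
        qtl_main={mk: float(beta[mk]) for mk in markers},
        qtl_site=qtl_site,
        epistasis={(a, b): float(beta[f"{a}__x__{b}"]) for a, b in epistatic_pairs},
        per_site_effects=per_site,
        fit=fit,
        interacting=interacting,
    )
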