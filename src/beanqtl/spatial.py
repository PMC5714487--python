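"""Per-site spatial adjustment and single-site heritability.

Plot-level flowering times within one site are adjusted for the randomized
row-column design with the mixed model

    TF = mu + G (fixed) + B (fixed) + BR + BC + eps

where B is the replicate, BR/BC are rows and columns nested in replicate
(random), and the adjusted mean of a line is its fixed-effect prediction at
the average replicate.  Broad-sense heritability at the site refits genotype
and replicate as random (genotype with the pedigree correlation of a
biparental RIL family) and takes Var(G) over the summed variance components.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import mixedmodel as mm

__all__ = ["kinship_matrix", "adjust_site_means", "heritability_single_site"]


def kinship_matrix(roles: dict) -> tuple:
    """Expected genetic correlation matrix of a biparental RIL family.

    ``roles`` maps line id -> 'parent1' | 'parent2' | 'ril'.  Correlations:
    0 between the two parents, 0.5 parent-RIL, 0.5 RIL-RIL, 1 on the
    diagonal.  Returns (K, level order).
    """
    valid = {"parent1", "parent2", "ril"}
    bad = {l: r for l, r in roles.items() if r not in valid}
    if bad:
        raise ValueError(f"unknown roles: {bad}")
    if not roles:
        raise ValueError("need at least one line")
    levels = sorted(roles, key=str)
    n = len(levels)
    K = np.full((n, n), 0.5)
    for i, a in enumerate(levels):
        for j, b in enumerate(levels):
            if i == j:
                K[i, j] = 1.0
            elif {roles[a], roles[b]} == {"parent1", "parent2"}:
                K[i, j] = 0.0
    return K, levels


def _eq1_spec(random_g: bool, K=None, levels=None) -> mm.ModelSpec:
    if random_g:
        rand = [
            mm.Corr("line", corr=K, levels=levels, name="genotype"),
            mm.Iid("rep", name="rep"),
            mm.Iid("rep:row", name="rep_row"),
            mm.Iid("rep:col", name="rep_col"),
        ]
        fixed = []
    else:
        rand = [mm.Iid("rep:row", name="rep_row"), mm.Iid("rep:col", name="rep_col")]
        fixed = ["line", "rep"]
    return mm.ModelSpec(
        response="tf_days",
        fixed=fixed,
        categorical={"line", "rep", "row", "col"},
        random=rand,
    )


def adjust_site_means(plots: pd.DataFrame, site, K=None) -> pd.DataFrame:
    """Spatially adjusted line means for one site.

    Returns a DataFrame (site, line, tf_adj, se).  The adjusted mean of line
    i is mu + G_i + mean_j(B_j): fixed-effect estimates evaluated at equally
    weighted replicates, purged of the random row/column effects.
    """
    sub = plots[plots["site"] == site].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"site {site!r} not present in plot table")
    counts = sub.groupby("line").size()
    missing = counts[counts < 1]
    if len(missing):
        warnings.warn(f"lines with no plots at {site}: {list(missing.index)}")
    fit = mm.fit_reml(_eq1_spec(random_g=False), sub)
    fit.require_converged()
    lines = sorted(sub["line"].unique(), key=str)
    reps = sorted(sub["rep"].unique(), key=str)
    beta, cov = fit.beta, fit.cov_beta
    names = list(beta.index)
    b_rep = np.mean([0.0] + [beta.get(f"rep[{r}]", 0.0) for r in reps[1:]])
    rows = []
    for line in lines:
        nm = f"line[{line}]"
        idx = [0] + ([names.index(nm)] if nm in names else [])
        est = beta.iloc[0] + (beta[nm] if nm in names else 0.0) + b_rep
        w = np.zeros(len(names))
        w[0] = 1.0
        if nm in names:
            w[names.index(nm)] = 1.0
        for r in reps[1:]:
            w[names.index(f"rep[{r}]")] = 1.0 / len(reps)
        se = float(np.sqrt(w @ cov @ w))
        rows.append({"site": site, "line": line, "tf_adj": float(est), "se": se})
    return pd.DataFrame(rows)


def heritability_single_site(plots: pd.DataFrame, site, K=None, levels=None) -> float:
    """Broad-sense heritability at one site.

    Refits the spatial model with genotype (correlation K across line
    levels) and replicate as random, and returns
    Var(G) / (Var(G) + Var(B) + Var(BR) + Var(BC) + Var(eps)).
    """
    sub = plots[plots["site"] == site].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"site {site!r} not present in plot table")
    if K is None:
        lv = sorted(sub["line"].unique(), key=str)
        K_, levels = kinship_matrix({l: "ril" for l in lv})
        K = K_
    fit = mm.fit_reml(_eq1_spec(random_g=True, K=K, levels=levels), sub)
    fit.require_converged()
    vg = fit.vc["genotype"]
    tot = vg + fit.vc["rep"] + fit.vc["rep_row"] + fit.vc["rep_col"] + fit.vc["residual"]
    if tot <= 0:
        raise ZeroDivisionError("total phenotypic variance is zero")
    return float(vg / tot)
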