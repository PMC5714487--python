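"""Multi-site mixed model with unstructured genetic covariance across sites.

The plot-level model across all sites is

    TF = mu + S (fixed) + S.B (fixed) + S.G + S.B.R + S.B.C + eps

with the site-by-genotype term S.G carrying an unstructured s x s covariance
across sites (distinct lines independent), row and column effects nested in
site x replicate with a separate variance per site, and a per-site residual
variance.  Heritability at a site is the genetic variance at that site over
the summed row, column, genetic and error components; the overall
heritability is the ratio of across-site averages (not the average ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mixedmodel as mm

__all__ = [
    "MultiSiteFit",
    "fit_multisite_model",
    "heritability_by_site",
    "heritability_from_components",
]

_COMPONENT_ROWS = ["rep_row", "rep_col", "site_line", "error"]


@dataclass
class MultiSiteFit:
    fit: mm.FitResult
    sites: list
    un: np.ndarray  # s x s genetic covariance across sites
    components: pd.DataFrame  # rows: rep_row, rep_col, site_line, error; cols: sites + Overall


def fit_multisite_model(plots: pd.DataFrame, max_iter: int = 200) -> MultiSiteFit:
    """Fit the multi-site model to the full plot table by REML."""
    sites = sorted(plots["site"].unique(), key=str)
    if len(sites) < 2:
        raise ValueError("multi-site model needs at least 2 sites")
    per_site_lines = plots.groupby("line")["site"].nunique()
    if (per_site_lines < 2).all():
        raise ValueError("each line must appear in at least 2 sites")
    random = [mm.Un("site", "line", name="site_line")]
    for s in sites:
        reps = plots.loc[plots["site"] == s, "rep"].nunique()
        if reps < 2:
            warnings.warn(f"site {s} has a single replicate; its row/column terms dropped")
            continue
        random.append(mm.Iid("rep:row", subset=("site", s), name=f"rep_row@{s}"))
        random.append(mm.Iid("rep:col", subset=("site", s), name=f"rep_col@{s}"))
    spec = mm.ModelSpec(
        response="tf_days",
        fixed=["site", "site:rep"],
        categorical={"site", "rep", "line", "row", "col"},
        random=random,
        residual="by_site",
        residual_by="site",
    )
    fit = mm.fit_reml(spec, plots, max_iter=max_iter)
    un = np.asarray(fit.vc["site_line"], float)
    comp = pd.DataFrame(index=_COMPONENT_ROWS, columns=sites + ["Overall"], dtype=float)
    for i, s in enumerate(sites):
        comp.loc["rep_row", s] = fit.vc.get(f"rep_row@{s}", 0.0)
        comp.loc["rep_col", s] = fit.vc.get(f"rep_col@{s}", 0.0)
        comp.loc["site_line", s] = un[i, i]
        comp.loc["error", s] = fit.vc.get(f"residual@{s}", 0.0)
    comp["Overall"] = comp[sites].mean(axis=1)
    return MultiSiteFit(fit=fit, sites=sites, un=un, components=comp)


def heritability_from_components(components: pd.DataFrame) -> pd.Series:
    """Per-site H_R^2 and overall H_T^2 from a component table.

    ``components`` has rows rep_row, rep_col, site_line, error and one
    column per site.  H_R^2(s) = V_sg(s) / total(s); H_T^2 is the across-site
    mean of V_sg over the across-site mean total.
    """
    sites = [c for c in components.columns if c != "Overall"]
    need = set(_COMPONENT_ROWS)
    if not need.issubset(components.index):
        raise ValueError(f"component table needs rows {sorted(need)}")
    tot = components.loc[_COMPONENT_ROWS, sites].sum(axis=0)
    if (tot <= 0).any():
        raise ZeroDivisionError("zero total variance at a site")
    out = components.loc["site_line", sites] / tot
    out["Overall"] = components.loc["site_line", sites].mean() / tot.mean()
    return out.astype(float)


def heritability_by_site(fit: MultiSiteFit) -> pd.Series:
    """Heritabilities from a fitted multi-site model (see
    :func:`heritability_from_components`)."""
    fit.fit.require_converged()
    return heritability_from_components(fit.components[fit.sites])
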