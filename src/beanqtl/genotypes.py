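"""Genotype containers, map functions, and HMM-based imputation.

The population is a set of fully homozygous recombinant inbred lines (RILs)
from a biparental cross, so every marker has exactly two states, coded -1
(first parent) and +1 (second parent); heterozygotes do not occur.  Missing
calls are imputed with a two-state hidden Markov model along each chromosome
whose transition probabilities come from the Haldane map function applied to
inter-marker distances.  The output is the posterior expected dosage
P(+1|data) - P(-1|data) in [-1, +1] rather than a hard call, which is what
downstream QTL regressions consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LinkageMap",
    "GenotypeMatrix",
    "DosageMatrix",
    "haldane_r",
    "ril_r",
    "impute_hmm",
    "pseudomarker_dosages",
]

_R_FLOOR = 1e-9  # keeps zero-distance transitions numerically proper


@dataclass
class LinkageMap:
    """Marker map: one row per marker (marker, chrom, pos_cm).

    Positions are 0-based cM within chromosome and non-decreasing; exact ties
    are permitted (recombinationally identical markers).
    """

    table: pd.DataFrame  # columns: marker, chrom, pos_cm

    def __post_init__(self):
        t = self.table
        required = {"marker", "chrom", "pos_cm"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicated marker names: {dup}")
        for c, sub in t.groupby("chrom", sort=False):
            pos = sub["pos_cm"].to_numpy(float)
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted on chromosome {c}")
            if np.any(pos < 0):
                raise ValueError(f"negative cM position on chromosome {c}")
        self.table = t.reset_index(drop=True)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.table["chrom"]))

    @property
    def markers(self) -> list:
        return self.table["marker"].tolist()

    def chrom_slice(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def positions(self, chrom) -> np.ndarray:
        return self.chrom_slice(chrom)["pos_cm"].to_numpy(float)


@dataclass
class GenotypeMatrix:
    """Lines x markers matrix of codes in {-1, +1, nan}; marker order must
    match the linkage map it is used with."""

    lines: list
    markers: list
    values: np.ndarray  # float, nan = missing

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (len(self.lines), len(self.markers)):
            raise ValueError("genotype matrix shape does not match line/marker ids")
        ok = np.isnan(v) | (v == -1) | (v == 1)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid genotype code {v[tuple(bad)]} at line "
                f"{self.lines[bad[0]]}, marker {self.markers[bad[1]]}; "
                "RIL codes are -1/+1/NA (no heterozygotes)"
            )
        self.values = v

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lines, columns=self.markers)


@dataclass
class DosageMatrix:
    """Lines x positions matrix of posterior expected codes in [-1, +1]."""

    lines: list
    positions: pd.DataFrame  # columns: name, chrom, pos_cm
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if not np.all(np.isfinite(v)):
            raise ValueError("dosages must be finite")
        if np.any(np.abs(v) > 1 + 1e-9):
            raise ValueError("dosages must lie in [-1, +1]")
        self.values = np.clip(v, -1.0, 1.0)

    def column(self, name) -> np.ndarray:
        idx = self.positions.index[self.positions["name"] == name]
        if len(idx) == 0:
            raise KeyError(f"position {name!r} not in dosage matrix")
        return self.values[:, idx[0]]


def haldane_r(d) -> np.ndarray | float:
    """Haldane map function: cM distance -> recombination fraction.

    r = (1 - exp(-2 d / 100)) / 2, in [0, 0.5).
    """
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0
    return float(r) if r.ndim == 0 else r


def ril_r(r) -> np.ndarray | float:
    """Meiotic recombination fraction -> expected fraction between fixed
    selfed-RIL genotypes: R = 2r / (1 + 2r)."""
    r = np.asarray(r, float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5]")
    R = 2.0 * r / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


def _forward_backward(obs: np.ndarray, rec: np.ndarray, error_rate: float) -> np.ndarray:
    """Vectorized 2-state forward-backward.

    obs: (n_lines, m) in {-1, +1, nan}; rec: (m-1,) switch probabilities.
    Returns dosage (n_lines, m) = P(state +1) - P(state -1).
    State order: [J (-1), C (+1)]; uniform prior at the chromosome start.
    """
    n, m = obs.shape
    e = np.ones((n, m, 2))
    isC = obs == 1
    isJ = obs == -1
    e[isJ, 0] = 1 - error_rate
    e[isJ, 1] = error_rate
    e[isC, 0] = error_rate
    e[isC, 1] = 1 - error_rate
    rec = np.clip(rec, _R_FLOOR, 0.5)

    alpha = np.empty((n, m, 2))
    a = 0.5 * e[:, 0]
    a /= a.sum(axis=1, keepdims=True)
    alpha[:, 0] = a
    for j in range(1, m):
        r = rec[j - 1]
        stay, sw = 1 - r, r
        a = np.column_stack(
            (a[:, 0] * stay + a[:, 1] * sw, a[:, 0] * sw + a[:, 1] * stay)
        ) * e[:, j]
        a /= a.sum(axis=1, keepdims=True)
        alpha[:, j] = a

    b = np.ones((n, 2))
    post = np.empty((n, m, 2))
    post[:, m - 1] = alpha[:, m - 1]
    for j in range(m - 2, -1, -1):
        r = rec[j]
        stay, sw = 1 - r, r
        eb = e[:, j + 1] * b
        b = np.column_stack(
            (stay * eb[:, 0] + sw * eb[:, 1], sw * eb[:, 0] + stay * eb[:, 1])
        )
        b /= b.sum(axis=1, keepdims=True)
        p = alpha[:, j] * b
        p /= p.sum(axis=1, keepdims=True)
        post[:, j] = p
    return post[:, :, 1] - post[:, :, 0]


def impute_hmm(
    G: GenotypeMatrix, linkage_map: LinkageMap, error_rate: float = 0.005
) -> DosageMatrix:
    """Impute missing genotypes as posterior expected dosages.

    Per line and chromosome a two-state HMM is run forward-backward; the
    transition switch probability between adjacent markers is
    ``haldane_r`` of their cM distance, the emission matches the hidden state
    with probability ``1 - error_rate``, and missing calls are uninformative.
    A fully missing chromosome yields dosage 0 everywhere (uniform prior).
    """
    if not 0 <= error_rate <= 0.2:
        raise ValueError("error_rate must be in [0, 0.2]")
    if list(G.markers) != list(linkage_map.markers):
        raise ValueError("genotype marker order does not match the map")
    out = np.empty_like(G.values)
    col = 0
    for chrom in linkage_map.chromosomes:
        sub = linkage_map.chrom_slice(chrom)
        m = len(sub)
        obs = G.values[:, col : col + m]
        if np.isnan(obs).all():
            warnings.warn(f"chromosome {chrom} fully missing; dosages set to 0")
            out[:, col : col + m] = 0.0
        else:
            rec = haldane_r(np.diff(sub["pos_cm"].to_numpy(float)))
            eff_err = max(error_rate, 0.0)
            out[:, col : col + m] = _forward_backward(obs, rec, eff_err)
            allmiss = np.isnan(obs).all(axis=1)
            if allmiss.any():
                warnings.warn(
                    f"{int(allmiss.sum())} lines fully missing on chromosome "
                    f"{chrom}; their dosages set to 0"
                )
                out[allmiss, col : col + m] = 0.0
        col += m
    pos = linkage_map.table.rename(columns={"marker": "name"})[["name", "chrom", "pos_cm"]]
    return DosageMatrix(lines=list(G.lines), positions=pos.copy(), values=out)


def pseudomarker_dosages(
    G: GenotypeMatrix,
    linkage_map: LinkageMap,
    step: float = 1.0,
    error_rate: float = 0.0,
) -> DosageMatrix:
    """Expected dosages on a cM grid (union of markers and ``step``-spaced
    pseudomarkers), for interval mapping between markers.

    Pseudomarker positions enter the same forward-backward recursion as
    markers with an uninformative emission, so a grid point's dosage is the
    exact conditional expectation given all markers on the chromosome.  With
    complete data and ``error_rate`` 0 the value at a marker equals its code.
    """
    if step <= 0:
        raise ValueError("grid step must be positive")
    if list(G.markers) != list(linkage_map.markers):
        raise ValueError("genotype marker order does not match the map")
    frames = []
    mats = []
    col = 0
    for chrom in linkage_map.chromosomes:
        sub = linkage_map.chrom_slice(chrom)
        m = len(sub)
        if m == 0:
            warnings.warn(f"chromosome {chrom} has no markers; skipped")
            continue
        mpos = sub["pos_cm"].to_numpy(float)
        lo, hi = mpos.min(), mpos.max()
        grid = np.arange(lo, hi + 1e-9, step)
        allpos = np.unique(np.concatenate([mpos, grid]))
        # observation matrix over the augmented grid
        obs = np.full((G.n_lines, len(allpos)), np.nan)
        names = [f"c{chrom}_{p:.2f}" for p in allpos]
        midx = np.searchsorted(allpos, mpos)
        obs[:, midx] = G.values[:, col : col + m]
        for k, j in enumerate(midx):
            names[j] = sub["marker"].iloc[k]
        rec = haldane_r(np.diff(allpos))
        mats.append(_forward_backward(obs, rec, max(error_rate, 0.0)))
        frames.append(
            pd.DataFrame({"name": names, "chrom": chrom, "pos_cm": allpos})
        )
        col += m
    pos = pd.concat(frames, ignore_index=True)
    values = np.hstack(mats)
    values[~np.isfinite(values)] = 0.0
    return DosageMatrix(lines=list(G.lines), positions=pos, values=values)
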