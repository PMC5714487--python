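"""Synthetic data with the structure the analysis assumes.

Generates linkage maps, fully homozygous RIL genotypes (Markov chain along
each chromosome with Haldane switch probabilities), per-site daily weather
from seasonal site profiles, and plot-level flowering-time phenotypes from a
generative QTL-EC truth model.  A :class:`TruthRecord` stores every draw so
parameter-recovery tests can compare estimates against the generating values.

The default five site profiles emulate a multi-environment bean trial with
contrasting photoperiod (roughly 11.5-15.9 h), minimum temperature (13-19
deg C), maximum temperature (25-32 deg C) and solar radiation, i.e. two
near-equatorial sites at different altitudes, a Caribbean winter site, a
subtropical spring site and a high-latitude summer site.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, LinkageMap, haldane_r
from .ecmodel import DailyWeather, window_ec_means, _fixed_point

__all__ = [
    "SiteProfile",
    "TruthModel",
    "TruthRecord",
    "simulate_map",
    "simulate_ril_genotypes",
    "simulate_site_weather",
    "simulate_line_site_tf",
    "simulate_trial",
    "default_site_profiles",
    "default_truth_model",
]


@dataclass
class SiteProfile:
    """Seasonal weather summary for one trial site."""

    site: str
    latitude: float  # degrees, [-90, 90]
    sowing_doy: int  # day of year, 1..365
    n_days: int = 160  # length of the daily series
    tmin_mean: float = 16.0  # deg C, seasonal mean at mid-season
    tmax_mean: float = 28.0
    temp_amplitude: float = 0.0  # deg C, seasonal half-range over the series
    temp_noise_sd: float = 2.5  # deg C, day-to-day noise
    srad_mean: float = 18.0  # MJ m^-2 d^-1
    srad_sd: float = 4.0

    def __post_init__(self):
        if abs(self.latitude) > 90:
            raise ValueError("latitude out of range")
        if self.tmax_mean <= self.tmin_mean:
            raise ValueError("Tmax mean must exceed Tmin mean")
        if self.n_days < 120:
            raise ValueError("weather series must cover at least 120 days")


@dataclass
class TruthModel:
    """Generative parameters for a simulated trial.

    QTL effects are days of TF per +1-coded allele; EC effects are days per
    unit of the centered covariate.  Spatial components are variances (d^2)
    of plot-design effects; ``plot_sd`` is the plot-level error sd (d).
    """

    intercept: float
    centering: dict
    ec_main: dict
    qtl_main: dict
    qtl_ec: dict = field(default_factory=dict)
    epistasis: dict = field(default_factory=dict)
    residual_sd: float = 1.0  # line x site deviation (d)
    line_sd: float = 1.5  # polygenic line effect shared across sites (d)
    var_rep: float = 0.5  # replicate variance (d^2)
    var_rep_row: float = 0.4
    var_rep_col: float = 0.4
    plot_sd: float = 1.5  # plot error sd (d)

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual sd must be positive")

    def check_markers(self, linkage_map: LinkageMap):
        known = set(linkage_map.markers)
        referenced = set(self.qtl_main) | {q for q, _ in self.qtl_ec} | {
            m for pair in self.epistasis for m in pair
        }
        missing = referenced - known
        if missing:
            raise ValueError(f"truth model references unknown markers: {sorted(missing)}")

    # same contract as QtlEcModel.linear_predictor so the generative and
    # inferential EC windows agree
    def linear_predictor(self, ecs: pd.DataFrame, dosages: pd.DataFrame) -> np.ndarray:
        out = np.full(len(dosages), float(self.intercept))
        for e, b in self.ec_main.items():
            out += b * (ecs[e].to_numpy(float) - self.centering[e])
        for q, a in self.qtl_main.items():
            out += a * dosages[q].to_numpy(float)
        for (q, e), c in self.qtl_ec.items():
            out += c * dosages[q].to_numpy(float) * (ecs[e].to_numpy(float) - self.centering[e])
        for (q1, q2), d in self.epistasis.items():
            out += d * dosages[q1].to_numpy(float) * dosages[q2].to_numpy(float)
        return out


@dataclass
class TruthRecord:
    """Everything drawn during a simulation, for recovery tests."""

    truth: TruthModel
    seed: int
    true_tf: pd.DataFrame  # line, site, tf_true, converged
    ecs: pd.DataFrame  # line, site + EC columns at the realized window

    def to_json(self) -> str:
        t = asdict(self.truth)
        t["qtl_ec"] = {f"{q}|{e}": v for (q, e), v in self.truth.qtl_ec.items()}
        t["epistasis"] = {f"{a}|{b}": v for (a, b), v in self.truth.epistasis.items()}
        return json.dumps(
            {
                "truth": t,
                "seed": self.seed,
                "true_tf": self.true_tf.to_dict(orient="list"),
                "ecs": self.ecs.to_dict(orient="list"),
            },
            indent=1,
            sort_keys=True,
        )

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        t = d["truth"]
        t["qtl_ec"] = {tuple(k.split("|")): v for k, v in t["qtl_ec"].items()}
        t["epistasis"] = {tuple(k.split("|")): v for k, v in t["epistasis"].items()}
        return cls(
            truth=TruthModel(**t),
            seed=d["seed"],
            true_tf=pd.DataFrame(d["true_tf"]),
            ecs=pd.DataFrame(d["ecs"]),
        )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_map(
    n_chrom: int, markers_per_chrom: int, chrom_length: float, seed: int
) -> LinkageMap:
    """Random marker map: per chromosome the first marker sits at 0 cM, the
    last at ``chrom_length``, and the interior markers at sorted uniform
    positions."""
    if n_chrom < 1 or markers_per_chrom < 2 or chrom_length <= 0:
        raise ValueError("need n_chrom >= 1, markers_per_chrom >= 2, chrom_length > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chrom + 1):
        interior = np.sort(rng.uniform(0, chrom_length, markers_per_chrom - 2))
        pos = np.concatenate([[0.0], interior, [chrom_length]])
        for i, p in enumerate(pos, 1):
            rows.append({"marker": f"M{c}_{i}", "chrom": c, "pos_cm": float(p)})
    return LinkageMap(pd.DataFrame(rows))


def simulate_ril_genotypes(
    linkage_map: LinkageMap, n_lines: int, seed: int
) -> GenotypeMatrix:
    """Fully homozygous RIL genotypes: per chromosome a two-state Markov
    chain along markers with switch probability ``haldane_r`` of the
    inter-marker distance (distances read as RIL-map distances); the first
    allele is Bernoulli(1/2) and chromosomes are independent."""
    if n_lines < 1:
        raise ValueError("need at least one line")
    rng = np.random.default_rng(seed)
    blocks = []
    for chrom in linkage_map.chromosomes:
        pos = linkage_map.positions(chrom)
        m = len(pos)
        r = haldane_r(np.diff(pos))
        state = rng.integers(0, 2, size=n_lines)
        cols = [state.copy()]
        for j in range(m - 1):
            flip = rng.random(n_lines) < r[j]
            state = np.where(flip, 1 - state, state)
            cols.append(state.copy())
        blocks.append(np.column_stack(cols))
    values = np.hstack(blocks) * 2.0 - 1.0
    lines = [f"RIL{i + 1:04d}" for i in range(n_lines)]
    return GenotypeMatrix(lines=lines, markers=linkage_map.markers, values=values)


def simulate_site_weather(profile: SiteProfile, seed: int) -> DailyWeather:
    """Daily Tmin/Tmax/Srad for one site.

    Temperatures follow a seasonal sinusoid keyed to day-of-year (peak at the
    northern-summer solstice) plus shared day-to-day noise; Tmax is kept at
    least 0.5 deg above Tmin.  Srad is Gaussian about its mean, floored just
    above zero.
    """
    rng = np.random.default_rng(seed)
    doy = (profile.sowing_doy - 1 + np.arange(profile.n_days)) % 365 + 1
    season = np.sin(2 * np.pi * (doy - 81) / 365.0)  # +1 near DOY 172
    if profile.latitude < 0:
        season = -season
    # Persistent (week-scale) cloudiness drives correlated anomalies: cloudy
    # spells reduce Tmax and solar radiation but insulate nights (higher
    # Tmin), so the three series are coupled the way weather systems couple
    # them rather than through one shared noise stream.
    phi = 0.85
    eps = rng.standard_normal(profile.n_days)
    cloud = np.empty(profile.n_days)
    cloud[0] = eps[0]
    for t in range(1, profile.n_days):
        cloud[t] = phi * cloud[t - 1] + np.sqrt(1 - phi**2) * eps[t]
    tmin = (
        profile.tmin_mean
        + profile.temp_amplitude * season
        + profile.temp_noise_sd * (0.45 * cloud + 0.6 * rng.standard_normal(profile.n_days))
    )
    tmax = (
        profile.tmax_mean
        + profile.temp_amplitude * season
        + profile.temp_noise_sd * (-0.6 * cloud + 0.6 * rng.standard_normal(profile.n_days))
    )
    tmax = np.maximum(tmax, tmin + 0.5)
    srad = profile.srad_mean + profile.srad_sd * (
        -0.5 * cloud + 0.6 * rng.standard_normal(profile.n_days)
    )
    srad = np.maximum(srad, 0.1)
    return DailyWeather(
        site=profile.site,
        latitude=profile.latitude,
        sowing_doy=profile.sowing_doy,
        tmin=tmin,
        tmax=tmax,
        srad=srad,
    )


def default_site_profiles() -> list:
    """Five contrasting trial sites (subtropical spring, high-latitude
    summer, two equatorial sites at different altitude, Caribbean winter)."""
    return [
        # base means are chosen so the realized sowing->flowering window
        # averages land near the emulated trial climate (seasonal ramp shifts
        # them by amplitude x mean seasonal factor over the window)
        SiteProfile("CIT", latitude=29.65, sowing_doy=90, tmin_mean=14.0, tmax_mean=28.0, temp_amplitude=8.0, srad_mean=20.6),
        SiteProfile("ND", latitude=47.00, sowing_doy=152, tmin_mean=10.2, tmax_mean=24.2, temp_amplitude=3.0, srad_mean=21.0),
        SiteProfile("PAL", latitude=3.48, sowing_doy=200, tmin_mean=18.1, tmax_mean=27.1, temp_amplitude=1.5, srad_mean=13.8),
        SiteProfile("POP", latitude=2.42, sowing_doy=200, tmin_mean=12.1, tmax_mean=24.1, temp_amplitude=1.5, srad_mean=15.0),
        SiteProfile("PR", latitude=18.47, sowing_doy=32, tmin_mean=22.5, tmax_mean=32.5, temp_amplitude=5.0, srad_mean=21.5),
    ]


#: canonical QTL architecture: (id, chrom, pos_cm, main effect d per +1 allele)
_QTL_LAYOUT = [
    ("TF1", 1, 22.1, -1.4),
    ("TF2", 1, 42.1, -2.28),
    ("TF3", 1, 58.8, 2.0),
    ("TF4", 1, 70.0, -0.6),
    ("TF5", 3, 38.2, 0.3),
    ("TF6", 3, 49.2, -1.0),
    ("TF7", 4, 42.2, 1.0),
    ("TF8", 6, 31.3, 0.5),
    ("TF9", 7, 11.7, 1.0),
    ("TF10", 7, 98.7, 0.55),
    ("TF11", 11, 2.1, -0.5),
    ("TF12", 11, 9.3, 0.3),
]

#: QTL x EC interaction coefficients keyed by QTL id (d per +1 allele per
#: centered-EC unit)
_QTL_EC_LAYOUT = {
    ("TF2", "Tmin"): -0.25,
    ("TF3", "DAY"): 0.8,
    ("TF3", "Tmin"): -0.2,
    ("TF5", "Tmax"): 0.2,
    ("TF7", "DAY"): 0.3,
    ("TF12", "Srad"): 0.08,
    ("TF12", "DAY"): 0.15,
}


def default_truth_model(linkage_map: LinkageMap, **overrides) -> tuple:
    """Truth model with the canonical 12-QTL, 4-EC architecture, anchored to
    the nearest map marker for each QTL.

    Returns (TruthModel, qtl_table) where qtl_table maps QTL ids to their
    assigned markers (columns: qtl, marker, chrom, pos_cm, effect,
    interacts)."""
    rows = []
    qtl_main = {}
    marker_of = {}
    for qid, chrom, pos, eff in _QTL_LAYOUT:
        sub = linkage_map.chrom_slice(chrom)
        if len(sub) == 0:
            raise ValueError(f"map has no chromosome {chrom} for QTL {qid}")
        i = (sub["pos_cm"] - pos).abs().idxmin()
        marker = linkage_map.table.loc[i, "marker"]
        if marker in marker_of.values():
            raise ValueError(f"map too sparse: QTL {qid} collides with another QTL marker")
        marker_of[qid] = marker
        qtl_main[marker] = eff
        rows.append(
            {
                "qtl": qid,
                "marker": marker,
                "chrom": chrom,
                "pos_cm": float(linkage_map.table.loc[i, "pos_cm"]),
                "effect": eff,
                "interacts": any(q == qid for q, _ in _QTL_EC_LAYOUT),
            }
        )
    truth = TruthModel(
        intercept=44.18,
        centering={"DAY": 12.37, "Srad": 18.218, "Tmin": 16.128, "Tmax": 27.458},
        ec_main={"DAY": 4.03, "Srad": -0.30, "Tmin": -0.61, "Tmax": -1.36},
        qtl_main=qtl_main,
        qtl_ec={(marker_of[q], e): v for (q, e), v in _QTL_EC_LAYOUT.items()},
        epistasis={(marker_of["TF1"], marker_of["TF2"]): -0.4},
        **overrides,
    )
    truth.check_markers(linkage_map)
    return truth, pd.DataFrame(rows)


def simulate_line_site_tf(
    truth: TruthModel,
    genotypes: GenotypeMatrix,
    weather_by_site: dict,
    seed: int,
) -> tuple:
    """Line x site true flowering times from the truth model.

    Per line and site the true TF solves the same fixed point used at
    prediction time: TF = truth(genotype, ECs averaged over [sowing, TF)) +
    line effect + line x site deviation.  Non-convergent lines are flagged.

    Returns (records DataFrame, TruthRecord); records carry one row per
    line x site with columns line, site, tf, the EC values at the realized
    window, one dosage column per truth marker, and ``converged``.
    """
    rng = np.random.default_rng(seed)
    gdf = genotypes.to_frame()
    markers = sorted(
        set(truth.qtl_main) | {q for q, _ in truth.qtl_ec} | {m for p in truth.epistasis for m in p}
    )
    dos = gdf[markers].reset_index(drop=True)
    n = len(dos)
    g_line = truth.line_sd * rng.standard_normal(n)
    frames = []
    for site, weather in weather_by_site.items():
        e_ls = truth.residual_sd * rng.standard_normal(n)
        tf, _, conv, _ = _fixed_point(truth, dos, weather, offset=g_line + e_ls)
        if not conv.all():
            warnings.warn(
                f"{int((~conv).sum())} lines did not reach a fixed point at site {site}; flagged"
            )
        ecs = window_ec_means(weather, np.clip(np.round(tf), 1, weather.n_days))
        frame = pd.DataFrame({"line": genotypes.lines, "site": site, "tf": tf})
        frame = pd.concat([frame, ecs.reset_index(drop=True)], axis=1)
        for mk in markers:
            frame[mk] = dos[mk].to_numpy()
        frame["converged"] = conv
        frames.append(frame)
    records = pd.concat(frames, ignore_index=True)
    rec = TruthRecord(
        truth=truth,
        seed=seed,
        true_tf=records[["line", "site", "tf", "converged"]].rename(columns={"tf": "tf_true"}),
        ecs=records[["line", "site"] + list(window_ec_means(list(weather_by_site.values())[0], [45]).columns)],
    )
    return records, rec


def simulate_trial(
    linkage_map: LinkageMap,
    genotypes: GenotypeMatrix,
    truth: TruthModel,
    sites: list,
    n_reps: int = 3,
    n_rows: int | None = None,
    n_cols: int | None = None,
    seed: int = 0,
) -> tuple:
    """Full plot-level trial: true line x site TF plus replicate, row-within-
    replicate, column-within-replicate and plot-error noise on a randomized
    row-column layout at every site.

    Returns (PlotTable DataFrame with columns site, rep, row, col, line,
    tf_days, and the TruthRecord).  Non-convergent line x site records are
    excluded from the plot table with a warning.
    """
    truth.check_markers(linkage_map)
    rng = np.random.default_rng(seed)
    n = genotypes.n_lines
    if n_rows is None:
        n_rows = int(np.ceil(np.sqrt(n)))
    if n_cols is None:
        n_cols = int(np.ceil(n / n_rows))
    if n_rows * n_cols < n:
        raise ValueError("row-column grid too small for the number of lines")
    weather = {p.site: simulate_site_weather(p, int(rng.integers(2**31))) for p in sites}
    records, truth_rec = simulate_line_site_tf(truth, genotypes, weather, int(rng.integers(2**31)))
    dropped = int((~records["converged"]).sum())
    if dropped:
        warnings.warn(f"excluding {dropped} non-convergent line x site records from plots")
    rows = []
    for p in sites:
        sub = records[(records["site"] == p.site) & records["converged"]]
        tf_true = dict(zip(sub["line"], sub["tf"]))
        for rep in range(1, n_reps + 1):
            b = np.sqrt(truth.var_rep) * rng.standard_normal()
            br = np.sqrt(truth.var_rep_row) * rng.standard_normal(n_rows)
            bc = np.sqrt(truth.var_rep_col) * rng.standard_normal(n_cols)
            cells = rng.permutation(n_rows * n_cols)[: len(sub)]
            for (line, cell) in zip(sub["line"], cells):
                r, c = divmod(int(cell), n_cols)
                rows.append(
                    {
                        "site": p.site,
                        "rep": rep,
                        "row": r + 1,
                        "col": c + 1,
                        "line": line,
                        "tf_days": tf_true[line]
                        + b
                        + br[r]
                        + bc[c]
                        + truth.plot_sd * rng.standard_normal(),
                    }
                )
    plots = pd.DataFrame(rows)
    truth_rec.weather = weather
    return plots, truth_rec
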