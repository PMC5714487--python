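"""Environmental covariates and the QTL-EC predictive model.

Flowering time (TF, days from sowing) is modeled as a linear function of
marker dosages at mapped QTL and of environmental covariates (ECs) averaged
over each line's own vegetative window, sowing to flowering:

    TF_i = mu + sum_e b_e (EC_ei - EC_e.) + sum_q a_q X_iq
         + sum_(q,e) c_qe X_iq (EC_ei - EC_e.) + sum_(q,q') d X_iq X_iq' + eps

ECs are centered at stored population constants so the intercept is the
population-mean TF.  Because the averaging window ends at flowering, which is
what the model predicts, prediction uses a fixed-point iteration on the
window length; training uses observed flowering dates, so no iteration is
needed there.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import mixedmodel as mm

__all__ = [
    "EC_NAMES",
    "DEFAULT_EC_PRIORITY",
    "DailyWeather",
    "day_length",
    "compute_line_ecs",
    "window_ec_means",
    "spearman_screen",
    "QtlEcModel",
    "EvalReport",
    "FixedPointError",
    "fit_qtl_ec_model",
    "predict_tf",
    "evaluate_predictions",
    "loso_cv",
]

EC_NAMES = ["DAY", "NIGHT", "Srad", "Tmin", "Tavg", "Tmax", "DTavg", "NTavg"]
#: greedy admission order for the collinearity screen; front-loads the four
#: covariates with the clearest biology (photoperiod, radiation, temperature
#: extremes)
DEFAULT_EC_PRIORITY = ["DAY", "Srad", "Tmin", "Tmax", "Tavg", "DTavg", "NTavg", "NIGHT"]

#: weight of Tmax in the daytime mean temperature (NTavg uses 1 - this)
DAYTIME_TMAX_WEIGHT = 0.75


class FixedPointError(RuntimeError):
    """Prediction window iteration failed to converge; carries trajectory."""

    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory


def day_length(latitude: float, day_of_year) -> np.ndarray | float:
    """Astronomical day length (hours) from latitude and day of year.

    Solar declination delta = 23.45 sin(2 pi (284 + DOY) / 365) degrees;
    hour angle omega = arccos(-tan(phi) tan(delta)); day length = 24 omega/pi.
    The arccos argument is clamped (with a warning) outside +-1, so polar
    day/night degenerate to 24 h / 0 h.
    """
    if np.any(np.abs(latitude) > 90):
        raise ValueError("latitude must be within [-90, 90] degrees")
    doy = np.asarray(day_of_year, float)
    delta = np.deg2rad(23.45 * np.sin(2 * np.pi * (284 + doy) / 365.0))
    arg = -np.tan(np.deg2rad(latitude)) * np.tan(delta)
    if np.any(arg < -1) or np.any(arg > 1):
        warnings.warn("polar day/night regime; day length clamped to 0/24 h")
    omega = np.arccos(np.clip(arg, -1.0, 1.0))
    h = 24.0 * omega / np.pi
    return float(h) if h.ndim == 0 else h


@dataclass
class DailyWeather:
    """Daily weather series for one site, starting at the sowing date.

    ``sowing_doy`` is the day-of-year of sowing (1..365); index t of the
    arrays is t days after sowing.
    """

    site: str
    latitude: float
    sowing_doy: int
    tmin: np.ndarray
    tmax: np.ndarray
    srad: np.ndarray

    def __post_init__(self):
        self.tmin = np.asarray(self.tmin, float)
        self.tmax = np.asarray(self.tmax, float)
        self.srad = np.asarray(self.srad, float)
        n = len(self.tmin)
        if len(self.tmax) != n or len(self.srad) != n:
            raise ValueError("weather series lengths differ")
        if np.any(self.tmax <= self.tmin):
            raise ValueError("Tmax must exceed Tmin on every day")
        if not 1 <= self.sowing_doy <= 365:
            raise ValueError("sowing day-of-year must be in 1..365")

    @property
    def n_days(self) -> int:
        return len(self.tmin)

    @property
    def doy(self) -> np.ndarray:
        return (self.sowing_doy - 1 + np.arange(self.n_days)) % 365 + 1

    def day_hours(self) -> np.ndarray:
        return np.asarray(day_length(self.latitude, self.doy), float)

    def daily_ec_frame(self) -> pd.DataFrame:
        day = self.day_hours()
        w = DAYTIME_TMAX_WEIGHT
        return pd.DataFrame(
            {
                "DAY": day,
                "NIGHT": 24.0 - day,
                "Srad": self.srad,
                "Tmin": self.tmin,
                "Tavg": (self.tmin + self.tmax) / 2.0,
                "Tmax": self.tmax,
                "DTavg": w * self.tmax + (1 - w) * self.tmin,
                "NTavg": (1 - w) * self.tmax + w * self.tmin,
            }
        )


def window_ec_means(weather: DailyWeather, windows) -> pd.DataFrame:
    """Mean of each EC over the first ``w`` days after sowing, for each
    window length in ``windows`` (whole days, 1..n_days)."""
    w = np.asarray(np.round(windows), int)
    if np.any(w < 1):
        raise ValueError("window length must be at least 1 day")
    if np.any(w > weather.n_days):
        raise ValueError(
            f"window of {int(w.max())} d exceeds weather coverage "
            f"({weather.n_days} d) at site {weather.site}"
        )
    daily = weather.daily_ec_frame()
    csum = np.vstack([np.zeros(daily.shape[1]), np.cumsum(daily.to_numpy(), axis=0)])
    means = csum[w] / w[:, None]
    return pd.DataFrame(means, columns=daily.columns)


def compute_line_ecs(weather: DailyWeather, tf_days) -> pd.DataFrame:
    """ECs averaged sowing -> flowering for one or more flowering times
    (days after sowing).  Scalar input returns a one-row frame."""
    scalar = np.isscalar(tf_days)
    out = window_ec_means(weather, np.atleast_1d(tf_days))
    return out if not scalar else out


def spearman_screen(
    ec_table: pd.DataFrame,
    rho_max: float = 0.5,
    priority: list | None = None,
):
    """Greedy collinearity screen on Spearman rank correlations.

    ECs are admitted in ``priority`` order; a candidate is rejected when its
    absolute rank correlation with any already admitted EC is >= ``rho_max``.
    Returns (selected list, full correlation DataFrame).
    """
    priority = list(priority or DEFAULT_EC_PRIORITY)
    cols = [c for c in priority if c in ec_table.columns]
    if len(ec_table) < 3:
        raise ValueError("need at least 3 records for the correlation screen")
    usable = []
    for c in cols:
        if ec_table[c].nunique() <= 1:
            warnings.warn(f"EC {c} is constant; excluded from screen")
        else:
            usable.append(c)
    rho = pd.DataFrame(
        stats.spearmanr(ec_table[usable].to_numpy())[0]
        if len(usable) > 2
        else np.corrcoef(ec_table[usable].rank().to_numpy().T),
        index=usable,
        columns=usable,
    )
    selected = []
    for c in usable:
        if all(abs(rho.loc[c, s]) < rho_max for s in selected):
            selected.append(c)
    return selected, rho


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------


@dataclass
class QtlEcModel:
    """The fitted QTL-EC linear model: all coefficients plus the EC centering
    constants needed to apply it to new weather."""

    intercept: float
    centering: dict  # EC -> centering constant
    ec_main: dict  # EC -> coefficient (d per unit of centered EC)
    qtl_main: dict  # marker -> coefficient (d per +1 allele)
    qtl_ec: dict = field(default_factory=dict)  # (marker, EC) -> coefficient
    epistasis: dict = field(default_factory=dict)  # (m1, m2) -> coefficient
    se: dict = field(default_factory=dict)  # coefficient name -> SE
    line_var: float = 0.0
    resid_var: float = 0.0

    def linear_predictor(self, ecs: pd.DataFrame, dosages: pd.DataFrame) -> np.ndarray:
        """Evaluate the model at EC records and marker dosages (row-aligned)."""
        n = len(dosages)
        out = np.full(n, float(self.intercept))
        for e, b in self.ec_main.items():
            out += b * (ecs[e].to_numpy(float) - self.centering[e])
        for q, a in self.qtl_main.items():
            out += a * dosages[q].to_numpy(float)
        for (q, e), c in self.qtl_ec.items():
            out += c * dosages[q].to_numpy(float) * (
                ecs[e].to_numpy(float) - self.centering[e]
            )
        for (q1, q2), d in self.epistasis.items():
            out += d * dosages[q1].to_numpy(float) * dosages[q2].to_numpy(float)
        return out

    @property
    def n_params(self) -> int:
        return 1 + len(self.ec_main) + len(self.qtl_main) + len(self.qtl_ec) + len(self.epistasis)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = {
            "intercept": self.intercept,
            "centering": self.centering,
            "ec_effects": self.ec_main,
            "qtl_effects": self.qtl_main,
            "interactions": {f"{q}|{e}": v for (q, e), v in self.qtl_ec.items()},
            "epistasis": {f"{a}|{b}": v for (a, b), v in self.epistasis.items()},
            "se": self.se,
            "line_var": self.line_var,
            "resid_var": self.resid_var,
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "QtlEcModel":
        d = json.loads(text)
        return cls(
            intercept=d["intercept"],
            centering=d["centering"],
            ec_main=d["ec_effects"],
            qtl_main=d["qtl_effects"],
            qtl_ec={tuple(k.split("|")): v for k, v in d["interactions"].items()},
            epistasis={tuple(k.split("|")): v for k, v in d["epistasis"].items()},
            se=d.get("se", {}),
            line_var=d.get("line_var", 0.0),
            resid_var=d.get("resid_var", 0.0),
        )

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "QtlEcModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class EvalReport:
    rmse: float
    adj_r2: float
    r2: float
    n: int
    n_params: int
    per_site: pd.DataFrame | None = None
    extrapolated_ecs: list = field(default_factory=list)

    @property
    def interpolative(self) -> bool:
        return not self.extrapolated_ecs


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_qtl_ec_model(
    records: pd.DataFrame,
    qtl_markers: list,
    interacting: list,
    epistatic_pairs: tuple = (),
    selected_ecs: list | None = None,
    alpha: float = 0.05,
    rho_max: float = 0.5,
    priority: list | None = None,
    centering: dict | None = None,
) -> QtlEcModel:
    """Fit the QTL-EC model to line x site records.

    ``records`` has one row per line x site with columns ``line``, ``site``,
    ``tf``, the eight EC columns, and one dosage column per QTL marker.

    For every QTL flagged as site-interacting, each screened EC is tested as
    its interaction partner (Wald, within a model that retains the site
    factor); significant interactions are kept.  EC main effects are then
    added, the site factor is dropped, and non-significant EC mains are
    removed from the final fit.
    """
    if records["site"].nunique() < 2:
        raise ValueError("QTL-EC model needs records from at least 2 sites")
    if selected_ecs is None:
        selected_ecs, _ = spearman_screen(records[EC_NAMES], rho_max, priority)
    df = records.copy()
    # centering defaults to across-record means; fixed constants may be
    # supplied to keep a model comparable with an external parameterization
    given = centering or {}
    centering = {e: float(given.get(e, df[e].mean())) for e in selected_ecs}
    for e in selected_ecs:
        df[f"c_{e}"] = df[e] - centering[e]

    # stage 1: test candidate QTL x EC interactions, one at a time, with the
    # site factor still standing in for unmodeled environment differences
    kept_int = []
    base_fixed = ["site"] + list(qtl_markers)
    for q in interacting:
        for e in selected_ecs:
            col = f"{q}__x__{e}"
            df[col] = df[q] * df[f"c_{e}"]
            spec = mm.ModelSpec(
                response="tf",
                fixed=base_fixed + [col],
                categorical={"site"},
                random=[mm.Iid("line")],
            )
            w = mm.wald_test(mm.fit_reml(spec, df), col)
            if w.pvalue < alpha:
                kept_int.append((q, e))

    # stage 2: replace the site factor by EC main effects
    for a, b in epistatic_pairs:
        df[f"{a}__x__{b}"] = df[a] * df[b]
    ec_cols = [f"c_{e}" for e in selected_ecs]
    int_cols = [f"{q}__x__{e}" for q, e in kept_int]
    epi_cols = [f"{a}__x__{b}" for a, b in epistatic_pairs]

    def _fit(ecs_in):
        fixed = [f"c_{e}" for e in ecs_in] + list(qtl_markers) + int_cols + epi_cols
        spec = mm.ModelSpec(
            response="tf", fixed=fixed, categorical=set(), random=[mm.Iid("line")]
        )
        return mm.fit_reml(spec, df)

    ecs_in = list(selected_ecs)
    fit = _fit(ecs_in)
    # one-at-a-time screening admits collinear interaction partners; prune
    # them jointly: drop the least significant interaction until all survive
    while int_cols:
        worst, worst_p = None, alpha
        for c in int_cols:
            p = mm.wald_test(fit, c).pvalue
            if p >= worst_p:
                worst, worst_p = c, p
        if worst is None:
            break
        int_cols.remove(worst)
        kept_int = [(q, e) for q, e in kept_int if f"{q}__x__{e}" != worst]
        fit = _fit(ecs_in)
    drop = [e for e in ecs_in if mm.wald_test(fit, f"c_{e}").pvalue >= alpha]
    if drop:
        ecs_in = [e for e in ecs_in if e not in drop]
        fit = _fit(ecs_in)

    beta = fit.beta
    se = fit.se
    model = QtlEcModel(
        intercept=float(beta["Intercept"]),
        centering={e: centering[e] for e in ecs_in},
        ec_main={e: float(beta[f"c_{e}"]) for e in ecs_in},
        qtl_main={q: float(beta[q]) for q in qtl_markers},
        qtl_ec={(q, e): float(beta[f"{q}__x__{e}"]) for q, e in kept_int},
        epistasis={(a, b): float(beta[f"{a}__x__{b}"]) for a, b in epistatic_pairs},
        se={name: float(se[name]) for name in beta.index},
        line_var=float(fit.vc.get("line", 0.0)),
        resid_var=float(fit.vc.get("residual", 0.0)),
    )
    # interactions may reference ECs dropped as mains; their centering
    # constants must still travel with the model
    for q, e in kept_int:
        if e not in model.centering:
            model.centering[e] = centering[e]
    return model


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def _fixed_point(
    model,
    dosages: pd.DataFrame,
    weather: DailyWeather,
    offset: np.ndarray | float = 0.0,
    init: float = 45.0,
    tol: float = 0.1,
    max_iter: int = 25,
):
    """Iterate TF -> EC window -> TF for a batch of genotypes at one site.

    Returns (tf, n_iter, converged_mask, trajectory).  ``offset`` adds a
    per-line constant (line effects during simulation)."""
    n = len(dosages)
    tf = np.full(n, float(init))
    traj = [tf.copy()]
    conv = np.zeros(n, bool)
    it = 0
    for it in range(1, max_iter + 1):
        w = np.clip(np.round(tf), 1, weather.n_days)
        ecs = window_ec_means(weather, w)
        new = model.linear_predictor(ecs, dosages) + offset
        new = np.clip(new, 1.0, float(weather.n_days))
        conv = np.abs(new - tf) < tol
        tf = new
        traj.append(tf.copy())
        if conv.all():
            break
    return tf, it, conv, traj


def predict_tf(
    model: QtlEcModel,
    genotype,
    weather: DailyWeather,
    init: float = 45.0,
    tol: float = 0.1,
    max_iter: int = 25,
):
    """Predict flowering time for one genotype at one site.

    ``genotype`` maps each model QTL marker to its dosage in [-1, +1].
    Returns (tf_days, n_iterations); raises :class:`FixedPointError` when the
    window iteration does not settle.
    """
    markers = set(model.qtl_main) | {q for q, _ in model.qtl_ec} | {
        m for pair in model.epistasis for m in pair
    }
    dos = (
        pd.DataFrame({q: [float(genotype[q])] for q in sorted(markers)})
        if markers
        else pd.DataFrame(index=[0])
    )
    tf, it, conv, traj = _fixed_point(model, dos, weather, 0.0, init, tol, max_iter)
    if not conv.all():
        raise FixedPointError(
            f"prediction window did not converge in {max_iter} iterations",
            trajectory=[float(t[0]) for t in traj],
        )
    return float(tf[0]), it


def evaluate_predictions(observed, predicted, n_params: int, site=None) -> EvalReport:
    """RMSE, squared Pearson correlation, and adjusted r^2 of predictions."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise ValueError("observed and predicted must be non-empty and paired")
    n = obs.size
    if n <= n_params + 1:
        raise ValueError("adjusted r^2 undefined: n <= n_params + 1")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2) if np.std(pred) > 0 and np.std(obs) > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    per_site = None
    if site is not None:
        rows = []
        for s, idx in pd.Series(range(n), index=site).groupby(level=0):
            i = idx.to_numpy()
            rows.append(
                {
                    "site": s,
                    "rmse": float(np.sqrt(np.mean((obs[i] - pred[i]) ** 2))),
                    "r2": float(np.corrcoef(obs[i], pred[i])[0, 1] ** 2)
                    if len(i) > 2 and np.std(pred[i]) > 0
                    else np.nan,
                    "n": len(i),
                }
            )
        per_site = pd.DataFrame(rows)
    return EvalReport(rmse=rmse, adj_r2=float(adj), r2=r2, n=n, n_params=n_params, per_site=per_site)


def loso_cv(
    records: pd.DataFrame,
    weather_by_site: dict,
    qtl_markers: list,
    interacting: list,
    epistatic_pairs: tuple = (),
    alpha: float = 0.05,
    selected_ecs: list | None = None,
) -> dict:
    """Leave-one-site-out cross-validation of the QTL-EC model.

    For each site the model is refit on the remaining sites (QTL set held
    fixed) and the held-out site is predicted through the window iteration
    with its own weather.  Emits an extrapolation warning when the held-out
    site's realized EC range falls outside the training range.
    Returns {site: EvalReport}.
    """
    sites = sorted(records["site"].unique())
    if len(sites) < 3:
        raise ValueError("leave-one-site-out needs at least 3 sites")
    out = {}
    for hold in sites:
        train = records[records["site"] != hold]
        test = records[records["site"] == hold]
        model = fit_qtl_ec_model(
            train,
            qtl_markers,
            interacting,
            epistatic_pairs,
            alpha=alpha,
            selected_ecs=selected_ecs,
        )
        extrap = []
        for e in model.centering:
            lo, hi = train[e].min(), train[e].max()
            if test[e].min() < lo - 1e-9 or test[e].max() > hi + 1e-9:
                extrap.append(e)
                warnings.warn(
                    f"holding out {hold}: EC {e} outside training range "
                    f"[{lo:.2f}, {hi:.2f}]; prediction is an extrapolation"
                )
        dos = test[list(model.qtl_main)].reset_index(drop=True)
        tf, _, conv, _ = _fixed_point(model, dos, weather_by_site[hold])
        if not conv.all():
            warnings.warn(
                f"{int((~conv).sum())} predictions did not converge for held-out {hold}"
            )
        rep = evaluate_predictions(test["tf"].to_numpy(), tf, model.n_params)
        rep.extrapolated_ecs = extrap
        out[hold] = rep
    return out
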