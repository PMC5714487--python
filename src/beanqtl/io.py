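"""CSV readers/writers and the flat-file pipeline configuration.

All tabular artifacts are plain CSV with documented headers; writers prepend
a ``#`` comment line carrying a config hash and the seed so every artifact
states its provenance.  Readers validate codes and cross-check marker sets
against the map, naming the offending rows or columns in their errors.

Formats
-------
genotypes.csv : line, then one column per marker with codes in {-1, 1, NA}
map.csv       : marker, chrom, pos_cm
phenotypes.csv: site, rep, row, col, line, tf_days
weather.csv   : site, latitude, sowing_doy, day, tmin_c, tmax_c, srad_mj_m2
                (day = days after sowing, 0-based)
config        : flat ``key = value`` lines; '#' starts a comment
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ecmodel import DailyWeather
from .genotypes import GenotypeMatrix, LinkageMap

__all__ = [
    "PipelineConfig",
    "read_config",
    "read_genotypes",
    "read_map",
    "read_phenotypes",
    "read_weather",
    "write_genotypes",
    "write_map",
    "write_phenotypes",
    "write_weather",
    "write_table",
    "read_table",
]


@dataclass
class PipelineConfig:
    """Parameters of a pipeline run; all stages read from this one object."""

    genotypes: str = "genotypes.csv"
    map: str = "map.csv"
    phenotypes: str = "phenotypes.csv"
    weather: str = "weather.csv"
    outdir: str = "out"
    seed: int = 1
    error_rate: float = 0.005
    scan_step: float = 1.0
    window: float = 5.0
    min_cofactor_distance: float = 50.0
    alpha: float = 0.05
    rho_max: float = 0.5
    min_sep: float = 10.0
    n_lines: int = 188
    n_chrom: int = 11
    markers_per_chrom: int = 47
    chrom_length: float = 85.0
    n_reps: int = 3
    extras: dict = field(default_factory=dict)

    _PATH_FIELDS = ("genotypes", "map", "phenotypes", "weather", "outdir", "extras")

    def digest(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        items = sorted(
            (k, str(v)) for k, v in vars(self).items() if k not in self._PATH_FIELDS
        )
        return hashlib.sha256(repr(items).encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"# beanqtl config={self.digest()} seed={self.seed}"


def read_config(path) -> PipelineConfig:
    cfg = PipelineConfig()
    types = {k: type(v) for k, v in vars(cfg).items()}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        if k in types and k != "extras":
            try:
                setattr(cfg, k, types[k](v))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad value for {k}: {v!r}") from exc
        else:
            cfg.extras[k] = v
    return cfg


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path, config: PipelineConfig | None = None, float_format=None):
    with open(path, "w") as fh:
        if config is not None:
            fh.write(config.header() + "\n")
        df.to_csv(fh, index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_map(linkage_map: LinkageMap, path, config=None):
    df = linkage_map.table.copy()
    df["pos_cm"] = df["pos_cm"].round(2)
    write_table(df, path, config)


def read_map(path) -> LinkageMap:
    df = read_table(path)
    missing = {"marker", "chrom", "pos_cm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: map is missing columns {sorted(missing)}")
    return LinkageMap(df)


def write_genotypes(G: GenotypeMatrix, path, config=None):
    df = G.to_frame().reset_index(names="line")
    write_table(df, path, config)


def read_genotypes(path, linkage_map: LinkageMap | None = None) -> GenotypeMatrix:
    df = read_table(path)
    if df.columns[0] != "line":
        raise ValueError(f"{path}: first column must be 'line'")
    if df["line"].duplicated().any():
        dup = df.loc[df["line"].duplicated(), "line"].tolist()
        raise ValueError(f"{path}: duplicated line ids: {dup}")
    markers = list(df.columns[1:])
    vals = df[markers].to_numpy(float)
    bad = ~(np.isnan(vals) | (vals == -1) | (vals == 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid genotype code {vals[i, j]!r} for line "
            f"{df['line'].iloc[i]!r}, marker {markers[j]!r}: RIL codes are "
            "-1/1/NA only (no heterozygous markers)"
        )
    if linkage_map is not None:
        gm, mm_ = set(markers), set(linkage_map.markers)
        if gm != mm_:
            raise ValueError(
                f"{path}: marker sets differ from map; only in genotypes: "
                f"{sorted(gm - mm_)[:5]}, only in map: {sorted(mm_ - gm)[:5]}"
            )
        vals = df[linkage_map.markers].to_numpy(float)
        markers = list(linkage_map.markers)
    return GenotypeMatrix(lines=df["line"].tolist(), markers=markers, values=vals)


def write_phenotypes(plots: pd.DataFrame, path, config=None):
    write_table(plots, path, config, float_format="%.4f")


def read_phenotypes(path) -> pd.DataFrame:
    df = read_table(path)
    missing = {"site", "rep", "row", "col", "line", "tf_days"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    return df


def write_weather(weather_by_site: dict, path, config=None):
    frames = []
    for site, w in weather_by_site.items():
        frames.append(
            pd.DataFrame(
                {
                    "site": site,
                    "latitude": w.latitude,
                    "sowing_doy": w.sowing_doy,
                    "day": np.arange(w.n_days),
                    "tmin_c": np.round(w.tmin, 3),
                    "tmax_c": np.round(w.tmax, 3),
                    "srad_mj_m2": np.round(w.srad, 3),
                }
            )
        )
    write_table(pd.concat(frames, ignore_index=True), path, config)


def read_weather(path) -> dict:
    df = read_table(path)
    missing = {"site", "latitude", "sowing_doy", "day", "tmin_c", "tmax_c", "srad_mj_m2"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"{path}: weather table missing columns {sorted(missing)}")
    out = {}
    for site, sub in df.groupby("site", sort=False):
        sub = sub.sort_values("day")
        if not np.array_equal(sub["day"].to_numpy(), np.arange(len(sub))):
            raise ValueError(f"{path}: site {site}: 'day' must run 0..n-1 without gaps")
        out[site] = DailyWeather(
            site=str(site),
            latitude=float(sub["latitude"].iloc[0]),
            sowing_doy=int(sub["sowing_doy"].iloc[0]),
            tmin=sub["tmin_c"].to_numpy(float),
            tmax=sub["tmax_c"].to_numpy(float),
            srad=sub["srad_mj_m2"].to_numpy(float),
        )
    return out
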