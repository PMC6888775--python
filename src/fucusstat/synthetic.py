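"""Synthetic coastal-survey generator with known ground truth.

Generates water-body zones along an inshore-offshore gradient, environmental
grids at their native resolutions, survey points with 11-class substrate
composition, per-zone Fucus outcomes from a generative hurdle model, and
dive transects whose true lower limits follow the log-linear depth model —
everything downstream of the raw surveys can therefore be tested against
embedded truth without any external data.

All randomness flows from a single root seed through named substreams, so a
fixed config yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special

from fucusstat.envstats import EnvironmentGrid, write_ascii_grid
from fucusstat.errors import ConfigurationError
from fucusstat.habitat import (
    SUBSTRATE_CLASSES,
    light_limit_depth,
    photic_depth,
    potential_flags,
    PotentialConfig,
)
from fucusstat.hurdle import design_matrix

VARIABLES = ("salinity", "exposure", "secchi", "ntot", "ptot")

# substream ids: the root seed plus one of these feeds each generator
_STREAMS = {"zones": 11, "grids": 23, "points": 37, "outcomes": 53, "transects": 71}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stream])))


@dataclass(frozen=True)
class TrueParams:
    """Ordered coefficient truth for one model part."""

    terms: tuple[str, ...]
    values: tuple[float, ...]
    phi: float | None = None

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.values):
            raise ConfigurationError("TrueParams: one value per term required")
        if self.phi is not None and self.phi <= 0:
            raise ConfigurationError("TrueParams: phi must be > 0")

    def with_intercept(self, value: float) -> "TrueParams":
        vals = list(self.values)
        vals[self.terms.index("intercept")] = float(value)
        return TrueParams(self.terms, tuple(vals), self.phi)

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        return design_matrix(table, self.terms) @ np.asarray(self.values)


@dataclass(frozen=True)
class HurdleTruth:
    positive: TrueParams
    binomial: TrueParams


# Published coefficient tables used as simulation truth; intercepts are not
# published and default to 0 until calibrated at generation time.
DEFAULT_POSITIVE_TRUTH = TrueParams(
    terms=("intercept", "salinity", "log_exposure", "secchi", "ntot", "ptot",
           "salinity:secchi"),
    values=(0.0, 1.51, 0.04, 2.48, 0.002, -0.004, -0.45),
    phi=20.0,
)
DEFAULT_BINOMIAL_TRUTH = TrueParams(
    terms=("intercept", "salinity", "log_exposure", "secchi", "ntot", "ptot",
           "salinity:secchi"),
    values=(0.0, 1.37, 0.92, 3.81, -0.004, 0.02, -0.60),
)
DEFAULT_HURDLE_TRUTH = HurdleTruth(
    positive=DEFAULT_POSITIVE_TRUTH, binomial=DEFAULT_BINOMIAL_TRUTH
)
DEFAULT_LOWERLIMIT_TRUTH = TrueParams(
    terms=("intercept", "salinity", "log_exposure", "secchi", "ntot",
           "salinity:secchi", "log_exposure:ntot"),
    values=(0.0, 0.66, 0.27, 1.19, 0.005, -0.21, -0.0005),
)

DEFAULT_CELL_SIZES = {
    "salinity": 20.0, "exposure": 25.0, "ntot": 100.0, "ptot": 100.0,
    "secchi": 300.0,
}


@dataclass
class SimulationConfig:
    n_zones: int = 126
    n_points_per_zone: int = 150
    n_transects: int = 328                  # generated; ~186 retained by default
    salinity_range: tuple[float, float] = (2.0, 6.5)
    secchi_range: tuple[float, float] = (3.0, 6.0)
    ntot_range: tuple[float, float] = (250.0, 550.0)
    ptot_range: tuple[float, float] = (10.0, 40.0)
    exposure_range: tuple[float, float] = (5e4, 2e5)   # log-uniform
    hurdle_params: HurdleTruth = field(default_factory=lambda: DEFAULT_HURDLE_TRUTH)
    lowerlimit_params: TrueParams = field(
        default_factory=lambda: DEFAULT_LOWERLIMIT_TRUTH
    )
    sigma_loglimit: float | None = None     # None -> calibrated to printed SE
    seed: int = 0
    covariate_correlation: float = 0.7
    grid_noise: float = 0.02                # fraction of each range's width
    grid_noise_smoothing: float = 0.0       # gaussian sigma in cells; 0 = white
    grid_cell_sizes: dict = field(default_factory=lambda: dict(DEFAULT_CELL_SIZES))
    zone_size_m: float = 600.0
    hard_fraction: float = 0.55
    video_fraction: float = 0.8
    validation_leak: float = 0.0            # off-layer Fucus plant rate
    photic_coefficient: float = 2.0
    light_fraction: float = 0.6
    substrate_continue_fraction: float = 186.0 / 328.0
    transect_depth_step_m: float = 1.0
    transect_max_depth_m: float | None = None
    calibrate_intercepts: bool = True
    target_mean_rate: float = 0.35
    target_presence_rate: float = 106.0 / 126.0
    target_median_limit_m: float = 3.0
    target_salinity_se: float = 0.21        # printed SE used to calibrate sigma

    def __post_init__(self) -> None:
        if self.n_zones < 2:
            raise ConfigurationError("n_zones must be >= 2")
        for name in ("salinity_range", "secchi_range", "ntot_range",
                     "ptot_range", "exposure_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: min must be <= max")
            if name == "exposure_range" and lo <= 0:
                raise ConfigurationError("exposure_range must be positive")
        if self.sigma_loglimit is not None and self.sigma_loglimit < 0:
            raise ConfigurationError("sigma_loglimit must be >= 0")
        if not 0 <= self.covariate_correlation <= 1:
            raise ConfigurationError("covariate_correlation must be in [0,1]")
        if not 0 <= self.substrate_continue_fraction <= 1:
            raise ConfigurationError("substrate_continue_fraction in [0,1]")
        if isinstance(self.hurdle_params, Mapping):
            self.hurdle_params = HurdleTruth(
                positive=_params_from_dict(self.hurdle_params["positive"]),
                binomial=_params_from_dict(self.hurdle_params["binomial"]),
            )
        if isinstance(self.lowerlimit_params, Mapping):
            self.lowerlimit_params = _params_from_dict(self.lowerlimit_params)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["hurdle_params"] = {
            "positive": asdict(self.hurdle_params.positive),
            "binomial": asdict(self.hurdle_params.binomial),
        }
        out["lowerlimit_params"] = asdict(self.lowerlimit_params)
        return out

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        kwargs = dict(raw)
        for key in ("salinity_range", "secchi_range", "ntot_range",
                    "ptot_range", "exposure_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _params_from_dict(raw: Mapping) -> TrueParams:
    return TrueParams(
        terms=tuple(raw["terms"]),
        values=tuple(raw["values"]),
        phi=raw.get("phi"),
    )


@dataclass
class WaterBodyZone:
    zone_id: int
    col: int
    row: int
    rect: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    gradient_t: float
    covariates: dict[str, float]

    @property
    def geometry(self):
        import shapely

        return shapely.box(*self.rect)


def _grid_layout(n_zones: int) -> tuple[int, int]:
    nx = int(np.ceil(np.sqrt(n_zones)))
    ny = int(np.ceil(n_zones / nx))
    return nx, ny


def generate_zones(config: SimulationConfig) -> list[WaterBodyZone]:
    """Zones tiling a planar domain, covariates varying along the x axis.

    Salinity, Secchi and (log) exposure increase offshore; nutrients decrease
    and are mutually correlated, mimicking the archipelago gradient
    structure. `covariate_correlation` sets how tightly each zone follows the
    gradient versus idiosyncratic variation.
    """
    rng = _rng(config.seed, "zones")
    nx, ny = _grid_layout(config.n_zones)
    size = config.zone_size_m
    corr = config.covariate_correlation
    zones: list[WaterBodyZone] = []

    def scale(rangepair: tuple[float, float], mix: float, logscale=False) -> float:
        lo, hi = rangepair
        if logscale:
            return float(np.exp(np.log(lo) + mix * (np.log(hi) - np.log(lo))))
        return float(lo + mix * (hi - lo))

    for i in range(config.n_zones):
        col, row = i // ny, i % ny
        t = (col + 0.5) / nx
        u = rng.uniform(size=5)
        mix_sal = np.clip(corr * t + (1 - corr) * u[0], 0, 1)
        mix_sec = np.clip(corr * t + (1 - corr) * u[1], 0, 1)
        mix_exp = np.clip(corr * t + (1 - corr) * u[2], 0, 1)
        mix_n = np.clip(corr * (1 - t) + (1 - corr) * u[3], 0, 1)
        # P-tot tracks the N-tot latent (printed transect r = 0.84)
        mix_p = np.clip(0.68 * mix_n + 0.32 * u[4], 0, 1)
        cov = {
            "salinity": scale(config.salinity_range, mix_sal),
            "secchi": scale(config.secchi_range, mix_sec),
            "exposure": scale(config.exposure_range, mix_exp, logscale=True),
            "ntot": scale(config.ntot_range, mix_n),
            "ptot": scale(config.ptot_range, mix_p),
        }
        rect = (col * size, row * size, (col + 1) * size, (row + 1) * size)
        zones.append(
            WaterBodyZone(
                zone_id=i, col=col, row=row, rect=rect, gradient_t=float(t),
                covariates=cov,
            )
        )
    return zones


def zone_table(zones: Sequence[WaterBodyZone]) -> pd.DataFrame:
    """Zone-level covariate table (one row per zone)."""
    rows = [{"zone_id": z.zone_id, **z.covariates} for z in zones]
    return pd.DataFrame(rows)


def zones_to_geojson(zones: Sequence[WaterBodyZone], path: str | Path) -> None:
    features = []
    for z in zones:
        x0, y0, x1, y1 = z.rect
        features.append(
            {
                "type": "Feature",
                "properties": {"zone_id": z.zone_id, **z.covariates},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                    ],
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def generate_grids(
    zones: Sequence[WaterBodyZone], config: SimulationConfig
) -> dict[str, EnvironmentGrid]:
    """One grid per variable at its native resolution.

    Cell values are the containing zone's mean plus Gaussian noise whose
    amplitude is `grid_noise` times the variable's range width (log-scale
    for exposure); cells outside every zone are nodata.
    """
    rng = _rng(config.seed, "grids")
    nx, ny = _grid_layout(config.n_zones)
    size = config.zone_size_m
    width, height = nx * size, ny * size
    ranges = {
        "salinity": config.salinity_range,
        "secchi": config.secchi_range,
        "ntot": config.ntot_range,
        "ptot": config.ptot_range,
        "exposure": tuple(np.log(config.exposure_range)),
    }
    zone_vals = {
        var: np.array(
            [z.covariates[var] for z in zones]
            if var != "exposure"
            else [np.log(z.covariates["exposure"]) for z in zones]
        )
        for var in VARIABLES
    }
    grids: dict[str, EnvironmentGrid] = {}
    for var in VARIABLES:
        cell = float(config.grid_cell_sizes[var])
        n_cols = int(round(width / cell))
        n_rows = int(round(height / cell))
        xs = (np.arange(n_cols) + 0.5) * cell
        ys = height - (np.arange(n_rows) + 0.5) * cell
        xg, yg = np.meshgrid(xs, ys)
        colz = np.floor(xg / size).astype(int)
        rowz = np.floor(yg / size).astype(int)
        idx = colz * ny + rowz
        valid = idx < len(zones)
        base = np.where(valid, zone_vals[var][np.minimum(idx, len(zones) - 1)], 0.0)
        lo, hi = ranges[var]
        # bounded (uniform) noise keeps every cell within range +- amplitude
        amp = config.grid_noise * (hi - lo)
        noise = rng.uniform(-1.0, 1.0, size=base.shape)
        if config.grid_noise_smoothing > 0:
            noise = ndimage.gaussian_filter(noise, config.grid_noise_smoothing)
            peak = np.abs(noise).max()
            if peak > 0:
                noise = noise / peak
        values = base + amp * noise
        if var == "exposure":
            values = np.exp(values)
        values = np.where(valid, values, -9999.0)
        grids[var] = EnvironmentGrid(
            name=var, x_origin=0.0, y_origin=0.0, cell_size=cell,
            values=values, nodata=-9999.0,
        )
    return grids


def _dirichlet_substrate(
    rng: np.random.Generator, n: int, hard: bool
) -> np.ndarray:
    """(n, 11) substrate cover matrix summing to 100 per row.

    Hard-dominated points draw Dirichlet weight only over the 7 hard classes
    plus a little sand; soft-dominated points have exactly zero hard cover.
    """
    out = np.zeros((n, len(SUBSTRATE_CLASSES)))
    if n == 0:
        return out
    if hard:
        alpha = np.array([2.0, 0.5, 0.5, 0.8, 1.2, 0.8, 0.6, 0.8, 0.3, 0.2, 0.2])
    else:
        alpha = np.array([0.0] * 7 + [2.0, 1.0, 0.8, 1.0])
    draw_idx = np.where(alpha > 0)[0]
    draws = rng.dirichlet(alpha[draw_idx], size=n) * 100.0
    out[:, draw_idx] = draws
    return out


def _point_light_limit(
    x: np.ndarray, y: np.ndarray, secchi_grid: EnvironmentGrid,
    config: SimulationConfig,
) -> np.ndarray:
    from fucusstat.envstats import extract_at_points

    secchi = extract_at_points(secchi_grid, x, y)
    secchi = np.where(np.isfinite(secchi) & (secchi > 0), secchi, np.nan)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(secchi)
    if ok.any():
        out[ok] = light_limit_depth(
            photic_depth(secchi[ok], config.photic_coefficient),
            config.light_fraction,
        )
    return out


def generate_survey_points(
    zones: Sequence[WaterBodyZone],
    grids: Mapping[str, EnvironmentGrid],
    config: SimulationConfig,
    outcomes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Survey-point table with substrate simplex rows and planted Fucus.

    Depths span 0 to 1.6x the local light limit so both potential and
    non-potential sites occur. When per-zone ``outcomes`` (from
    :func:`simulate_zone_outcomes`) are given, Fucus is planted on potential
    sites of present zones with probability equal to the zone's rate;
    ``validation_leak`` plants off-layer Fucus for layer-validation tests.
    """
    rng = _rng(config.seed, "points")
    rates = None
    if outcomes is not None:
        rates = outcomes.set_index("zone_id")["rate"].to_dict()
    frames = []
    pid = 0
    for z in zones:
        n = config.n_points_per_zone
        x0, y0, x1, y1 = z.rect
        x = rng.uniform(x0, x1, size=n)
        y = rng.uniform(y0, y1, size=n)
        limit = _point_light_limit(x, y, grids["secchi"], config)
        depth_cap = np.where(np.isfinite(limit), 1.6 * np.maximum(limit, 0.5), 5.0)
        depth = rng.uniform(0.0, depth_cap)
        hard_mask = rng.uniform(size=n) < config.hard_fraction
        substrate = np.zeros((n, len(SUBSTRATE_CLASSES)))
        substrate[hard_mask] = _dirichlet_substrate(rng, int(hard_mask.sum()), True)
        substrate[~hard_mask] = _dirichlet_substrate(
            rng, int((~hard_mask).sum()), False
        )
        method = np.where(
            rng.uniform(size=n) < config.video_fraction, "video", "dive"
        )
        df = pd.DataFrame(
            {
                "point_id": np.arange(pid, pid + n),
                "zone_id": z.zone_id,
                "x": x,
                "y": y,
                "depth_m": depth,
                "method": method,
            }
        )
        pid += n
        for j, cls in enumerate(SUBSTRATE_CLASSES):
            df[cls] = substrate[:, j]
        fucus = np.zeros(n)
        if rates is not None:
            rate = float(rates.get(z.zone_id, 0.0))
            pot = potential_flags(
                df, limit,
                PotentialConfig(light_fraction=config.light_fraction,
                                photic_coefficients=config.photic_coefficient),
            )
            occupied = pot & (rng.uniform(size=n) < rate)
            fucus[occupied] = rng.uniform(5.0, 90.0, size=int(occupied.sum()))
            if config.validation_leak > 0:
                leak = (~pot) & (rng.uniform(size=n) < config.validation_leak)
                fucus[leak] = rng.uniform(1.0, 30.0, size=int(leak.sum()))
        df["fucus_cover_pct"] = fucus
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _calibrate_logit_intercept(
    lp_rest: np.ndarray, target_mean: float
) -> float:
    """Intercept b0 such that mean(expit(b0 + lp_rest)) == target_mean."""

    def f(b0: float) -> float:
        return float(np.mean(special.expit(b0 + lp_rest))) - target_mean

    return float(optimize.brentq(f, -60.0, 60.0))


def calibrate_hurdle_intercepts(
    truth: HurdleTruth, zone_covariates: pd.DataFrame,
    target_mean_rate: float, target_presence_rate: float,
) -> HurdleTruth:
    """Set the unpublished intercepts from marginal targets on a fixed design."""
    pos, bino = truth.positive, truth.binomial
    lp_pos = pos.with_intercept(0.0).linear_predictor(zone_covariates)
    lp_bin = bino.with_intercept(0.0).linear_predictor(zone_covariates)
    return HurdleTruth(
        positive=pos.with_intercept(
            _calibrate_logit_intercept(lp_pos, target_mean_rate)
        ),
        binomial=bino.with_intercept(
            _calibrate_logit_intercept(lp_bin, target_presence_rate)
        ),
    )


def simulate_zone_outcomes(
    zones: Sequence[WaterBodyZone] | pd.DataFrame,
    hurdle_params: HurdleTruth,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-zone presence flag and occurrence rate from the hurdle truth.

    Presence ~ Bernoulli(expit(binomial lp)); rates of present zones are
    Beta(mu*phi, (1-mu)*phi) draws with mu = expit(positive lp), re-drawn in
    the measure-zero event of an exact 0/1; absent zones get rate 0.
    """
    if hurdle_params.positive.phi is None or hurdle_params.positive.phi <= 0:
        raise ConfigurationError("positive-part phi must be > 0")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else _rng(int(seed), "outcomes")
    )
    table = zones if isinstance(zones, pd.DataFrame) else zone_table(zones)
    p_presence = special.expit(
        np.clip(hurdle_params.binomial.linear_predictor(table), -35, 35)
    )
    mu = special.expit(
        np.clip(hurdle_params.positive.linear_predictor(table), -35, 35)
    )
    phi = hurdle_params.positive.phi
    presence = rng.uniform(size=len(table)) < p_presence
    rate = np.zeros(len(table))
    a, b = mu * phi, (1 - mu) * phi
    draws = rng.beta(a, b)
    for _ in range(100):  # re-draw boundary roundings; support stays open
        bad = presence & ((draws <= 0.0) | (draws >= 1.0))
        if not bad.any():
            break
        draws[bad] = rng.beta(a[bad], b[bad])
    # extreme mu can make every draw round to the boundary; nudge the last
    # representable step inward so the positive-part support stays open
    draws = np.clip(draws, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    rate[presence] = draws[presence]
    return pd.DataFrame(
        {
            "zone_id": table["zone_id"].to_numpy()
            if "zone_id" in table else np.arange(len(table)),
            "p_presence": p_presence,
            "presence": presence,
            "mu": mu,
            "rate": rate,
        }
    )


def calibrate_sigma_from_se(
    X: np.ndarray, terms: Sequence[str], target_se: float,
    term: str = "salinity",
) -> float:
    """Residual sigma making the OLS SE of ``term`` equal ``target_se``."""
    cjj = float(np.linalg.inv(X.T @ X)[list(terms).index(term),
                                       list(terms).index(term)])
    return target_se / np.sqrt(cjj)


def sample_transect_covariates(
    zones: Sequence[WaterBodyZone],
    grids: Mapping[str, EnvironmentGrid],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Random transect locations with grid-extracted covariate values."""
    from fucusstat.envstats import extract_at_points

    n = config.n_transects
    zidx = rng.integers(0, len(zones), size=n)
    rows = []
    for i, zi in enumerate(zidx):
        x0, y0, x1, y1 = zones[zi].rect
        rows.append(
            {
                "transect_id": i,
                "zone_id": zones[zi].zone_id,
                "x": rng.uniform(x0, x1),
                "y": rng.uniform(y0, y1),
            }
        )
    table = pd.DataFrame(rows)
    for var in VARIABLES:
        table[var] = extract_at_points(
            grids[var], table["x"].to_numpy(), table["y"].to_numpy()
        )
    # grid noise can push exposure to <= 0 in principle; clip to a floor
    table["exposure"] = np.maximum(table["exposure"].to_numpy(), 1e-6)
    return table


def generate_transects(
    zones: Sequence[WaterBodyZone],
    grids: Mapping[str, EnvironmentGrid],
    lowerlimit_params: TrueParams,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TrueParams, float]:
    """Dive transects with embedded true lower limits.

    Returns ``(points, truth, calibrated_params, sigma)``. Each transect has
    a monotone depth profile sampled at ``transect_depth_step_m`` vertical
    intervals; Fucus cover is >= 10% from the surface down to the true limit
    L and < 10% below; hard substrate continues below L for a
    ``substrate_continue_fraction`` share of transects, soft otherwise.
    Transects whose L exceeds the (fixed) maximum depth are flagged censored
    in the truth table.
    """
    rng = _rng(config.seed, "transects")
    cov = sample_transect_covariates(zones, grids, config, rng)
    params = lowerlimit_params
    X = design_matrix(cov, list(params.terms))
    if config.calibrate_intercepts:
        lp0 = params.with_intercept(0.0).linear_predictor(cov)
        params = params.with_intercept(
            float(np.log(config.target_median_limit_m) - np.median(lp0))
        )
    sigma = config.sigma_loglimit
    if sigma is None:
        sigma = calibrate_sigma_from_se(
            X, params.terms, config.target_salinity_se, term="salinity"
        )
    lp = params.linear_predictor(cov)
    eps = rng.normal(0.0, sigma, size=len(cov))
    true_limit = np.exp(lp + eps)
    continues = rng.uniform(size=len(cov)) < config.substrate_continue_fraction
    step = config.transect_depth_step_m
    frames = []
    truth_rows = []
    for i in range(len(cov)):
        L = float(true_limit[i])
        if config.transect_max_depth_m is not None:
            max_depth = config.transect_max_depth_m
            censored = L > max_depth
        else:
            max_depth = float(np.ceil(L) + rng.uniform(1.0, 4.0))
            censored = False
        slope = rng.uniform(0.05, 0.25)
        depths = np.arange(0.0, max_depth + step / 2, step)
        dist = depths / slope
        above = depths <= L
        cover = np.where(
            above,
            rng.uniform(15.0, 90.0, size=len(depths)),
            rng.uniform(0.0, 5.0, size=len(depths)),
        )
        sub = np.zeros((len(depths), len(SUBSTRATE_CLASSES)))
        sub[above] = _dirichlet_substrate(rng, int(above.sum()), True)
        below = ~above
        sub[below] = _dirichlet_substrate(
            rng, int(below.sum()), bool(continues[i])
        )
        df = pd.DataFrame(
            {
                "transect_id": i,
                "zone_id": cov["zone_id"].iloc[i],
                "x": cov["x"].iloc[i],
                "y": cov["y"].iloc[i],
                "distance_m": dist,
                "depth_m": depths,
            }
        )
        for j, cls in enumerate(SUBSTRATE_CLASSES):
            df[cls] = sub[:, j]
        df["fucus_cover_pct"] = cover
        frames.append(df)
        truth_rows.append(
            {
                "transect_id": i,
                "zone_id": int(cov["zone_id"].iloc[i]),
                "x": float(cov["x"].iloc[i]),
                "y": float(cov["y"].iloc[i]),
                "true_lower_limit_m": L,
                "linear_predictor": float(lp[i]),
                "censored": bool(censored),
                "substrate_continues": bool(continues[i]),
                "expected_detected": bool((not censored) and L >= step),
                **{v: float(cov[v].iloc[i]) for v in VARIABLES},
            }
        )
    points = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return points, truth, params, float(sigma)


@dataclass
class SyntheticDataset:
    """Everything one simulation run produces, plus its ground truth."""

    config: SimulationConfig
    zones: list[WaterBodyZone]
    grids: dict[str, EnvironmentGrid]
    outcomes: pd.DataFrame
    survey_points: pd.DataFrame
    transects: pd.DataFrame
    transect_truth: pd.DataFrame
    hurdle_truth: HurdleTruth
    lowerlimit_truth: TrueParams
    sigma_loglimit: float


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run every generator stage with calibrated truths."""
    zones = generate_zones(config)
    grids = generate_grids(zones, config)
    hurdle_truth = config.hurdle_params
    if config.calibrate_intercepts:
        hurdle_truth = calibrate_hurdle_intercepts(
            hurdle_truth, zone_table(zones),
            config.target_mean_rate, config.target_presence_rate,
        )
    outcomes = simulate_zone_outcomes(zones, hurdle_truth, seed=config.seed)
    points = generate_survey_points(zones, grids, config, outcomes=outcomes)
    transects, truth, ll_params, sigma = generate_transects(
        zones, grids, config.lowerlimit_params, config
    )
    return SyntheticDataset(
        config=config, zones=zones, grids=grids, outcomes=outcomes,
        survey_points=points, transects=transects, transect_truth=truth,
        hurdle_truth=hurdle_truth, lowerlimit_truth=ll_params,
        sigma_loglimit=sigma,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the standard text outputs; returns {label: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ds.survey_points.to_csv(out / "survey_points.csv", index=False)
    paths["survey_points"] = out / "survey_points.csv"
    ds.transects.to_csv(out / "transects.csv", index=False)
    paths["transects"] = out / "transects.csv"
    zones_to_geojson(ds.zones, out / "zones.geojson")
    paths["zones"] = out / "zones.geojson"
    for var, grid in ds.grids.items():
        write_ascii_grid(grid, out / f"{var}.asc")
        paths[f"grid_{var}"] = out / f"{var}.asc"
    truth = {
        "hurdle_truth": {
            "positive": asdict(ds.hurdle_truth.positive),
            "binomial": asdict(ds.hurdle_truth.binomial),
        },
        "lowerlimit_truth": asdict(ds.lowerlimit_truth),
        "sigma_loglimit": ds.sigma_loglimit,
        "zone_outcomes": ds.outcomes.to_dict(orient="list"),
        "transect_truth": ds.transect_truth[
            ~ds.transect_truth["censored"]
        ].to_dict(orient="list"),
        "n_censored_transects": int(ds.transect_truth["censored"].sum()),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
    paths["truth"] = out / "truth.json"
    return paths
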