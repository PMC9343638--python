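"""Synthetic study generator: covariate fields, exceedance truth, wells, population.

The generator emulates the structure of a continental-scale groundwater
quality study with known ground truth: spatially autocorrelated
environmental covariates at two resolutions, a sparse-logistic exceedance
process with ~10% prevalence at a 1.5 mg/L guideline, duplicate well
measurements, well depths, clustered rural/urban population, and
country-level untreated-groundwater usage rates. Every output is a
deterministic function of the scenario seed.

Random fields are truncated-Gaussian smoothed white noise; the stated
smoothness is the kernel SD in cells, which serves as the correlation
length. Concentrations use lognormal bodies with pooled median near
0.3 mg/L, split at the guideline so labels and concentrations agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, optimize, stats

from .grids import Band, CovariateStack, GridSpec, Raster, coarse_grid

GUIDELINE_MG_L = 1.5


@dataclass
class SyntheticScenario:
    """Full parameterization of one synthetic study.

    Coefficients are on the logit scale. ``intercept=None`` asks
    :func:`gen_truth_surface` to calibrate it by bisection so the spatial
    mean exceedance probability hits ``target_prevalence``.
    """

    seed: int = 0
    grid_shape: tuple[int, int] = (200, 200)
    cell_size: float = 1.0
    n_covariates: int = 12
    informative_indices: tuple[int, ...] = (0, 1, 2)
    true_coefficients: tuple[float, ...] | None = None
    intercept: float | None = None
    target_prevalence: float = 0.102
    smoothness: float | tuple[float, ...] = 10.0
    n_wells: int = 5000
    duplicate_rate: float = 0.10
    n_countries: int = 4
    continent_assignment: dict[int, str] | None = None
    coarse_factor: int = 2
    n_coarse: int = 3  # trailing continuous bands stored at coarse resolution
    categorical_index: int | None = None  # defaults to the last band
    depth_median_m: float = 70.0
    depth_log_sd: float = 2.25
    insitu: bool = True

    def __post_init__(self) -> None:
        if self.grid_shape[0] <= 0 or self.grid_shape[1] <= 0:
            raise ValueError(f"grid shape must be positive, got {self.grid_shape}")
        if self.n_covariates < 1:
            raise ValueError("need at least one covariate")
        if self.true_coefficients is None:
            # strong default effects on the informative bands, zero elsewhere;
            # sized so a Bayes-oracle classifier clearly separates the classes
            defaults = [2.5, -2.0, 2.0, 1.8, -1.6, 1.4]
            beta = np.zeros(self.n_covariates)
            for j, idx in enumerate(self.informative_indices):
                beta[idx] = defaults[j % len(defaults)] * (1 + j // len(defaults))
            self.true_coefficients = tuple(beta)
        self.true_coefficients = tuple(float(b) for b in self.true_coefficients)
        if len(self.true_coefficients) != self.n_covariates:
            raise ValueError("coefficient vector length must equal n_covariates")
        for idx in range(self.n_covariates):
            informative = idx in self.informative_indices
            if informative != (self.true_coefficients[idx] != 0):
                raise ValueError(
                    "coefficients must be nonzero exactly on informative_indices"
                )
        if np.isscalar(self.smoothness):
            self.smoothness = tuple([float(self.smoothness)] * self.n_covariates)
        else:
            self.smoothness = tuple(float(s) for s in self.smoothness)
        if len(self.smoothness) != self.n_covariates:
            raise ValueError("smoothness must be scalar or per-band")
        if any(s < 0 for s in self.smoothness):
            raise ValueError("smoothness must be nonnegative")
        if self.categorical_index is None:
            self.categorical_index = self.n_covariates - 1
        if self.continent_assignment is None:
            self.continent_assignment = {
                c: ("ContinentA" if c % 2 == 0 else "ContinentB")
                for c in range(self.n_countries)
            }
        if not 0 <= self.duplicate_rate <= 1:
            raise ValueError("duplicate_rate must be in [0, 1]")

    @property
    def band_names(self) -> list[str]:
        return [f"cov{i:02d}" for i in range(self.n_covariates)]

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            nrows=self.grid_shape[0], ncols=self.grid_shape[1], cell_size=self.cell_size
        )

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        d["continent_assignment"] = dict(self.continent_assignment)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "informative_indices", "true_coefficients", "smoothness"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("continent_assignment") is not None:
            d["continent_assignment"] = {int(k): v for k, v in d["continent_assignment"].items()}
        return cls(**d)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sd_cells: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise; sd_cells=0 means raw noise."""
    z = rng.standard_normal(shape)
    if sd_cells > 0:
        z = ndimage.gaussian_filter(z, sigma=sd_cells, mode="reflect", truncate=4.0)
    z = z - z.mean()
    sd = z.std()
    if sd > 0:
        z = z / sd
    return z


def gen_covariate_rasters(scenario: SyntheticScenario) -> CovariateStack:
    """Generate the covariate stack: continuous smoothed fields plus one
    binary categorical band, with the trailing continuous bands stored at
    an integer-multiple coarser cell size to exercise resampling."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    fine = scenario.grid
    stack = CovariateStack()
    coarse_set = _coarse_indices(scenario)
    for i, name in enumerate(scenario.band_names):
        sd = scenario.smoothness[i]
        if i == scenario.categorical_index:
            # binary lithology-like indicator: thresholded smoothed field
            z = _smooth_field(rng, fine.shape, max(sd, 1.0))
            data = (z > np.quantile(z, 0.8)).astype(float)
            stack.add(Band(name, Raster(data, fine), kind="categorical"))
        elif i in coarse_set:
            g = coarse_grid(fine, scenario.coarse_factor)
            z = _smooth_field(rng, g.shape, sd / scenario.coarse_factor)
            stack.add(Band(name, Raster(z, g), kind="continuous"))
        else:
            z = _smooth_field(rng, fine.shape, sd)
            stack.add(Band(name, Raster(z, fine), kind="continuous"))
    return stack


def _coarse_indices(scenario: SyntheticScenario) -> set[int]:
    out: set[int] = set()
    i = scenario.n_covariates - 1
    while len(out) < scenario.n_coarse and i >= 0:
        if i != scenario.categorical_index and i not in scenario.informative_indices:
            out.add(i)
        i -= 1
    return out


def _fine_band_values(stack: CovariateStack, fine: GridSpec) -> dict[str, np.ndarray]:
    """Every band block-replicated onto the fine grid (values unchanged)."""
    out = {}
    for name, band in stack.bands.items():
        g = band.raster.grid
        if g.shape == fine.shape:
            out[name] = band.raster.data
        else:
            factor = round(g.cell_size / fine.cell_size)
            out[name] = np.repeat(np.repeat(band.raster.data, factor, 0), factor, 1)
    return out


def gen_truth_surface(stack: CovariateStack, scenario: SyntheticScenario) -> Raster:
    """Cellwise true exceedance probability p = expit(b0 + sum beta_i cov_i).

    If the scenario leaves the intercept free, it is found by bisection so
    that the spatial mean probability equals ``target_prevalence``.
    """
    fine = stack.fine_grid
    if fine.shape != scenario.grid.shape:
        raise ValueError("stack does not align with the scenario grid")
    values = _fine_band_values(stack, fine)
    lin = np.zeros(fine.shape)
    for i, name in enumerate(scenario.band_names):
        beta = scenario.true_coefficients[i]
        if beta != 0:
            lin += beta * values[name]
    if scenario.intercept is not None:
        b0 = scenario.intercept
    else:
        target = scenario.target_prevalence

        def mean_gap(b: float) -> float:
            return float(stats.logistic.cdf(b + lin).mean() - target)

        b0 = optimize.brentq(mean_gap, -30.0, 30.0, xtol=1e-10)
    p = stats.logistic.cdf(b0 + lin)
    return Raster(p, fine)


def _truncated_lognormal(
    rng: np.random.Generator, n: int, median: float, log_sd: float,
    upper: float | None = None, lower: float | None = None,
) -> np.ndarray:
    """Lognormal draws restricted to (lower, upper) via inverse-CDF."""
    mu = np.log(median)
    dist = stats.lognorm(s=log_sd, scale=np.exp(mu))
    lo = dist.cdf(lower) if lower is not None else 0.0
    hi = dist.cdf(upper) if upper is not None else 1.0
    u = rng.uniform(lo, hi, size=n)
    return dist.ppf(u)


def gen_measurements(
    truth: Raster, scenario: SyntheticScenario
) -> pd.DataFrame:
    """Raw (pre-deduplication) well measurement table.

    Wells land in uniformly random cells; the exceedance label is Bernoulli
    in the local truth probability; concentrations are lognormal below the
    guideline for negatives and shifted above it for positives. A
    ``duplicate_rate`` fraction of wells contribute 2-3 replicate rows whose
    concentrations are jittered on the same side of the guideline.
    """
    if scenario.n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if truth.grid.shape != scenario.grid.shape:
        raise ValueError("truth surface does not align with the scenario grid")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))
    g = truth.grid
    n = scenario.n_wells
    rows = rng.integers(0, g.nrows, n)
    cols = rng.integers(0, g.ncols, n)
    # coordinates uniform within the cell, so extraction must re-find the cell
    x = g.x0 + (cols + rng.uniform(0, 1, n)) * g.cell_size
    y = g.y0 - (rows + rng.uniform(0, 1, n)) * g.cell_size
    p = truth.data[rows, cols]
    label = (rng.uniform(size=n) < p).astype(int)

    conc = np.empty(n)
    neg, pos = label == 0, label == 1
    # pooled median ~0.3 mg/L: negatives dominate at ~90% prevalence share
    conc[neg] = _truncated_lognormal(
        rng, int(neg.sum()), median=0.3, log_sd=0.9, upper=GUIDELINE_MG_L
    )
    conc[pos] = GUIDELINE_MG_L + stats.lognorm(s=0.8, scale=0.9).ppf(
        rng.uniform(size=int(pos.sum()))
    )
    depth = _truncated_lognormal(
        rng, n, median=scenario.depth_median_m, log_sd=scenario.depth_log_sd
    )

    df = pd.DataFrame(
        {
            "well_id": [f"w{i:06d}" for i in range(n)],
            "lon": x,
            "lat": y,
            "concentration": conc,
            "depth": depth,
        }
    )
    if scenario.insitu:
        # monotone-positive parameter and a V-shaped one, both noisy
        z = np.log(p / (1 - p))
        df["insitu_mono"] = 7.0 + 0.6 * z + rng.normal(0, 0.8, n)
        sign = rng.choice([-1.0, 1.0], size=n)
        df["insitu_vee"] = sign * (z - z.min() + rng.normal(0, 0.8, n))

    # replicate rows for a fraction of wells, concentration jittered but
    # clamped to the label's side of the guideline
    n_dup = int(round(scenario.duplicate_rate * n))
    if n_dup > 0:
        dup_wells = rng.choice(n, size=n_dup, replace=False)
        extra = []
        for w in dup_wells:
            for _ in range(int(rng.integers(1, 3))):  # 1-2 extra rows -> 2-3 total
                row = df.iloc[w].copy()
                c = row["concentration"] * np.exp(rng.normal(0, 0.1))
                if label[w] == 1:
                    c = max(c, GUIDELINE_MG_L + 1e-6)
                else:
                    c = min(c, GUIDELINE_MG_L - 1e-6)
                row["concentration"] = c
                extra.append(row)
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
        df = df.sort_values("well_id", kind="stable").reset_index(drop=True)
    return df


def gen_population_and_usage(
    scenario: SyntheticScenario,
) -> tuple[Raster, Raster, Raster, pd.DataFrame]:
    """(rural_pop, urban_pop, country_ids, usage) on the scenario grid.

    Countries tile the grid in contiguous vertical strips. Population is a
    sum of Gaussian settlement clusters (urban: fewer, denser). Usage rates
    are per-country fractions of domestic use from untreated groundwater.
    """
    if scenario.n_countries < 1:
        raise ValueError("need at least one country")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 3]))
    g = scenario.grid
    nr, nc = g.shape

    edges = np.linspace(0, nc, scenario.n_countries + 1).astype(int)
    country = np.zeros((nr, nc))
    for c in range(scenario.n_countries):
        country[:, edges[c] : edges[c + 1]] = c

    yy, xx = np.mgrid[0:nr, 0:nc]

    def clustered(n_blobs: int, spread: float, peak: float) -> np.ndarray:
        pop = np.zeros((nr, nc))
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, nr), rng.uniform(0, nc)
            s = spread * rng.uniform(0.5, 1.5)
            amp = peak * rng.lognormal(0, 0.5)
            pop += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
        return pop

    rural = clustered(n_blobs=max(8, nr // 10), spread=nr / 12, peak=50.0)
    urban = clustered(n_blobs=max(3, nr // 40), spread=nr / 40, peak=400.0)

    usage = pd.DataFrame(
        {
            "country_id": np.arange(scenario.n_countries),
            "rural_fraction": rng.uniform(0.3, 0.9, scenario.n_countries),
            "urban_fraction": rng.uniform(0.1, 0.6, scenario.n_countries),
            "continent": [
                scenario.continent_assignment[c] for c in range(scenario.n_countries)
            ],
        }
    )
    if ((usage[["rural_fraction", "urban_fraction"]] < 0).any().any()
            or (usage[["rural_fraction", "urban_fraction"]] > 1).any().any()):
        raise ValueError("usage fractions must lie in [0, 1]")
    return Raster(rural, g), Raster(urban, g), Raster(country, g), usage


def write_scenario_outputs(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Materialize every synthetic input as text files under ``out_dir``."""
    from .grids import write_ascii

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = gen_covariate_rasters(scenario)
    truth = gen_truth_surface(stack, scenario)
    wells = gen_measurements(truth, scenario)
    rural, urban, country, usage = gen_population_and_usage(scenario)

    paths: dict[str, Path] = {}
    cov_dir = out / "covariates"
    cov_dir.mkdir(exist_ok=True)
    for name, band in stack.bands.items():
        p = cov_dir / f"{name}.asc"
        write_ascii(band.raster, p)
        paths[name] = p
    kinds = pd.DataFrame(
        {
            "band": stack.names,
            "kind": [stack.bands[n].kind for n in stack.names],
            "native_resolution": [stack.bands[n].native_resolution for n in stack.names],
        }
    )
    for key, obj in [
        ("band_kinds", kinds), ("measurements", wells), ("usage", usage),
    ]:
        p = out / f"{key}.csv"
        obj.to_csv(p, index=False)
        paths[key] = p
    for key, rast in [
        ("truth", truth), ("pop_rural", rural), ("pop_urban", urban), ("countries", country),
    ]:
        p = out / f"{key}.asc"
        write_ascii(rast, p)
        paths[key] = p
    scenario.to_yaml(out / "scenario.yaml")
    paths["scenario"] = out / "scenario.yaml"
    return paths
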