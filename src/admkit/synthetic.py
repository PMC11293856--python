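"""Synthetic ocean worlds with planted associations.

The generator emulates the three inputs the framework consumes: a
compositional sample-by-taxon abundance table with per-sample metadata,
matching environmental predictors, and gridded fields with future climate
trajectories. The generative model is deliberately minimal:

* temperature falls linearly with absolute latitude; nitrate and silicate
  are drawn anticorrelated with temperature at a target Pearson strength
  (strongly negative, mirroring real surface-ocean nutrient structure);
  salinity is near-constant noise;
* each taxon has a Gaussian thermal niche; its log-abundance is the niche
  response scaled by a gain, plus noise. Below a niche-response cutoff the
  taxon is structurally absent (a true zero), so presence/absence carries
  environmental signal;
* planted associated pairs share a latent log-abundance factor (same sign
  for positive pairs, opposite signs for negative pairs) and share their
  thermal niche, coupling both their abundances and their co-occurrence;
* rows are optionally closed to relative abundances, making the table
  compositional like real metagenomic profiles.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .adm import DEFAULT_FEATURES, EnvTable
from .compositional import AbundanceTable
from .projection import GridField

__all__ = [
    "SyntheticSpec",
    "generate_sample_sites",
    "generate_env",
    "generate_grid",
    "generate_abundances",
    "generate_future_grids",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic world.

    Defaults give the standard fixture: 80 samples, 50 taxa, 20 planted
    positive pairs, a latitudinal temperature gradient and nutrient fields
    anticorrelated with temperature at Pearson ~ -0.9.
    """

    n_samples: int = 80
    n_taxa: int = 50
    n_planted_positive_pairs: int = 20
    n_planted_negative_pairs: int = 0
    # environment
    lat_range: tuple[float, float] = (-65.0, 65.0)
    temp_equator: float = 28.0  # degC at latitude 0
    temp_lat_slope: float = 0.3  # degC lost per degree of |latitude|
    temp_noise_sd: float = 1.0
    nutrient_anticorrelation: float = -0.9  # target Pearson(T, NO3)
    nitrate_mean: float = 12.0  # umol/kg
    nitrate_sd: float = 6.0
    silicate_anticorrelation: float = -0.7
    silicate_mean: float = 15.0
    silicate_sd: float = 6.0
    salinity_mean: float = 35.0  # PSU
    salinity_noise_sd: float = 0.1
    # niches and abundances
    niche_breadth_range: tuple[float, float] = (6.0, 10.0)
    niche_gain: float = 5.0
    log_baseline: float = 2.0
    log_noise_sd: float = 0.15
    presence_cutoff: float = 0.3  # niche response below this -> structural zero
    coupling: float = 2.0  # latent-factor weight for planted pairs
    pair_niche_offset: float = 4.0  # degC between a planted pair's thermal optima
    compositional_closure: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        n_pair_taxa = 2 * (self.n_planted_positive_pairs + self.n_planted_negative_pairs)
        if n_pair_taxa > self.n_taxa:
            raise ValueError("planted pairs require more taxa than n_taxa provides")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)


def _env_features(spec: SyntheticSpec, lat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Feature matrix [temperature, salinity, nitrate, silicate] at latitudes."""
    n = lat.shape[0]
    temp = (
        spec.temp_equator
        - spec.temp_lat_slope * np.abs(lat)
        + rng.normal(0.0, spec.temp_noise_sd, n)
    )
    t_sd = temp.std()
    z_t = (temp - temp.mean()) / t_sd if t_sd > 0 else np.zeros(n)

    def nutrient(r: float, mean: float, sd: float) -> np.ndarray:
        noise = rng.normal(0.0, 1.0, n)
        vals = mean + sd * (r * z_t + np.sqrt(1.0 - r**2) * noise)
        return np.clip(vals, 0.05, None)

    nitrate = nutrient(spec.nutrient_anticorrelation, spec.nitrate_mean, spec.nitrate_sd)
    silicate = nutrient(spec.silicate_anticorrelation, spec.silicate_mean, spec.silicate_sd)
    salinity = spec.salinity_mean + rng.normal(0.0, spec.salinity_noise_sd, n)
    return np.column_stack([temp, salinity, nitrate, silicate])


def generate_sample_sites(spec: SyntheticSpec) -> pd.DataFrame:
    """Random sampling locations: metadata frame indexed by sample id."""
    rng = np.random.default_rng(spec.seed)
    lat = rng.uniform(*spec.lat_range, spec.n_samples)
    lon = rng.uniform(-180.0, 180.0, spec.n_samples)
    return pd.DataFrame(
        {
            "latitude": lat,
            "longitude": lon,
            "depth": 10.0,
            "month": rng.integers(1, 13, spec.n_samples),
            "size_fraction": "0.22-3",
        },
        index=pd.Index([f"S{i:03d}" for i in range(spec.n_samples)], name="sample_id"),
    )


def generate_env(spec: SyntheticSpec, sample_meta: pd.DataFrame) -> EnvTable:
    """Environmental predictors at sample locations (seed offset 1)."""
    rng = np.random.default_rng(spec.seed + 1)
    features = _env_features(spec, sample_meta["latitude"].to_numpy(dtype=float), rng)
    return EnvTable(
        sample_ids=[str(s) for s in sample_meta.index],
        features=features,
        feature_names=list(DEFAULT_FEATURES),
    )


def generate_grid(
    spec: SyntheticSpec,
    lat_step: float = 5.0,
    lon_step: float = 10.0,
    time_label: str = "present",
) -> GridField:
    """A coarse regular grid of the same synthetic environment (seed offset 2)."""
    lats = np.arange(spec.lat_range[0], spec.lat_range[1] + 1e-9, lat_step)
    lons = np.arange(-180.0, 180.0, lon_step)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    glat, glon = glat.ravel(), glon.ravel()
    rng = np.random.default_rng(spec.seed + 2)
    features = _env_features(spec, glat, rng)
    return GridField(
        lat=glat, lon=glon, features=features,
        feature_names=list(DEFAULT_FEATURES), time_label=time_label,
    )


def generate_abundances(
    spec: SyntheticSpec, env: EnvTable, sample_meta: pd.DataFrame | None = None
) -> tuple[AbundanceTable, list[dict]]:
    """Abundance table with planted pairwise associations (seed offset 3).

    Returns the table and the ground truth: one record per planted pair
    with keys ``taxon_j``, ``taxon_k``, ``sign``.
    """
    rng = np.random.default_rng(spec.seed + 3)
    n, m = env.features.shape[0], spec.n_taxa
    temp = env.features[:, env.feature_names.index("temperature")]
    t_lo, t_hi = temp.min(), temp.max()

    optima = rng.uniform(t_lo, t_hi, m)
    breadths = rng.uniform(*spec.niche_breadth_range, m)

    taxon_ids = [f"T{j:03d}" for j in range(m)]
    ground_truth: list[dict] = []
    signs: list[int] = [1] * spec.n_planted_positive_pairs + [-1] * spec.n_planted_negative_pairs
    pair_members: list[tuple[int, int]] = []
    next_taxon = 0
    for sign in signs:
        j, k = next_taxon, next_taxon + 1
        next_taxon += 2
        if sign > 0:
            # near-shared thermal niche couples co-occurrence; the small
            # offset makes the pair's log-ratio divergence (hence alpha)
            # vary smoothly with temperature, planting an environmental
            # signal in association strength
            optima[k] = optima[j] + spec.pair_niche_offset
        else:
            # negative pairs exclude each other: thermal optima mirrored
            # across the midpoint of the sampled temperature range
            optima[k] = t_lo + t_hi - optima[j]
        breadths[k] = breadths[j]
        pair_members.append((j, k))
        ground_truth.append(
            {"taxon_j": taxon_ids[j], "taxon_k": taxon_ids[k],
             "sign": "positive" if sign > 0 else "negative"}
        )

    niche = np.exp(-((temp[:, None] - optima[None, :]) ** 2) / (2.0 * breadths[None, :] ** 2))
    log_abund = (
        spec.log_baseline
        + spec.niche_gain * niche
        + rng.normal(0.0, spec.log_noise_sd, (n, m))
    )
    for (j, k), sign in zip(pair_members, signs):
        latent = rng.normal(0.0, 1.0, n)
        log_abund[:, j] += spec.coupling * latent
        log_abund[:, k] += sign * spec.coupling * latent

    values = np.exp(log_abund)
    present = niche >= spec.presence_cutoff  # structural zeros outside the niche
    # positively planted partners share one habitat window (the first
    # member's), so the pair co-occurs or co-vanishes together; their
    # abundances still diverge smoothly inside the window through the
    # offset optima. Negative pairs keep their own (mirrored) windows.
    for (j, k), sign in zip(pair_members, signs):
        if sign > 0:
            present[:, k] = present[:, j]
    values[~present] = 0.0
    if spec.compositional_closure:
        row_sums = values.sum(axis=1, keepdims=True)
        if np.any(row_sums == 0):
            raise ValueError("a sample lost every taxon; relax presence_cutoff")
        values = values / row_sums

    sample_ids = list(env.sample_ids)
    table = AbundanceTable(
        values=values, sample_ids=sample_ids, taxon_ids=taxon_ids,
        sample_meta=sample_meta,
    )
    return table, ground_truth


def generate_future_grids(
    spec: SyntheticSpec,
    base_grid: GridField,
    years: list[int],
    warming_per_decade: float = 0.3,
    nutrient_decline_fraction_per_decade: float = 0.05,
    noise_sd: float = 0.0,
) -> list[GridField]:
    """Monotone climate trajectories from a base grid (seed offset 4).

    Temperature rises linearly, nitrate declines geometrically at the given
    per-decade fraction and silicate at half that rate; salinity only
    receives noise. The first listed year is the base state.
    """
    rng = np.random.default_rng(spec.seed + 4)
    names = base_grid.feature_names
    i_t, i_n = names.index("temperature"), names.index("nitrate")
    i_si = names.index("silicate")
    base_year = years[0]
    out = []
    for year in years:
        decades = (year - base_year) / 10.0
        f = base_grid.features.copy()
        f[:, i_t] += warming_per_decade * decades
        f[:, i_n] *= (1.0 - nutrient_decline_fraction_per_decade) ** decades
        f[:, i_si] *= (1.0 - nutrient_decline_fraction_per_decade / 2.0) ** decades
        if noise_sd > 0:
            f += rng.normal(0.0, noise_sd, f.shape)
        out.append(
            GridField(
                lat=base_grid.lat, lon=base_grid.lon, features=f,
                feature_names=list(names), time_label=str(year),
                valid_mask=base_grid.valid_mask.copy(),
            )
        )
    return out
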