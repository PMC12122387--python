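"""Synthetic morphometric survey generator with known ground truth.

Emulates a coastal survey of threespine stickleback: ten marine (estuary /
lagoon / inlet) and six freshwater (lake) sites, 20-60 fish per site, eight
linear traits measured in millimetres plus two counted traits (lateral
plates, gill rakers), all scaling allometrically with standard length.
Site-level means are drawn hierarchically: a habitat base value, a shared
freshwater offset (the "parallel" component of divergence), a site-specific
deviation of that offset (the "non-parallel" component), and residual
among-site jitter.  Fish-level noise is independent Gaussian, so configured
within-site variances are honoured exactly in expectation; counted traits
are rounded to non-negative integers afterwards.

The generator also produces site coordinates, a 19-variable bioclimatic
table driven by three latent geographic factors, and a water/land raster
whose ocean, rivers and lakes connect every site, so the geographic and
environmental analyses can run end to end on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

# Trait order follows the field convention: armour traits, foraging traits,
# then swimming/body traits.
TRAITS = (
    "lateral_plate_number",
    "first_dorsal_spine_length",
    "second_dorsal_spine_length",
    "pelvic_spine_length",
    "pelvic_girdle_length",
    "gill_raker_number",
    "mouth_width",
    "eye_diameter",
    "body_depth",
    "caudal_peduncle_length",
)

COUNT_TRAITS = ("lateral_plate_number", "gill_raker_number")

#: Default per-site sample sizes for the 10 marine and 6 freshwater sites.
MARINE_N = (20, 39, 40, 38, 22, 60, 60, 25, 20, 27)
FRESHWATER_N = (29, 25, 30, 30, 30, 29)

_D = dict  # brevity in the default tables below

#: Marine (ancestral-proxy) trait means at the mean standard length, in mm
#: for linear traits and counts for plates/rakers.
DEFAULT_MARINE_MEANS = _D(
    lateral_plate_number=32.0,
    first_dorsal_spine_length=5.5,
    second_dorsal_spine_length=6.0,
    pelvic_spine_length=7.5,
    pelvic_girdle_length=10.5,
    gill_raker_number=21.0,
    mouth_width=4.0,
    eye_diameter=4.5,
    body_depth=11.0,
    caudal_peduncle_length=4.0,
)

#: Shared freshwater offset: loss of armour, fewer gill rakers, deeper body.
DEFAULT_PARALLEL_EFFECT = _D(
    lateral_plate_number=-25.0,
    first_dorsal_spine_length=-0.8,
    second_dorsal_spine_length=-0.9,
    pelvic_spine_length=-1.6,
    pelvic_girdle_length=-1.8,
    gill_raker_number=-2.5,
    mouth_width=-0.2,
    eye_diameter=0.1,
    body_depth=1.2,
    caudal_peduncle_length=0.0,
)

#: Within-site (fish-level) SDs; ~70% of the marine trait variance.
DEFAULT_TRAIT_SDS = _D(
    lateral_plate_number=0.35,
    first_dorsal_spine_length=0.65,
    second_dorsal_spine_length=0.47,
    pelvic_spine_length=0.43,
    pelvic_girdle_length=0.65,
    gill_raker_number=2.7,
    mouth_width=0.28,
    eye_diameter=0.20,
    body_depth=0.43,
    caudal_peduncle_length=0.12,
)

#: Among-site jitter applied to every site's mean (both habitats).
DEFAULT_AMONG_SITE_SD = _D(
    lateral_plate_number=0.1,
    first_dorsal_spine_length=0.4,
    second_dorsal_spine_length=0.3,
    pelvic_spine_length=0.28,
    pelvic_girdle_length=0.42,
    gill_raker_number=1.7,
    mouth_width=0.18,
    eye_diameter=0.13,
    body_depth=0.28,
    caudal_peduncle_length=0.08,
)

#: Site-specific deviation of the freshwater offset (non-parallel component);
#: drives realised theta angles away from zero.
DEFAULT_NONPARALLEL_SD = _D(
    lateral_plate_number=3.0,
    first_dorsal_spine_length=0.3,
    second_dorsal_spine_length=0.3,
    pelvic_spine_length=0.5,
    pelvic_girdle_length=0.6,
    gill_raker_number=1.2,
    mouth_width=0.15,
    eye_diameter=0.10,
    body_depth=0.4,
    caudal_peduncle_length=0.10,
)

#: Slope of each raw trait on standard length (mm trait per mm length).
DEFAULT_ALLOMETRIC_SLOPES = _D(
    lateral_plate_number=0.05,
    first_dorsal_spine_length=0.08,
    second_dorsal_spine_length=0.09,
    pelvic_spine_length=0.12,
    pelvic_girdle_length=0.18,
    gill_raker_number=0.02,
    mouth_width=0.07,
    eye_diameter=0.06,
    body_depth=0.25,
    caudal_peduncle_length=0.06,
)


class SimConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


def _as_trait_dict(value, name: str) -> dict[str, float]:
    if isinstance(value, dict):
        missing = set(TRAITS) - set(value)
        if missing:
            raise SimConfigError(f"{name} missing traits: {sorted(missing)}")
        return {t: float(value[t]) for t in TRAITS}
    value = np.asarray(value, dtype=float)
    if value.shape != (len(TRAITS),):
        raise SimConfigError(f"{name} must have one value per trait ({len(TRAITS)})")
    return dict(zip(TRAITS, value.tolist()))


@dataclass
class SimConfig:
    """Parameters of the synthetic survey; defaults reproduce the study design
    (10 marine + 6 freshwater sites, 20-60 fish each, classic marine-freshwater
    trait contrasts)."""

    n_marine_sites: int = 10
    n_freshwater_sites: int = 6
    n_per_site: int | Sequence[int] | None = None  # None -> study sample sizes
    trait_means_marine: dict = field(default_factory=lambda: dict(DEFAULT_MARINE_MEANS))
    parallel_effect: dict = field(default_factory=lambda: dict(DEFAULT_PARALLEL_EFFECT))
    trait_sds: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SDS))
    among_site_sd: dict = field(default_factory=lambda: dict(DEFAULT_AMONG_SITE_SD))
    nonparallel_sd: dict = field(default_factory=lambda: dict(DEFAULT_NONPARALLEL_SD))
    allometric_slopes: dict = field(
        default_factory=lambda: dict(DEFAULT_ALLOMETRIC_SLOPES)
    )
    length_mean_mm: float = 50.71
    length_sd_mm: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_marine_sites < 1 or self.n_freshwater_sites < 1:
            raise SimConfigError("site counts must be >= 1")
        self.trait_means_marine = _as_trait_dict(self.trait_means_marine, "trait_means_marine")
        self.parallel_effect = _as_trait_dict(self.parallel_effect, "parallel_effect")
        for name in ("trait_sds", "among_site_sd", "nonparallel_sd"):
            d = _as_trait_dict(getattr(self, name), name)
            if any(v < 0 for v in d.values()):
                raise SimConfigError(f"{name} must be non-negative")
            setattr(self, name, d)
        self.allometric_slopes = _as_trait_dict(self.allometric_slopes, "allometric_slopes")
        if self.length_mean_mm <= 0 or self.length_sd_mm < 0:
            raise SimConfigError("length_mean_mm must be > 0 and length_sd_mm >= 0")
        for n in self.site_sample_sizes():
            if n < 2:
                raise SimConfigError("every site needs n_per_site >= 2")

    @property
    def trait_means_freshwater(self) -> dict[str, float]:
        return {
            t: self.trait_means_marine[t] + self.parallel_effect[t] for t in TRAITS
        }

    def site_sample_sizes(self) -> list[int]:
        """Per-site sample sizes, marine sites first."""
        k = self.n_marine_sites + self.n_freshwater_sites
        if self.n_per_site is None:
            marine = [MARINE_N[i % len(MARINE_N)] for i in range(self.n_marine_sites)]
            fresh = [
                FRESHWATER_N[i % len(FRESHWATER_N)]
                for i in range(self.n_freshwater_sites)
            ]
            return marine + fresh
        if np.isscalar(self.n_per_site):
            return [int(self.n_per_site)] * k
        sizes = [int(n) for n in self.n_per_site]
        if len(sizes) != k:
            raise SimConfigError(f"n_per_site list must have {k} entries")
        return sizes

    def site_names(self) -> tuple[list[str], list[str]]:
        marine = [f"marine_{i + 1:02d}" for i in range(self.n_marine_sites)]
        fresh = [f"lake_{i + 1:02d}" for i in range(self.n_freshwater_sites)]
        return marine, fresh


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset, for parameter-recovery tests.

    ``site_means`` are the realised site-level expected trait values at the
    mean standard length.  ``divergence_directions`` are the expected
    freshwater-minus-marine offset vectors in raw trait space (marine habitat
    base as origin).  ``expected_theta_deg`` holds the angle between those
    offset vectors for every unordered freshwater pair; with no non-parallel
    component all offsets coincide and every expected theta is zero.
    """

    site_means: pd.DataFrame
    divergence_directions: pd.DataFrame
    expected_theta_deg: pd.DataFrame


def _pairwise_angles_deg(vectors: pd.DataFrame) -> pd.DataFrame:
    rows = []
    sites = list(vectors.index)
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            va, vb = vectors.loc[a].to_numpy(), vectors.loc[b].to_numpy()
            na, nb = np.linalg.norm(va), np.linalg.norm(vb)
            if na == 0 or nb == 0:
                ang = np.nan
            else:
                ang = np.degrees(np.arccos(np.clip(va @ vb / (na * nb), -1.0, 1.0)))
            rows.append({"site_a": a, "site_b": b, "theta_deg": ang})
    return pd.DataFrame(rows)


def generate_specimens(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate one survey.

    Returns ``(specimens, metadata, truth)`` where ``specimens`` has one row
    per fish (site, habitat, standard_length_mm, 10 trait columns),
    ``metadata`` has one row per site (site, habitat, latitude, longitude)
    and ``truth`` records the realised site means and expected divergence
    geometry.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    marine_sites, fresh_sites = config.site_names()
    sizes = config.site_sample_sizes()
    habitats = ["marine"] * config.n_marine_sites + [
        "freshwater"
    ] * config.n_freshwater_sites

    # site-level expected means (hierarchical draw, one per site)
    site_means = {}
    directions = {}
    for site, habitat in zip(marine_sites + fresh_sites, habitats):
        means = {}
        offset = {}
        for t in TRAITS:
            m = config.trait_means_marine[t]
            off = 0.0
            if habitat == "freshwater":
                off = config.parallel_effect[t] + rng.normal(
                    0.0, config.nonparallel_sd[t]
                )
            means[t] = m + off + rng.normal(0.0, config.among_site_sd[t])
            offset[t] = off
        site_means[site] = means
        if habitat == "freshwater":
            directions[site] = offset

    rows = []
    for site, habitat, n in zip(marine_sites + fresh_sites, habitats, sizes):
        lengths = rng.normal(config.length_mean_mm, config.length_sd_mm, size=n)
        lengths = np.clip(lengths, 1.0, None)
        for j in range(n):
            row = {
                "site": site,
                "habitat": habitat,
                "standard_length_mm": lengths[j],
            }
            for t in TRAITS:
                value = (
                    site_means[site][t]
                    + config.allometric_slopes[t]
                    * (lengths[j] - config.length_mean_mm)
                    + rng.normal(0.0, config.trait_sds[t])
                )
                if t in COUNT_TRAITS:
                    value = max(0.0, round(value))
                row[t] = value
            rows.append(row)
    specimens = pd.DataFrame(rows)

    metadata = _site_metadata(config, rng, marine_sites, fresh_sites)

    means_df = pd.DataFrame(site_means).T.loc[marine_sites + fresh_sites, list(TRAITS)]
    dir_df = pd.DataFrame(directions).T.reindex(columns=list(TRAITS))
    truth = TruthRecord(
        site_means=means_df,
        divergence_directions=dir_df,
        expected_theta_deg=_pairwise_angles_deg(dir_df),
    )
    return specimens, metadata, truth


def _site_metadata(config, rng, marine_sites, fresh_sites) -> pd.DataFrame:
    """Coastal layout: marine sites along a western shoreline band, lakes
    inland to the east, spread over ~2 degrees of latitude."""
    rows = []
    lat0, lat1 = 48.4, 50.6
    n_m, n_f = len(marine_sites), len(fresh_sites)
    for i, site in enumerate(marine_sites):
        lat = lat0 + (lat1 - lat0) * (i + 0.5) / n_m + rng.normal(0, 0.05)
        lon = -126.0 + rng.normal(0, 0.15)
        rows.append({"site": site, "habitat": "marine", "latitude": lat, "longitude": lon})
    for i, site in enumerate(fresh_sites):
        lat = lat0 + (lat1 - lat0) * (i + 0.5) / n_f + rng.normal(0, 0.05)
        lon = -124.2 + rng.normal(0, 0.25)
        rows.append(
            {"site": site, "habitat": "freshwater", "latitude": lat, "longitude": lon}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# climate

BIO_VARS = tuple(f"BIO{i:02d}" for i in range(1, 20))

# latent factor loadings: factor 0 = thermal gradient (latitude-driven),
# factor 1 = precipitation gradient (longitude/orographic), factor 2 =
# seasonality. Temperature-level variables load together on factor 0 and
# precipitation totals on factor 1 strongly enough that |r| > 0.80 within
# each block, which is what triggers collinearity pruning downstream.
_BIO_LOADINGS = {
    "BIO01": (1.0, 0.0, 0.0),
    "BIO02": (0.15, -0.1, 0.7),
    "BIO03": (-0.45, 0.2, 0.45),
    "BIO04": (0.2, 0.0, 1.0),
    "BIO05": (1.0, 0.0, 0.3),
    "BIO06": (1.0, 0.0, -0.3),
    "BIO07": (0.1, 0.0, 1.0),
    "BIO08": (0.6, 0.5, 0.1),
    "BIO09": (0.9, -0.2, 0.0),
    "BIO10": (1.0, 0.0, 0.15),
    "BIO11": (1.0, 0.0, -0.15),
    "BIO12": (0.0, 1.0, 0.0),
    "BIO13": (0.0, 1.0, 0.25),
    "BIO14": (0.0, 0.9, -0.35),
    "BIO15": (0.1, 0.35, -0.6),
    "BIO16": (0.0, 1.0, 0.2),
    "BIO17": (0.0, 0.95, -0.25),
    "BIO18": (0.1, 0.9, -0.2),
    "BIO19": (-0.1, 0.95, 0.25),
}
# the "annual" variables (BIO01-03, 08, 12, 15) get extra independent noise
# so they stay mutually below the pruning threshold, as real annual
# summaries do; redundant monthly/quarterly variables remain collinear with
# their block and are the ones pruned.
_BIO_EXTRA_NOISE = {"BIO02": 0.45, "BIO03": 0.45, "BIO08": 0.35, "BIO15": 0.45}
_BIO_SCALE = {  # rough realistic units: degC for 01-11, mm for 12-19
    "BIO01": (9.0, 1.5), "BIO02": (7.0, 0.8), "BIO03": (45.0, 3.0),
    "BIO04": (450.0, 40.0), "BIO05": (21.0, 1.8), "BIO06": (-1.0, 1.8),
    "BIO07": (22.0, 2.0), "BIO08": (5.0, 1.6), "BIO09": (14.0, 1.7),
    "BIO10": (15.0, 1.6), "BIO11": (3.0, 1.6), "BIO12": (1800.0, 400.0),
    "BIO13": (300.0, 70.0), "BIO14": (30.0, 12.0), "BIO15": (55.0, 8.0),
    "BIO16": (800.0, 180.0), "BIO17": (120.0, 40.0), "BIO18": (140.0, 45.0),
    "BIO19": (750.0, 170.0),
}


def generate_climate(metadata: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Per-site table of the 19 bioclimatic variables (BIO01-BIO19).

    Values are linear combinations of three latent geographic factors (a
    thermal gradient tied to latitude, a precipitation gradient tied to
    longitude, and a seasonality factor) plus measurement noise, on roughly
    WorldClim-like scales.  Variables within the temperature and
    precipitation blocks are correlated above the conventional |r| = 0.80
    pruning threshold by construction.
    """
    if len(metadata) == 0:
        raise ValueError("metadata is empty")
    rng = np.random.default_rng(seed)
    lat = metadata["latitude"].to_numpy(dtype=float)
    lon = metadata["longitude"].to_numpy(dtype=float)
    z = lambda x: (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    n = len(metadata)
    factors = np.column_stack(
        [
            -z(lat) + 0.15 * rng.normal(size=n),
            z(lon) + 0.15 * rng.normal(size=n),
            rng.normal(size=n),
        ]
    )
    out = {"site": metadata["site"].to_numpy()}
    for var in BIO_VARS:
        load = np.asarray(_BIO_LOADINGS[var])
        signal = factors @ load
        noise_sd = (0.15 + _BIO_EXTRA_NOISE.get(var, 0.0)) * max(
            np.linalg.norm(load), 1e-9
        )
        latent = signal + rng.normal(0.0, noise_sd, size=n)
        mu, sd = _BIO_SCALE[var]
        out[var] = mu + sd * latent / max(np.linalg.norm(load), 1e-9)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# water raster

def generate_water_raster(shape, land_cells=(), resolution_km: float = 1.0):
    """Boolean water grid: every cell is water except the listed land cells."""
    from mfdiv.geo_env import WaterRaster  # avoid import cycle at module load

    if resolution_km <= 0:
        raise ValueError("resolution_km must be > 0")
    nrow, ncol = int(shape[0]), int(shape[1])
    if nrow < 1 or ncol < 1:
        raise ValueError("shape must be positive")
    water = np.ones((nrow, ncol), dtype=bool)
    for r, c in land_cells:
        if not (0 <= r < nrow and 0 <= c < ncol):
            raise ValueError(f"land cell {(r, c)} outside grid {shape}")
        water[r, c] = False
    return WaterRaster(water=water, resolution_km=float(resolution_km))


def synthetic_geography(
    metadata: pd.DataFrame, shape=(60, 60), resolution_km: float = 5.0
):
    """Raster + per-site cells for the synthetic coastline.

    The western third of the grid is ocean; each freshwater site sits in a
    small lake connected to the ocean by a river carved along its row, so all
    sites are mutually reachable through water.  Returns ``(raster,
    site_cells)`` with ``site_cells`` a dict site -> (row, col).
    """
    from mfdiv.geo_env import WaterRaster

    nrow, ncol = shape
    water = np.zeros((nrow, ncol), dtype=bool)
    coast = ncol // 3
    water[:, :coast] = True  # ocean band

    lat = metadata["latitude"]
    lon = metadata["longitude"]
    lat_lo, lat_hi = lat.min() - 0.05, lat.max() + 0.05
    lon_lo, lon_hi = lon.min() - 0.05, lon.max() + 0.05

    def cell(la, lo):
        r = int((lat_hi - la) / (lat_hi - lat_lo) * (nrow - 1))
        c = int((lo - lon_lo) / (lon_hi - lon_lo) * (ncol - 1))
        return min(max(r, 0), nrow - 1), min(max(c, 0), ncol - 1)

    site_cells = {}
    for _, row in metadata.iterrows():
        r, c = cell(row["latitude"], row["longitude"])
        if row["habitat"] == "marine":
            c = min(c, coast - 1)  # marine sites sit in the ocean band
        else:
            c = max(c, coast + 2)  # lakes inland
            water[r, coast:c + 1] = True  # river to the ocean
            rr = slice(max(r - 1, 0), min(r + 2, nrow))
            water[rr, max(c - 1, 0):min(c + 2, ncol)] = True  # the lake
        site_cells[row["site"]] = (r, c)
    return WaterRaster(water=water, resolution_km=float(resolution_km)), site_cells


def with_no_divergence(config: SimConfig) -> SimConfig:
    """Copy of ``config`` with no habitat effect at all (null generator)."""
    zero = {t: 0.0 for t in TRAITS}
    return replace(config, parallel_effect=dict(zero), nonparallel_sd=dict(zero))
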