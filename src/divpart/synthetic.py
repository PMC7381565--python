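"""Synthetic communities, environment tables and paleoclimate grids.

The generator emulates the sampling design of a latitudinal soil-nematode
survey: 16 sites spanning 22-40 degrees N, three plots per site averaged to
site level, and ~150 individuals identified to genus per plot (multinomial
subsampling).  Environmental variables come in the three predictor sets
(climatic, soil, historical), each driven by one latent factor; latent
factors share a configurable pairwise cross-set correlation through a
common latitudinal component, so collinearity between predictor sets — the
reason variation partitioning is needed at all — is under experimental
control.

Diversity responds to a linear combination of the set latents (the
``effect_sizes`` mapping), realized through a Gaussian-niche community
model: genus optima spread along a composite gradient, and the evenness of
the niche weights rises with the site's diversity driver, so both richness
and Shannon's diversity track it after multinomial subsampling.  Because
the driver is linear in jointly Gaussian latents, the pure/shared
adjusted-variance fractions it generates have a closed form, recorded as
the dataset's ground truth.

All randomness flows from one master seed via named substreams, so adding
one component never perturbs another's draws.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .containers import CommunityMatrix, PredictorTable
from .paleoclim import ClimateGrid

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "gen_env_tables",
    "gen_community",
    "gen_dataset",
    "gen_null_dataset",
    "gen_paleo_grids",
]

_SETS = ("climatic", "soil", "historical")

# variable roster: (name, set, baseline, slope on the set latent)
# magnitudes loosely follow a temperate latitudinal gradient in China
_VARIABLE_DEFS = [
    ("MAT", "climatic", 14.0, -6.0),  # degC
    ("MAP", "climatic", 1000.0, -450.0),  # mm
    ("TS", "climatic", 700.0, 250.0),  # sd of monthly T x 100
    ("PS", "climatic", 60.0, -15.0),
    ("SOC", "soil", 18.0, 6.0),  # g/kg
    ("TN", "soil", 1.5, 0.5),  # g/kg
    ("pH", "soil", 6.8, -0.9),
    ("TA", "historical", 6.0, 1.5),  # degC
    ("PA", "historical", 250.0, 80.0),  # mm
    ("TCV", "historical", 2.5, 0.6),  # log10 km
    ("PCV", "historical", 2.2, 0.5),
]
#: fraction of the slope magnitude used as independent per-variable noise
_VARIABLE_NOISE = 0.3


@dataclass
class SimulationConfig:
    """Parameters of the stated synthetic world.

    ``effect_sizes`` maps predictor-set name to the standardized slope of
    the latent diversity driver on that set's latent factor;
    ``cross_set_correlation`` is the pairwise correlation between set
    latents (induced by a shared latitudinal component, so latitude
    coupling is its square root); ``noise_sd`` is the driver's residual
    standard deviation; ``plot_sd`` the plot-to-plot jitter of the niche
    gradient position.
    """

    n_sites: int = 16
    n_plots: int = 3
    n_genera: int = 64
    individuals_identified: int = 150
    lat_range: tuple[float, float] = (22.0, 40.0)
    effect_sizes: dict[str, float] = dc_field(default_factory=dict)
    cross_set_correlation: float = 0.6
    noise_sd: float = 0.5
    plot_sd: float = 0.3
    niche_breadth: float = 1.0
    dominance_scale: float = 5.0
    dominance_sensitivity: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 4:
            raise ValueError("n_sites must be >= 4")
        for name in ("n_plots", "n_genera", "individuals_identified"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        bad = set(self.effect_sizes) - set(_SETS)
        if bad:
            raise ValueError(f"unknown predictor sets in effect_sizes: {sorted(bad)}")
        if not (0.0 <= self.cross_set_correlation < 1.0):
            raise ValueError(
                "cross_set_correlation must be in [0, 1): the latent covariance "
                "degenerates at 1"
            )
        if self.noise_sd <= 0 or self.plot_sd < 0 or self.niche_breadth <= 0:
            raise ValueError("noise_sd and niche_breadth must be positive; plot_sd >= 0")

    def substream(self, name: str) -> np.random.Generator:
        """Named, independent child stream of the master seed."""
        # stable digest: Python's str hash is salted per process
        key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class SyntheticDataset:
    """Community + environment + site coordinates with known ground truth."""

    community: CommunityMatrix
    env: PredictorTable
    truth: dict[str, float]
    site_coords: np.ndarray  # (n_sites, 2) of (lon, lat) degrees
    plot_counts: np.ndarray | None = None  # (n_sites, n_plots, n_genera) integer counts


def _site_labels(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def _latitudes(cfg: SimulationConfig) -> np.ndarray:
    lo, hi = cfg.lat_range
    return np.linspace(lo, hi, cfg.n_sites)


def gen_env_tables(cfg: SimulationConfig) -> PredictorTable:
    """Generate the 11-variable environment table (4 climatic, 3 soil, 4 historical).

    Each set's latent factor is ``sqrt(rho) * L + sqrt(1 - rho) * eps`` with
    L the standardized latitude and eps set-specific white noise, so any two
    set latents correlate at exactly ``rho = cfg.cross_set_correlation``.
    Variables are affine in their set latent plus independent noise.
    """
    rng = cfg.substream("env")
    lat = _latitudes(cfg)
    L = _zscore(lat)
    rho = cfg.cross_set_correlation
    latents = {
        s: np.sqrt(rho) * L + np.sqrt(1.0 - rho) * rng.standard_normal(cfg.n_sites)
        for s in _SETS
    }
    data = {}
    labels = {}
    for name, pset, base, slope in _VARIABLE_DEFS:
        noise = _VARIABLE_NOISE * abs(slope) * rng.standard_normal(cfg.n_sites)
        data[name] = base + slope * latents[pset] + noise
        labels[name] = pset
    sites = _site_labels(cfg.n_sites)
    return PredictorTable(sites, pd.DataFrame(data, index=sites), labels)


def set_latent_estimates(env: PredictorTable) -> dict[str, np.ndarray]:
    """Recover each set's latent factor from the observed variables.

    Average of the variables' z-scores, sign-aligned with the generating
    slopes; a consistent (if attenuated) estimator of the set latent.
    """
    signs = {name: np.sign(slope) for name, _, _, slope in _VARIABLE_DEFS}
    out = {}
    for pset in _SETS:
        cols = env.variables(pset)
        z = np.column_stack([signs.get(c, 1.0) * _zscore(env.values[c].to_numpy(float))
                             for c in cols])
        out[pset] = _zscore(z.mean(axis=1))
    return out


def diversity_driver(cfg: SimulationConfig, env: PredictorTable) -> np.ndarray:
    """Latent diversity driver: effect-weighted set latents plus noise."""
    rng = cfg.substream("driver")
    latents = set_latent_estimates(env)
    s = np.zeros(cfg.n_sites)
    for pset, a in cfg.effect_sizes.items():
        s = s + a * latents[pset]
    return s + cfg.noise_sd * rng.standard_normal(cfg.n_sites)


def gen_community(cfg: SimulationConfig, env: PredictorTable) -> CommunityMatrix:
    """Gaussian-niche community sampled by plot-level multinomial draws.

    Genus optima are spread uniformly along the composite gradient with a
    common niche breadth.  Site evenness rises with the diversity driver
    (a dominance exponent decays with the standardized driver), so richness
    and Shannon's diversity respond to ``cfg.effect_sizes``.  Each plot's
    counts sum to exactly ``cfg.individuals_identified``; the site matrix is
    the arithmetic plot mean and may be fractional.
    """
    if env.n_sites != cfg.n_sites:
        raise ValueError("environment table row count does not match cfg.n_sites")
    rng = cfg.substream("community")
    s = diversity_driver(cfg, env)
    g = _zscore(s)
    span = 2.0 * cfg.niche_breadth
    optima = rng.uniform(g.min() - span, g.max() + span, size=cfg.n_genera)
    rank = np.arange(cfg.n_genera) / max(cfg.n_genera - 1, 1)
    plot_counts = np.zeros((cfg.n_sites, cfg.n_plots, cfg.n_genera), dtype=np.int64)
    for i in range(cfg.n_sites):
        dominance = cfg.dominance_scale * np.exp(-cfg.dominance_sensitivity * g[i])
        for plot in range(cfg.n_plots):
            gp = g[i] + cfg.plot_sd * rng.standard_normal()
            niche = np.exp(-((gp - optima) ** 2) / (2.0 * cfg.niche_breadth**2))
            w = niche * np.exp(-dominance * rank)
            total = w.sum()
            if total <= 0:
                raise ValueError(
                    f"site {_site_labels(cfg.n_sites)[i]!r}: all niche weights are zero"
                )
            plot_counts[i, plot] = rng.multinomial(cfg.individuals_identified, w / total)
    site_abund = plot_counts.mean(axis=1)
    genera = [f"G{j + 1:02d}" for j in range(cfg.n_genera)]
    cm = CommunityMatrix(_site_labels(cfg.n_sites), genera, site_abund)
    cm._plot_counts = plot_counts  # raw plot-level draws, for inspection
    return cm


def _truth_fractions(cfg: SimulationConfig) -> dict[str, float]:
    """Closed-form pure/shared variance fractions of the linear driver.

    The driver is linear in equicorrelated standard-normal latents, so the
    population R^2 of every latent subset has a closed form; the seven
    fractions follow by inclusion-exclusion.  This is ground truth for the
    driver itself — sampling the community attenuates but cannot reorder it.
    """
    rho = cfg.cross_set_correlation
    a = np.array([cfg.effect_sizes.get(s, 0.0) for s in _SETS])
    R = np.full((3, 3), rho) + (1.0 - rho) * np.eye(3)
    var_s = float(a @ R @ a) + cfg.noise_sd**2

    def r2(subset):
        idx = list(subset)
        cov = R[idx] @ a  # cov(driver, latents in subset)
        return float(cov @ np.linalg.solve(R[np.ix_(idx, idx)], cov)) / var_s

    names = {0: "C", 1: "S", 2: "H"}
    r = {"".join(names[i] for i in sub): r2(sub)
         for k in (1, 2, 3) for sub in itertools.combinations(range(3), k)}
    return {
        "C": r["CSH"] - r["SH"],
        "S": r["CSH"] - r["CH"],
        "H": r["CSH"] - r["CS"],
        "CS": r["CH"] + r["SH"] - r["CSH"] - r["H"],
        "CH": r["CS"] + r["SH"] - r["CSH"] - r["S"],
        "SH": r["CS"] + r["CH"] - r["CSH"] - r["C"],
        "CSH": r["C"] + r["S"] + r["H"] - r["CS"] - r["CH"] - r["SH"] + r["CSH"],
    }


def gen_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Full synthetic dataset: environment, community, coordinates, truth."""
    env = gen_env_tables(cfg)
    community = gen_community(cfg, env)
    rng = cfg.substream("coords")
    lat = _latitudes(cfg)
    lon = rng.uniform(100.0, 120.0, size=cfg.n_sites)
    coords = np.column_stack([lon, lat])
    return SyntheticDataset(
        community=community,
        env=env,
        truth=_truth_fractions(cfg),
        site_coords=coords,
        plot_counts=community._plot_counts,
    )


def gen_null_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Dataset whose diversity is pure noise, independent of all predictors.

    All effect sizes are forced to zero; the recorded truth is zero for
    every fraction.  This is the type-I-error harness for the permutation
    tests.
    """
    null_cfg = SimulationConfig(
        **{**cfg.__dict__, "effect_sizes": {}},
    )
    ds = gen_dataset(null_cfg)
    ds.truth = {k: 0.0 for k in ds.truth}
    return ds


def gen_paleo_grids(
    nx: int,
    ny: int,
    cellsize_km: float,
    field_spec: dict | None = None,
    seed: int = 0,
) -> tuple[ClimateGrid, ClimateGrid]:
    """Co-registered (current, LGM) grid pair with analytically known structure.

    ``field_spec`` keys: ``kind`` ("planar" or "noisy-planar"), plane
    coefficients ``a``, ``b``, ``c`` (T = a x + b y + c, with x east and y
    north in km from the lower-left corner), ``lgm_offset`` added to the
    current field to form the LGM field (default -4.0, i.e. an anomaly of
    +4), and ``noise_sd`` for the noisy variant.  Planar fields have exact
    anomaly ``-lgm_offset`` and exact gradient magnitude ``hypot(a, b)``.
    """
    if nx < 3 or ny < 3:
        raise ValueError("nx and ny must be >= 3: the gradient stencil needs interior cells")
    spec = dict(field_spec or {})
    kind = spec.get("kind", "planar")
    a = spec.get("a", 0.003)
    b = spec.get("b", 0.004)
    c = spec.get("c", 10.0)
    lgm_offset = spec.get("lgm_offset", -4.0)
    noise_sd = spec.get("noise_sd", 0.5)
    variable = spec.get("variable", "MAT")

    cols = (np.arange(nx) + 0.5) * cellsize_km
    rows_north_up = (ny - np.arange(ny) - 0.5) * cellsize_km
    x, y = np.meshgrid(cols, rows_north_up)
    current = a * x + b * y + c
    lgm = current + lgm_offset
    if kind == "noisy-planar":
        rng = np.random.default_rng(seed)
        current = current + noise_sd * rng.standard_normal(current.shape)
        lgm = lgm + noise_sd * rng.standard_normal(lgm.shape)
    elif kind != "planar":
        raise ValueError(f"unknown field kind {kind!r}")
    mk = lambda v, epoch: ClimateGrid(
        v, cellsize=cellsize_km, origin=(0.0, 0.0), epoch=epoch,
        variable=variable, cell_units="km",
    )
    return mk(current, "current"), mk(lgm, "lgm")
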