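"""Synthetic community-assembly datasets with known ground truth.

The generator produces the same five-table structure the analysis
consumes: plots clustered in three river-basin-like groups across a
configurable spatial extent, a bimodal soil gradient separating two
habitat classes, species with niche optima on that gradient, binary
chemical profiles with controlled sharing, continuous traits loaded on
latent factors, and communities assembled under tunable habitat
filtering (convergence on continuous traits) and limiting-similarity
divergence (on chemical profiles).  Neutral settings —
``sigma_filt = inf`` and ``lambda_div = 0`` — give uniform assembly,
which the calibration tests rely on.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dissimilarity import haversine_km
from .io_validation import (
    AnalysisBundle,
    BinaryTraitMatrix,
    ContinuousTraitMatrix,
    EnvironmentTable,
    OccurrenceMatrix,
    write_bundle,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_environment",
    "generate_species_pool",
    "assemble_communities",
    "generate_dataset",
]

SOIL_VARIABLES = ("P", "NO3", "CN", "K", "Ca", "Mg", "sand", "silt", "clay")
NUTRIENT_VARIABLES = ("P", "NO3", "CN", "K", "Ca")

# native-scale (offset, habitat slope, noise scale) per soil variable;
# negative slope = richer on the clay (h = -1) side
_SOIL_MODEL = {
    "P": (12.0, -4.0, 4.0),
    "NO3": (20.0, -6.0, 6.0),
    "CN": (14.0, 3.5, 3.5),
    "K": (120.0, -35.0, 35.0),
    "Ca": (450.0, -150.0, 150.0),
    "Mg": (90.0, -28.0, 28.0),
}

GOLDEN_ANGLE = 2.399963229728653


@dataclass
class SyntheticConfig:
    n_plots: int = 19
    n_species: int = 29
    n_metabolites: int = 189
    n_traits: int = 14
    n_plots_habitat_a: int | None = None  # white-sand-like class (h = +1); default ~half
    extent_min_km: float = 0.5
    extent_max_km: float = 200.0
    mean_richness: float = 7.0
    sigma_filt: float = math.inf  # habitat filtering strength (smaller = stronger)
    lambda_div: float = 0.0  # limiting-similarity strength (larger = stronger)
    mean_metabolites_per_species: float = 31.4  # sharing parameter
    sm_coverage: float = 27 / 29
    rut_coverage: float = 16 / 29
    habitat_noise: float = 0.15
    soil_noise: float = 1.0
    rut_noise: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_plots", "n_species", "n_metabolites", "n_traits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.lambda_div < 0:
            raise ValueError("lambda_div must be >= 0")
        for name in ("sm_coverage", "rut_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 2 <= self.mean_richness:
            raise ValueError("mean_richness must be at least 2")
        if self.n_plots_habitat_a is None:
            # the 19-plot default splits 9/10; other sizes scale the same way
            self.n_plots_habitat_a = max(1, round(self.n_plots * 9 / 19))
        if not 0 < self.n_plots_habitat_a < self.n_plots:
            raise ValueError("need plots in both habitat classes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if raw.get("sigma_filt") in ("inf", ".inf", None) and "sigma_filt" in raw:
            raw["sigma_filt"] = math.inf
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["sigma_filt"]):
            d["sigma_filt"] = "inf"
        return d


@dataclass
class SyntheticDataset:
    bundle: AnalysisBundle
    ground_truth: dict = field(default_factory=dict)


def _plot_layout(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Plot coordinates in 3 spatial clusters plus habitat assignment."""
    base_lon, base_lat = -73.5, -4.2
    e = config.extent_max_km
    centers_km = np.array([(0.0, 0.0), (0.52 * e, 0.12 * e), (0.92 * e, -0.12 * e)])
    km_per_deg_lat = 111.19
    km_per_deg_lon = km_per_deg_lat * math.cos(math.radians(base_lat))

    rows = []
    cluster_counts: dict[int, int] = {0: 0, 1: 0, 2: 0}
    for i in range(config.n_plots):
        c = i % 3
        k = cluster_counts[c]
        cluster_counts[c] += 1
        # deterministic spiral keeps within-cluster plots >= extent_min apart
        radius = config.extent_min_km * (k + 1) * 1.05
        angle = GOLDEN_ANGLE * k
        x = centers_km[c, 0] + radius * math.cos(angle)
        y = centers_km[c, 1] + radius * math.sin(angle)
        habitat = "habitat_a" if i < config.n_plots_habitat_a else "habitat_b"
        rows.append(
            {
                "plot": f"plot{i + 1:02d}",
                "cluster": c,
                "habitat": habitat,
                "longitude": base_lon + x / km_per_deg_lon,
                "latitude": base_lat + y / km_per_deg_lat,
            }
        )
    return pd.DataFrame(rows).set_index("plot")


def generate_environment(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[EnvironmentTable, pd.DataFrame]:
    """Environment table plus per-plot ground truth (h, cluster, habitat).

    Nine soil variables respond affinely to a bimodal latent habitat
    score h (±1 per class, plus noise); sand/silt/clay live on the
    100% simplex so the texture triple is exactly collinear — feeding
    the VIF-elimination path.
    """
    layout = _plot_layout(config, rng)
    h = np.where(layout["habitat"] == "habitat_a", 1.0, -1.0)
    h = h + config.habitat_noise * rng.standard_normal(len(h))

    s = config.soil_noise
    data = {}
    for var, (a, b, noise) in _SOIL_MODEL.items():
        data[var] = a + b * h + s * noise * rng.standard_normal(len(h))
    sand = 55.0 + 18.0 * h + s * 3.0 * rng.standard_normal(len(h))
    clay = 28.0 - 12.0 * h + s * 2.5 * rng.standard_normal(len(h))
    sand = np.clip(sand, 5.0, 90.0)
    clay = np.clip(clay, 2.0, 80.0)
    over = sand + clay > 95.0
    scale = np.where(over, 95.0 / (sand + clay), 1.0)
    sand, clay = sand * scale, clay * scale
    data["sand"], data["clay"] = sand, clay
    data["silt"] = 100.0 - sand - clay

    soil = pd.DataFrame(data, index=layout.index)[list(SOIL_VARIABLES)]
    coords = layout[["longitude", "latitude"]]
    truth = layout[["cluster", "habitat"]].copy()
    truth["h"] = h
    return EnvironmentTable(soil, coords), truth


def _species_ids(n: int) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(n)]


def generate_species_pool(
    config: SyntheticConfig, rng: np.random.Generator
) -> dict:
    """Species chemistry, continuous traits, niche optima and coverage.

    Chemical profiles are drawn per metabolite: each metabolite occupies
    2 + Poisson(rate) species, with the rate set by the sharing
    parameter (`mean_metabolites_per_species`); at least two holders are
    guaranteed to be chemistry-covered species, and the total count over
    covered species is calibrated to the configured per-species mean.
    Continuous traits load on the niche optimum (first half), on an
    independent latent factor (next block), or on noise alone.
    """
    n_sp = config.n_species
    species = _species_ids(n_sp)
    mu = np.where(
        np.arange(n_sp) % 2 == 0,
        rng.normal(1.0, 0.4, n_sp),
        rng.normal(-1.0, 0.4, n_sp),
    )

    n_sm_cov = max(2, round(config.sm_coverage * n_sp))
    n_rut_cov = max(3, round(config.rut_coverage * n_sp))
    sm_covered = sorted(rng.choice(n_sp, size=n_sm_cov, replace=False))
    rut_covered = sorted(rng.choice(n_sp, size=n_rut_cov, replace=False))

    sm = _generate_chemistry(config, rng, n_sp, sm_covered)

    g = rng.standard_normal(n_sp)  # second latent factor
    n_t = config.n_traits
    traits = np.empty((n_sp, n_t))
    third = max(1, n_t // 2)
    block2 = max(third + 1, (3 * n_t) // 4)
    offsets = rng.uniform(5.0, 50.0, n_t)
    scales = rng.uniform(0.5, 5.0, n_t)
    for t in range(n_t):
        if t < third:
            latent = mu
        elif t < block2:
            latent = g
        else:
            latent = np.zeros(n_sp)
        raw = latent + config.rut_noise * rng.standard_normal(n_sp)
        traits[:, t] = offsets[t] + scales[t] * raw
    trait_ids = [f"trait{t + 1:02d}" for t in range(n_t)]

    return {
        "species_ids": species,
        "mu": pd.Series(mu, index=species, name="niche_optimum"),
        "sm_full": pd.DataFrame(
            sm, index=species, columns=[f"met{m + 1:03d}" for m in range(config.n_metabolites)]
        ),
        "rut_full": pd.DataFrame(traits, index=species, columns=trait_ids),
        "sm_covered": [species[i] for i in sm_covered],
        "rut_covered": [species[i] for i in rut_covered],
    }


def _generate_chemistry(
    config: SyntheticConfig,
    rng: np.random.Generator,
    n_sp: int,
    covered: list[int],
) -> np.ndarray:
    n_met = config.n_metabolites
    n_cov = len(covered)
    covered_arr = np.asarray(covered)
    cov_mask = np.zeros(n_sp, dtype=bool)
    cov_mask[covered_arr] = True

    rate = max(0.0, n_cov * config.mean_metabolites_per_species / n_met - 2.0)
    sm = np.zeros((n_sp, n_met), dtype=int)
    for m in range(n_met):
        k = min(int(2 + rng.poisson(rate)), n_sp)
        first_two = rng.choice(covered_arr, size=2, replace=False)
        holders = set(first_two.tolist())
        remaining = [i for i in range(n_sp) if i not in holders]
        extra = k - 2
        if extra > 0:
            holders.update(rng.choice(remaining, size=min(extra, len(remaining)), replace=False).tolist())
        sm[list(holders), m] = 1

    # every species needs a nonempty profile (Jaccard must be defined)
    for i in np.flatnonzero(sm.sum(axis=1) == 0):
        sm[i, rng.integers(0, n_met)] = 1

    # calibrate the covered-species total to the configured mean
    target = round(n_cov * config.mean_metabolites_per_species)
    target = min(target, n_cov * n_met)
    for _ in range(20 * n_cov * n_met):
        total = int(sm[covered_arr].sum())
        if total == target:
            break
        if total < target:
            zero_r, zero_c = np.nonzero(sm[covered_arr] == 0)
            if len(zero_r) == 0:
                break
            pick = rng.integers(0, len(zero_r))
            sm[covered_arr[zero_r[pick]], zero_c[pick]] = 1
        else:
            one_r, one_c = np.nonzero(sm[covered_arr] == 1)
            col_cov = sm[covered_arr].sum(axis=0)
            row_tot = sm[covered_arr].sum(axis=1)
            ok = (col_cov[one_c] > 2) & (row_tot[one_r] > 1)
            cand = np.flatnonzero(ok)
            if len(cand) == 0:
                break
            pick = cand[rng.integers(0, len(cand))]
            sm[covered_arr[one_r[pick]], one_c[pick]] = 0
    return sm


def _jaccard_full(sm: np.ndarray) -> np.ndarray:
    b = sm.astype(bool)
    inter = (b[:, None, :] & b[None, :, :]).sum(axis=2)
    union = (b[:, None, :] | b[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return d


def assemble_communities(
    pool: dict,
    env_truth: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> OccurrenceMatrix:
    """Fill plots sequentially under filtering and divergence pressure.

    A candidate species s joins plot p with probability proportional to
    exp(-(mu_s - h_p)^2 / (2 sigma_filt^2)) *
    exp(lambda_div * mean Jaccard dissimilarity to residents).
    Neutral settings reduce this to a uniform draw without replacement.
    """
    species = pool["species_ids"]
    mu = pool["mu"].to_numpy()
    n_sp = len(species)
    jac = _jaccard_full(pool["sm_full"].to_numpy())

    plots = list(env_truth.index)
    h = env_truth["h"].to_numpy()
    occ = np.zeros((len(plots), n_sp), dtype=int)
    mean_extra = max(0.0, config.mean_richness - 2.0)
    for pi in range(len(plots)):
        richness = 2 + int(rng.poisson(mean_extra))
        richness = min(richness, n_sp)
        if richness > n_sp:
            raise ValueError("target richness exceeds species pool size")
        if math.isinf(config.sigma_filt):
            log_filt = np.zeros(n_sp)
        else:
            log_filt = -((mu - h[pi]) ** 2) / (2.0 * config.sigma_filt**2)
        residents: list[int] = []
        for _ in range(richness):
            candidates = np.array([s for s in range(n_sp) if s not in residents])
            lw = log_filt[candidates].copy()
            if config.lambda_div > 0 and residents:
                lw = lw + config.lambda_div * jac[np.ix_(candidates, residents)].mean(axis=1)
            w = np.exp(lw - lw.max())
            w /= w.sum()
            residents.append(int(rng.choice(candidates, p=w)))
        occ[pi, residents] = 1
    return OccurrenceMatrix(pd.DataFrame(occ, index=plots, columns=species))


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Full bundle plus ground-truth sidecar; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    env, truth = generate_environment(config, rng)
    pool = generate_species_pool(config, rng)
    occurrence = assemble_communities(pool, truth, config, rng)

    sm = BinaryTraitMatrix(pool["sm_full"].loc[pool["sm_covered"]].copy())
    rut = ContinuousTraitMatrix(pool["rut_full"].loc[pool["rut_covered"]].copy())
    bundle = AnalysisBundle(occurrence, sm, rut, env)

    truth_out = {
        "config": config.to_dict(),
        "niche_optima": pool["mu"].to_dict(),
        "plot_truth": truth.to_dict(orient="index"),
        "sm_covered": pool["sm_covered"],
        "rut_covered": pool["rut_covered"],
    }
    dataset = SyntheticDataset(bundle=bundle, ground_truth=truth_out)
    if out_dir is not None:
        out = Path(out_dir)
        write_bundle(bundle, out)
        (out / "ground_truth.json").write_text(json.dumps(truth_out, indent=2))
    return dataset
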