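"""Seeded synthetic inputs mimicking a two-ecotype barrier study.

Every generator draws from a substream of one root seed (via
``numpy.random.SeedSequence.spawn``), so the full input set is reproducible
from a single integer and each module's inputs can be regenerated
independently.

Defaults mirror the motivating field study of parapatric white-sand /
brown-sand tree ecotypes: 103 vs 76 occurrence points on anti-correlated
suitability surfaces over a 250 m grid; 12 vs 39 monitored trees censused
biweekly for 36 months with a shared flowering season but higher flowering
abundance in the brown-sand population; 15 insect morphospecies with strongly
divergent visitation profiles (expected Bray-Curtis dissimilarity about
0.82); and hand crosses with 38 parental / 104 hybrid flowers, adhesion means
159 vs 112 grains (negative-binomial, overdispersed), germination
probabilities 0.46 vs 0.44, and seed-set rates 0.39 vs 0.164.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .crossing import CrossRecord
from .ecogeography import OccurrenceSet, SuitabilityGrid
from .pollinators import VisitationTable

__all__ = [
    "GridConfig",
    "PhenologyConfig",
    "PollinatorConfig",
    "CrossingConfig",
    "SimulationConfig",
    "make_suitability_pair",
    "make_phenology",
    "make_visitation",
    "make_crosses",
    "expected_stage_ri",
    "expected_phenology_series",
    "expected_visitation_dissimilarity",
]

# Visitation profile shaped like the observed morphospecies skew: a few taxa
# shared at very different frequencies, most exclusive to one ecotype.
_DEFAULT_VISITS_A = (22, 6, 9, 0, 0, 0, 0, 0, 2, 0, 0, 0, 0, 0, 1)
_DEFAULT_VISITS_B = (4, 4, 84, 2, 9, 10, 7, 1, 34, 10, 2, 8, 1, 1, 0)


@dataclass(frozen=True)
class GridConfig:
    rows: int = 80
    cols: int = 100
    pixel_size: float = 250.0
    correlation_length_px: float = 4.0
    contrast: float = 3.0
    n_occurrences_a: int = 103
    n_occurrences_b: int = 76
    n_background: int = 10_000


@dataclass(frozen=True)
class PhenologyConfig:
    n_trees_a: int = 12
    n_trees_b: int = 39
    n_months: int = 36
    # per-month flowering probability = level * seasonal shape in [0, 1]
    level_a: float = 0.35
    level_b: float = 0.6
    peak_month: int = 9          # month-of-year of the flowering peak (1-12)
    season_width: float = 2.0    # SD of the seasonal bump, months
    season_floor: float = 0.05
    censuses_per_month: int = 2
    start: str = "2006-01"


@dataclass(frozen=True)
class PollinatorConfig:
    proportions_a: tuple = tuple(v / sum(_DEFAULT_VISITS_A) for v in _DEFAULT_VISITS_A)
    proportions_b: tuple = tuple(v / sum(_DEFAULT_VISITS_B) for v in _DEFAULT_VISITS_B)
    total_visits_a: int = 40
    total_visits_b: int = 177
    concentration: float | None = None  # Dirichlet jitter around the proportions


@dataclass(frozen=True)
class CrossingConfig:
    n_parental: int = 38
    n_hybrid: int = 104
    n_negative_controls: int = 20
    adhesion_mean_parental: float = 159.0
    adhesion_mean_hybrid: float = 112.0
    adhesion_dispersion: float = 3.0  # NB shape k; +inf-like large k ~ Poisson
    germination_p_parental: float = 0.46
    germination_p_hybrid: float = 0.44
    seed_rate_parental: float = 0.39
    seed_rate_hybrid: float = 0.164


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    grid: GridConfig = field(default_factory=GridConfig)
    phenology: PhenologyConfig = field(default_factory=PhenologyConfig)
    pollinators: PollinatorConfig = field(default_factory=PollinatorConfig)
    crossing: CrossingConfig = field(default_factory=CrossingConfig)
    ecotype_a: str = "white_sand"
    ecotype_b: str = "brown_sand"

    def rngs(self) -> dict[str, np.random.Generator]:
        """One independent generator per module, spawned from the root seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("grid", "phenology", "pollinators", "crossing")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# habitat suitability + occurrences
# ---------------------------------------------------------------------------

def _latent_field(rng: np.random.Generator, rows: int, cols: int, corr_px: float) -> np.ndarray:
    """Standardized Gaussian random field via kernel-smoothed white noise."""
    z = rng.standard_normal((rows, cols))
    if corr_px > 0:
        z = ndimage.gaussian_filter(z, sigma=corr_px, mode="wrap")
    z = (z - z.mean()) / z.std()
    return z


def make_suitability_pair(
    config: SimulationConfig,
) -> tuple[SuitabilityGrid, SuitabilityGrid, OccurrenceSet]:
    """Two anti-correlated suitability surfaces plus occurrence points.

    A smooth latent soil field is mapped through a logistic link to
    suitability for ecotype A and through the sign-flipped link for ecotype B;
    ``contrast`` scales the link slope, so contrast 0 gives identical
    surfaces and large contrast gives near-disjoint niches.  Occurrences are
    sampled across pixels with probability proportional to suitability and
    placed at pixel centers.
    """
    g = config.grid
    rng = config.rngs()["grid"]
    z = _latent_field(rng, g.rows, g.cols, g.correlation_length_px)
    suit_a = special.expit(g.contrast * z)
    suit_b = special.expit(-g.contrast * z)
    origin = (0.0, g.rows * g.pixel_size)
    grid_a = SuitabilityGrid(suit_a, g.pixel_size, origin, "synthetic")
    grid_b = SuitabilityGrid(suit_b, g.pixel_size, origin, "synthetic")

    def _sample(surface: np.ndarray, n: int, ecotype: str) -> pd.DataFrame:
        p = surface.ravel() / surface.sum()
        idx = rng.choice(surface.size, size=n, replace=True, p=p)
        r, c = np.unravel_index(idx, surface.shape)
        x = (c + 0.5) * g.pixel_size
        y = origin[1] - (r + 0.5) * g.pixel_size
        return pd.DataFrame({"x": x, "y": y, "ecotype": ecotype})

    points = pd.concat(
        [
            _sample(suit_a, g.n_occurrences_a, config.ecotype_a),
            _sample(suit_b, g.n_occurrences_b, config.ecotype_b),
        ],
        ignore_index=True,
    )
    return grid_a, grid_b, OccurrenceSet(points)


def sample_background(grid: SuitabilityGrid, n: int, rng: np.random.Generator) -> np.ndarray:
    """Suitability scores at n uniformly drawn background pixels."""
    finite = grid.values[np.isfinite(grid.values)].ravel()
    return rng.choice(finite, size=n, replace=True)


# ---------------------------------------------------------------------------
# phenology
# ---------------------------------------------------------------------------

def _monthly_curve(cfg: PhenologyConfig, level: float) -> np.ndarray:
    """Per-month flowering probability over the simulated span."""
    months = np.arange(cfg.n_months)
    moy = months % 12 + 1
    dist = np.minimum(np.abs(moy - cfg.peak_month), 12 - np.abs(moy - cfg.peak_month))
    shape = cfg.season_floor + (1 - cfg.season_floor) * np.exp(-0.5 * (dist / cfg.season_width) ** 2)
    return np.clip(level * shape, 0.0, 1.0)


def make_phenology(config: SimulationConfig) -> pd.DataFrame:
    """Biweekly flowering survey for two populations with shared seasonality.

    Each tree flowers independently each month with its population's monthly
    probability; a flowering tree is flagged in every census of that month.
    Returns a survey table (date, tree_id, population, flowering).
    """
    cfg = config.phenology
    rng = config.rngs()["phenology"]
    curves = {
        config.ecotype_a: (_monthly_curve(cfg, cfg.level_a), cfg.n_trees_a),
        config.ecotype_b: (_monthly_curve(cfg, cfg.level_b), cfg.n_trees_b),
    }
    start = pd.Period(cfg.start, freq="M")
    rows = []
    for pop, (curve, n_trees) in curves.items():
        flowering = rng.random((n_trees, cfg.n_months)) < curve[None, :]
        for t in range(n_trees):
            tree_id = f"{pop}_{t:03d}"
            for m in range(cfg.n_months):
                month = start + m
                for c in range(cfg.censuses_per_month):
                    day = 1 + c * (28 // max(cfg.censuses_per_month, 1))
                    date = pd.Timestamp(month.year, month.month, day)
                    rows.append((date, tree_id, pop, int(flowering[t, m])))
    return pd.DataFrame(rows, columns=["date", "tree_id", "population", "flowering"])


def expected_phenology_series(config: SimulationConfig):
    """Expected per-month flowering counts (A = ecotype_a focal) for the config.

    Gives the deterministic series a large-sample survey converges to; useful
    as a closed-form target for parameter-recovery checks.
    """
    from .ri_core import FloweringSeries

    cfg = config.phenology
    a = _monthly_curve(cfg, cfg.level_a) * cfg.n_trees_a
    b = _monthly_curve(cfg, cfg.level_b) * cfg.n_trees_b
    periods = tuple(str(pd.Period(cfg.start, freq="M") + m) for m in range(cfg.n_months))
    return FloweringSeries(periods, tuple(a), tuple(b), cfg.n_trees_a, cfg.n_trees_b)


# ---------------------------------------------------------------------------
# pollinators
# ---------------------------------------------------------------------------

def make_visitation(config: SimulationConfig) -> VisitationTable:
    """Multinomial visit counts for each ecotype's community profile.

    With ``concentration`` set, each ecotype's proportions are drawn from a
    Dirichlet centered on the configured profile (larger concentration =
    smaller jitter); otherwise the profiles are used as-is.
    """
    cfg = config.pollinators
    rng = config.rngs()["pollinators"]
    pa = np.asarray(cfg.proportions_a, dtype=float)
    pb = np.asarray(cfg.proportions_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("ecotype proportion vectors must have equal length")
    if cfg.concentration is not None:
        eps = 1e-9  # Dirichlet needs strictly positive parameters
        pa = rng.dirichlet(cfg.concentration * pa + eps)
        pb = rng.dirichlet(cfg.concentration * pb + eps)
    counts_a = rng.multinomial(cfg.total_visits_a, pa / pa.sum())
    counts_b = rng.multinomial(cfg.total_visits_b, pb / pb.sum())
    index = [f"morphospecies_{chr(ord('A') + i)}" for i in range(len(pa))]
    df = pd.DataFrame(
        {config.ecotype_a: counts_a, config.ecotype_b: counts_b}, index=pd.Index(index, name="morphospecies")
    )
    return VisitationTable(df)


def expected_visitation_dissimilarity(config: SimulationConfig) -> float:
    """Bray-Curtis dissimilarity of the expected (noise-free) count vectors."""
    cfg = config.pollinators
    ea = np.asarray(cfg.proportions_a, dtype=float) * cfg.total_visits_a
    eb = np.asarray(cfg.proportions_b, dtype=float) * cfg.total_visits_b
    return 1.0 - 2.0 * np.minimum(ea, eb).sum() / (ea.sum() + eb.sum())


# ---------------------------------------------------------------------------
# hand crosses
# ---------------------------------------------------------------------------

def _negative_binomial_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """NB(mean, shape k); variance = mean + mean^2/k.  Infinite k degenerates
    to the constant mean (dispersion -> 0 of the count noise)."""
    if not math.isfinite(dispersion):
        return np.full(size, round(mean), dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def make_crosses(config: SimulationConfig) -> list[CrossRecord]:
    """Seeded hand-cross records for both treatments plus negative controls.

    Per flower: adhered ~ NB(treatment mean, dispersion); germinated ~
    Binomial(adhered, treatment p); seed_set ~ Bernoulli(treatment rate).
    Maternal trees are all ecotype B (the study crossed in one direction
    only); negative controls never set seed.
    """
    cfg = config.crossing
    rng = config.rngs()["crossing"]
    maternal = config.ecotype_b
    records: list[CrossRecord] = []

    def _arm(n: int, pollen: str, mean: float, p_germ: float, seed_rate: float, tag: str) -> None:
        adhered = _negative_binomial_counts(rng, mean, cfg.adhesion_dispersion, n)
        germinated = rng.binomial(adhered, p_germ)
        seeds = rng.random(n) < seed_rate
        for i in range(n):
            records.append(
                CrossRecord(
                    flower_id=f"{tag}_{i:04d}",
                    maternal_ecotype=maternal,
                    pollen_ecotype=pollen,
                    adhered=int(adhered[i]),
                    germinated=int(germinated[i]),
                    seed_set=bool(seeds[i]),
                    control_type="none",
                )
            )

    _arm(cfg.n_parental, maternal, cfg.adhesion_mean_parental, cfg.germination_p_parental,
         cfg.seed_rate_parental, "parental")
    _arm(cfg.n_hybrid, config.ecotype_a, cfg.adhesion_mean_hybrid, cfg.germination_p_hybrid,
         cfg.seed_rate_hybrid, "hybrid")
    for i in range(cfg.n_negative_controls):
        records.append(
            CrossRecord(
                flower_id=f"negctrl_{i:04d}",
                maternal_ecotype=maternal,
                pollen_ecotype=None,
                seed_set=False,
                control_type="negative",
            )
        )
    return records


def expected_stage_ri(config: SimulationConfig) -> dict[str, float]:
    """Closed-form RI4A of the crossing generator's parameters per stage."""
    cfg = config.crossing

    def _ri(h: float, c: float) -> float:
        return 1.0 - 2.0 * h / (h + c)

    return {
        "adhesion": _ri(cfg.adhesion_mean_hybrid, cfg.adhesion_mean_parental),
        "germination": _ri(cfg.germination_p_hybrid, cfg.germination_p_parental),
        "seed_set": _ri(cfg.seed_rate_hybrid, cfg.seed_rate_parental),
    }
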