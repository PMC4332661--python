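"""Synthetic two-cohort thickness data with planted correlation structure.

Cohorts are drawn from a multivariate normal whose correlation matrix is a
uniform background plus per-pair planted targets.  Targets that are not
jointly positive definite are repaired by eigenvalue clipping; the repair
is rejected if it moves any correlation by more than a tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from cortsep.io_atlas import CASE, CONTROL, COHORTS, RegionAtlas, ThicknessTable, load_atlas

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedPair:
    """Target correlation for one region pair, per cohort."""

    i: int
    j: int
    r_case: float
    r_control: float

    def target(self, cohort: str) -> float:
        return self.r_case if cohort == CASE else self.r_control


@dataclass
class SyntheticSpec:
    """Generative parameters for the two synthetic cohorts."""

    n_regions: int = 70
    n_case: int = 64
    n_control: int = 39
    region_means: float | np.ndarray = 2.5
    region_sds: float | np.ndarray = 0.15
    base_correlation: float = 0.1
    planted_pairs: tuple[PlantedPair, ...] = ()
    seed: int = 0
    max_pd_perturbation: float = 0.05
    clip_floor: float = 0.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("cohort sizes must be >= 2")
        if not (0 <= self.base_correlation < 1):
            raise ValueError("base_correlation must lie in [0, 1)")
        for p in self.planted_pairs:
            if not (0 <= p.i < self.n_regions and 0 <= p.j < self.n_regions):
                raise ValueError(f"planted pair ({p.i}, {p.j}) out of range")
            if p.i == p.j:
                raise ValueError(f"planted self-pair ({p.i}, {p.j})")
            if abs(p.r_case) >= 1 or abs(p.r_control) >= 1:
                raise ValueError(f"planted |r| must be < 1: {p}")
        means = np.broadcast_to(np.asarray(self.region_means, float), (self.n_regions,))
        sds = np.broadcast_to(np.asarray(self.region_sds, float), (self.n_regions,))
        if np.any(sds <= 0) or np.any(means <= 0):
            raise ValueError("region means and sds must be positive")

    @property
    def cohort_sizes(self) -> dict[str, int]:
        return {CASE: self.n_case, CONTROL: self.n_control}

    def means_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.region_means, float), (self.n_regions,)
        ).copy()

    def sds_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.region_sds, float), (self.n_regions,)).copy()


def nearest_positive_definite(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped, diagonal-renormalized repair of a correlation matrix.

    Clips eigenvalues below ``eps``, reassembles, and rescales to unit
    diagonal.  Deterministic; idempotent on matrices that are already
    positive definite with unit diagonal.
    """
    sym = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= eps:
        return sym
    w = np.clip(w, eps, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2.0


@dataclass(frozen=True)
class CovarianceResult:
    """Cohort covariance with its implied correlation and PD-repair report."""

    covariance: np.ndarray
    correlation: np.ndarray
    max_perturbation: float
    repaired: bool


def target_correlation(spec: SyntheticSpec, cohort: str) -> np.ndarray:
    """Raw (possibly indefinite) target correlation matrix for one cohort."""
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    R = np.full((spec.n_regions, spec.n_regions), spec.base_correlation)
    np.fill_diagonal(R, 1.0)
    for p in spec.planted_pairs:
        R[p.i, p.j] = R[p.j, p.i] = p.target(cohort)
    return R


def build_covariance(spec: SyntheticSpec, cohort: str) -> CovarianceResult:
    """Positive-definite covariance realizing the cohort's correlation targets.

    If the raw target matrix is not positive definite it is projected with
    :func:`nearest_positive_definite`; the maximum absolute change of any
    correlation is reported and must not exceed ``spec.max_pd_perturbation``.
    """
    raw = target_correlation(spec, cohort)
    repaired_matrix = nearest_positive_definite(raw)
    perturbation = float(np.abs(repaired_matrix - raw).max())
    repaired = perturbation > 0
    if repaired:
        logger.info(
            "PD repair applied for cohort %s: max correlation perturbation %.4g",
            cohort,
            perturbation,
        )
    if perturbation > spec.max_pd_perturbation:
        raise ValueError(
            f"PD repair perturbs correlations by {perturbation:.4f} "
            f"(> tolerance {spec.max_pd_perturbation}); the planted targets are "
            "mutually inconsistent"
        )
    sds = spec.sds_vector()
    cov = repaired_matrix * np.outer(sds, sds)
    return CovarianceResult(cov, repaired_matrix, perturbation, repaired)


def simulate_cohort(
    spec: SyntheticSpec,
    cohort: str,
    seed: int | np.random.SeedSequence | None = None,
    atlas: RegionAtlas | None = None,
) -> ThicknessTable:
    """Draw one cohort of thickness vectors; deterministic given seed.

    Values are clipped at ``spec.clip_floor`` mm to keep them strictly
    positive; clipping is logged when triggered.
    """
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort {cohort!r}")
    if atlas is None and spec.n_regions == 70:
        atlas = load_atlas("dk70")
    elif atlas is None:
        names = tuple(f"lh_r{i:03d}" for i in range(spec.n_regions))
        atlas = RegionAtlas(names, ("lh",) * spec.n_regions)
    cov = build_covariance(spec, cohort).covariance
    n = spec.cohort_sizes[cohort]
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    chol = np.linalg.cholesky(cov)
    draws = spec.means_vector() + rng.standard_normal((n, spec.n_regions)) @ chol.T
    n_clipped = int(np.sum(draws < spec.clip_floor))
    if n_clipped:
        logger.warning(
            "clipped %d of %d draws (%.3f%%) at floor %.2f mm",
            n_clipped,
            draws.size,
            100.0 * n_clipped / draws.size,
            spec.clip_floor,
        )
    draws = np.maximum(draws, spec.clip_floor)
    ids = tuple(f"{cohort}{i:05d}" for i in range(n))
    return ThicknessTable(ids, (cohort,) * n, draws, atlas)


def simulate_cohorts(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[ThicknessTable, ThicknessTable]:
    """Draw both cohorts with independent, seed-derived streams."""
    master = np.random.SeedSequence(spec.seed if seed is None else seed)
    s_case, s_control = master.spawn(2)
    case = simulate_cohort(spec, CASE, seed=s_case)
    control = simulate_cohort(spec, CONTROL, seed=s_control)
    return case, control


def hub_scenario(
    r_case: float = 0.8,
    r_control: float = 0.0,
    n_hub_pairs: int = 15,
    hub_loading: float = 0.95,
    hub_region: int | None = None,
    base_correlation: float = 0.1,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[SyntheticSpec, tuple[PlantedPair, ...]]:
    """Default planted scenario: one hub region correlated with many others.

    The hub (right temporal pole by default) is correlated at ``r_case``
    with ``n_hub_pairs`` neighbour regions in the case cohort and at
    ``r_control`` in controls.  To keep the case target positive definite
    the neighbours form a latent-factor clique: each neighbour loads
    ``r_case / hub_loading`` on a shared factor, so neighbour-neighbour
    correlations equal ``(r_case / hub_loading)**2`` — planted identically
    in BOTH cohorts so that only the hub pairs differ between groups.

    Returns the spec together with the hub pairs themselves (the pairs a
    feature-selection step is expected to recover).
    """
    if not 0 < abs(r_case) < hub_loading <= 1:
        raise ValueError("need 0 < |r_case| < hub_loading <= 1")
    spec_probe = SyntheticSpec(seed=seed, base_correlation=base_correlation, **spec_kwargs)
    p = spec_probe.n_regions
    if hub_region is None:
        atlas = load_atlas("dk70") if p == 70 else None
        hub_region = atlas.index("rh_temporalpole") if atlas is not None else p - 1
    neighbours = [r for r in range(p) if r != hub_region][:n_hub_pairs]
    if len(neighbours) < n_hub_pairs:
        raise ValueError("not enough regions for the requested number of hub pairs")

    nn = (r_case / hub_loading) ** 2
    hub_pairs = tuple(
        PlantedPair(min(hub_region, r), max(hub_region, r), r_case, r_control)
        for r in neighbours
    )
    support = tuple(
        PlantedPair(min(a, b), max(a, b), nn, nn)
        for k, a in enumerate(neighbours)
        for b in neighbours[k + 1 :]
    )
    spec = replace(spec_probe, planted_pairs=hub_pairs + support)
    return spec, hub_pairs
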