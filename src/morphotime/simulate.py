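"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* :func:`simulate_mature` — a mature feature table with two discrete classes
  (a compact basket-like class and a larger stellate-like class) whose
  separation lives in a configurable informative feature group, plus a
  continuous within-class gradient along the stellate axon-span axis.
* :func:`simulate_development` — developmental snapshot tables: two
  birthdate cohorts progress along a latent maturation variable ``s`` drawn
  from per-age windows; their mean feature trajectories coincide before a
  divergence point ``s_div`` and separate after it; the stellate axon span
  rises to an interior peak and then retracts; a configurable rare
  short-axon lineage hides inside the early-born cohort.
* :func:`simulate_swc` — programmatically built SWC trees whose features
  (cable lengths, Sholl crossings, branch levels, collateral classes,
  spans, filopodia, structural counts) are computed analytically during
  construction and emitted as ground truth for the extractors.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io import (
    AnnotationRecord,
    FeatureTable,
    LayerGeometry,
    NeuronReconstruction,
    SWC_AXON,
    SWC_DENDRITE,
    SWC_SOMA,
)
from .morphometrics import (
    DEFAULT_SHOLL_RADII,
    FeatureDef,
    FeatureSchema,
    load_schema,
)

__all__ = [
    "MaturePopulationConfig",
    "DevelopmentConfig",
    "SwcFixtureConfig",
    "simulate_mature",
    "simulate_development",
    "simulate_swc",
    "fixture_schema",
]


# ---------------------------------------------------------------------------
# Mature population

# plausible (location, scale) pairs mapping standardized effects onto
# micrometre/count scales; clustering standardizes them away again
_MATURE_SCALES = {
    "dendrite_length": (900.0, 250.0),
    "axon_length": (2500.0, 900.0),
    "axon_sholl_10": (3.0, 1.5),
    "axon_sholl_50": (8.0, 3.0),
    "axon_sholl_100": (6.0, 3.0),
    "axon_sholl_150": (3.0, 2.0),
    "axon_sholl_200": (1.5, 1.2),
    "axon_mean_branch_level": (4.0, 1.5),
    "axon_max_branch_level": (10.0, 4.0),
    "axon_straightness": (0.85, 0.05),
    "soma_volume": (700.0, 200.0),
    "filopodia_count": (8.0, 4.0),
    "filopodia_density": (0.01, 0.004),
    "dendrite_ml_height": (80.0, 25.0),
    "axon_ml_height": (70.0, 25.0),
    "axon_span": (180.0, 80.0),
    "axon_z_depth": (20.0, 8.0),
    "collateral_up_count": (4.0, 2.5),
    "collateral_up_length": (150.0, 80.0),
    "collateral_up_percent": (50.0, 15.0),
    "collateral_down_count": (4.0, 2.5),
    "collateral_down_length": (150.0, 80.0),
    "collateral_down_percent": (50.0, 15.0),
    "weighted_basket_score": (2.0, 1.5),
    "axon_carrying_dendrite": (0.3, 0.4),
    "primary_dendrites": (3.0, 1.0),
    "relative_ml_position": (0.5, 0.2),
}

_MATURE_INFORMATIVE = (
    "axon_length", "axon_span", "axon_ml_height", "axon_straightness",
    "weighted_basket_score", "axon_max_branch_level",
)


@dataclass
class MaturePopulationConfig:
    """Two-class mature population with a stellate-internal gradient.

    ``separation`` is the class mean gap, in within-class SD units, applied
    on the informative feature group only; the stellate gradient adds a
    continuous axis (amplitude in SD units) on the span-related features.
    """

    n_bc: int = 19
    n_sc: int = 60
    separation: float = 4.0
    informative_group: tuple[str, ...] = _MATURE_INFORMATIVE
    sc_gradient_features: tuple[str, ...] = (
        "axon_span", "axon_length", "axon_ml_height")
    sc_gradient_amplitude: float = 1.5
    noise_sd: float = 1.0
    feature_names: tuple[str, ...] = tuple(_MATURE_SCALES)

    def __post_init__(self) -> None:
        if self.n_bc < 2 or self.n_sc < 2:
            raise ValueError("class counts must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive (degenerate covariance)")
        if self.sc_gradient_amplitude < 0 or self.separation < 0:
            raise ValueError("amplitudes must be >= 0")
        unknown = [f for f in self.informative_group
                   if f not in self.feature_names]
        unknown += [f for f in self.sc_gradient_features
                    if f not in self.feature_names]
        if unknown:
            raise ValueError(f"unknown features in config: {unknown}")


def simulate_mature(config: MaturePopulationConfig | None = None,
                    seed: int | None = 0,
                    ) -> tuple[FeatureTable, pd.DataFrame]:
    """Draw a mature two-class feature table plus ground truth.

    Returns (table, truth) where truth has ``true_label`` ('BC'/'SC') and
    the stellate ``gradient`` value (NaN for basket cells).
    """
    cfg = config or MaturePopulationConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_bc + cfg.n_sc
    names = list(cfg.feature_names)
    is_bc = np.array([True] * cfg.n_bc + [False] * cfg.n_sc)
    Z = rng.normal(0.0, cfg.noise_sd, size=(n, len(names)))
    half = cfg.separation / 2.0
    for j, name in enumerate(names):
        if name in cfg.informative_group:
            Z[:, j] += np.where(is_bc, half, -half)
    gradient = np.full(n, np.nan)
    gradient[~is_bc] = rng.uniform(0.0, 1.0, size=cfg.n_sc)
    for j, name in enumerate(names):
        if name in cfg.sc_gradient_features:
            Z[~is_bc, j] += cfg.sc_gradient_amplitude * (gradient[~is_bc] - 0.5)
    data = np.empty_like(Z)
    for j, name in enumerate(names):
        loc, scale = _MATURE_SCALES.get(name, (0.0, 1.0))
        data[:, j] = loc + scale * Z[:, j]
    ids = pd.Index([f"cell{i:03d}" for i in range(n)], name="cell_id")
    features = pd.DataFrame(data, index=ids, columns=names)
    metadata = pd.DataFrame({
        "curated_class": np.where(is_bc, "canonical_BC", "canonical_SC"),
    }, index=ids)
    truth = pd.DataFrame({
        "true_label": np.where(is_bc, "BC", "SC"),
        "gradient": gradient,
    }, index=ids)
    return FeatureTable(features, metadata), truth


# ---------------------------------------------------------------------------
# Developmental trajectories

# per-feature trajectory coefficients in standardized units:
# (base growth amplitude, BC offset, SC offset, rare-lineage offset);
# offsets are multiplied by the post-divergence ramp v(s)
_DEV_TRAJ = {
    "axon_length": (2.0, 0.5, 0.2, -0.8),
    "axon_sholl_10": (1.2, 0.2, 0.1, -0.3),
    "axon_sholl_50": (1.5, 0.3, 0.1, -0.5),
    "axon_sholl_100": (1.2, 0.8, 0.1, -0.6),
    "axon_sholl_150": (0.8, 0.6, 0.0, -0.4),
    "axon_sholl_200": (0.5, 0.5, -0.1, -0.3),
    "axon_mean_branch_level": (1.5, 0.2, 0.3, -0.3),
    "axon_max_branch_level": (1.5, 0.2, 0.3, -0.3),
    "axon_straightness": (-1.0, -0.2, 0.0, 0.3),
    "axon_ml_height": (1.2, 0.3, 0.4, -0.4),
    "axon_span": (2.0, 1.0, 0.0, -0.6),  # SC gets the hump term instead
    "axon_z_depth": (0.8, 0.1, 0.1, -0.2),
    "collateral_up_count": (1.0, 0.1, 0.5, -0.2),
    "collateral_up_length": (1.0, 0.1, 0.5, -0.2),
    "collateral_up_percent": (0.3, -0.5, 0.5, 0.0),
    "collateral_down_count": (1.0, 0.8, 0.0, -0.3),
    "collateral_down_length": (1.0, 0.8, 0.0, -0.3),
    "collateral_down_percent": (0.3, 0.5, -0.5, 0.0),
    "pcl_reaching_branches": (0.8, 0.9, -0.1, -0.3),
    "soma_x_diameter": (0.8, 0.15, 0.05, -0.1),
    "soma_y_diameter": (0.8, 0.15, 0.05, -0.1),
    "soma_z_diameter": (0.8, 0.1, 0.05, -0.1),
    "soma_volume": (1.5, 0.4, 0.1, -0.3),
    "soma_height": (-1.0, -0.5, 0.3, -0.4),
    "relative_ml_position": (-1.0, -0.5, 0.3, -0.4),
    "primary_dendrites": (1.0, 0.05, 0.05, 0.0),
    "axon_terminal_count": (1.5, 0.2, 0.2, -0.4),
    "axon_branch_point_count": (1.5, 0.2, 0.2, -0.4),
}

_DEV_SCALES = {
    "axon_length": (30.0, 150.0),
    "axon_sholl_10": (1.0, 2.0),
    "axon_sholl_50": (1.0, 2.0),
    "axon_sholl_100": (0.5, 1.5),
    "axon_sholl_150": (0.3, 1.2),
    "axon_sholl_200": (0.1, 0.8),
    "axon_mean_branch_level": (1.0, 2.0),
    "axon_max_branch_level": (2.0, 4.0),
    "axon_straightness": (0.85, 0.05),
    "axon_ml_height": (20.0, 30.0),
    "axon_span": (30.0, 60.0),
    "axon_z_depth": (8.0, 6.0),
    "collateral_up_count": (1.0, 2.0),
    "collateral_up_length": (20.0, 40.0),
    "collateral_up_percent": (50.0, 15.0),
    "collateral_down_count": (1.0, 2.0),
    "collateral_down_length": (20.0, 40.0),
    "collateral_down_percent": (50.0, 15.0),
    "pcl_reaching_branches": (0.5, 1.5),
    "soma_x_diameter": (7.0, 1.5),
    "soma_y_diameter": (7.0, 1.5),
    "soma_z_diameter": (7.0, 1.5),
    "soma_volume": (600.0, 500.0),
    "soma_height": (60.0, 25.0),
    "relative_ml_position": (0.5, 0.2),
    "primary_dendrites": (2.0, 1.0),
    "axon_terminal_count": (4.0, 6.0),
    "axon_branch_point_count": (3.0, 5.0),
}


@dataclass
class DevelopmentConfig:
    """Two-fate developmental snapshot generator.

    ``s_div`` is the latent maturation point where the cohort mean
    trajectories separate (1.0 = never, the no-divergence null);
    ``noise_sd`` is the per-feature Gaussian noise in standardized units;
    ``rare_sc_fraction`` of the early-born cohort follows a short-axon
    stellate trajectory while keeping the early-born fate label.  Snapshot
    ages (days post induction) map to truncated-Gaussian windows of ``s``,
    emulating within-age developmental variability.
    """

    n_bc_cohort: int = 423
    n_sc_cohort: int = 309
    s_div: float = 0.1
    noise_sd: float = 0.2
    rare_sc_fraction: float = 0.1
    n_states: int = 8
    ages: tuple[float, ...] = (5.0, 7.0, 10.0, 13.0, 16.0, 25.0)
    age_window_sd: float = 0.15
    stage_jitter_sd: float = 0.03
    feature_names: tuple[str, ...] = tuple(_DEV_TRAJ)

    def __post_init__(self) -> None:
        if not (0 < self.s_div <= 1.0):
            raise ValueError("s_div must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.rare_sc_fraction < 0.5):
            raise ValueError("rare_sc_fraction must be in [0, 0.5)")
        if self.n_bc_cohort < 2 or self.n_sc_cohort < 2:
            raise ValueError("cohort sizes must be >= 2")


def _dev_ramp(s: np.ndarray, s_div: float, tau: float = 0.12) -> np.ndarray:
    """Post-divergence separation ramp: saturating in (s - s_div)/tau.

    Divergent phenotypes are expressed soon after the fate split rather than
    accruing linearly over the whole timeline, so cohorts already separate
    within the first pseudotime bin when the split is early.
    """
    if s_div >= 1.0:
        return np.zeros_like(s)
    return np.clip(1.0 - np.exp(-np.maximum(s - s_div, 0.0) / tau), 0.0, 1.0)


def _dev_mu_matrix(names: list[str], s: np.ndarray, lineage: np.ndarray,
                   s_div: float) -> np.ndarray:
    """Mean feature trajectories, (n_cells, n_features).

    All lineages share one growth axis (the base amplitudes); lineage
    offsets are projected orthogonal to that axis so fate separation reads
    as a distinct phenotype direction rather than as advanced or retarded
    maturity — in the real data both the maturation ordering and the fate
    separation are recoverable simultaneously, which requires exactly this
    geometry.  The stellate axon span additionally carries a non-monotone
    expansion-then-retraction term.
    """
    base = np.array([_DEV_TRAJ[n][0] for n in names])
    ghat = base / np.linalg.norm(base)
    offsets = {}
    for li, col in (("BC", 1), ("SC", 2), ("rare_SC", 3)):
        o = np.array([_DEV_TRAJ[n][col] for n in names])
        offsets[li] = o - (o @ ghat) * ghat
    v = _dev_ramp(s, s_div)
    mu = np.outer(s, base)
    for li in ("BC", "SC", "rare_SC"):
        mask = lineage == li
        if mask.any():
            mu[mask] += np.outer(v[mask], offsets[li])
    if "axon_span" in names:
        # stellate expansion then retraction: a half-sine in maturation time,
        # peaking in the interior and returning to the shared trajectory
        j = names.index("axon_span")
        sc_mask = lineage == "SC"
        if s_div < 1.0 and sc_mask.any():
            u = np.clip((s[sc_mask] - s_div) / (1.0 - s_div), 0.0, 1.0)
            mu[sc_mask, j] += 1.4 * np.sin(np.pi * u)
    return mu


def simulate_development(config: DevelopmentConfig | None = None,
                         seed: int | None = 0,
                         ) -> tuple[FeatureTable, pd.DataFrame]:
    """Draw developmental snapshots plus ground truth (s, lineage, state).

    Returns (table, truth); the table's metadata carries fate_label,
    expert_stage and dpi, the truth frame the latent maturation ``s``, the
    true lineage (BC / SC / rare_SC) and the discretized trajectory state.
    """
    cfg = config or DevelopmentConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_bc_cohort + cfg.n_sc_cohort
    if cfg.n_states > max(n // 10, 2):
        warnings.warn(
            f"n_states={cfg.n_states} may exceed what {n} cells can resolve")
    fate = np.array(["BC_fated"] * cfg.n_bc_cohort
                    + ["SC_fated"] * cfg.n_sc_cohort)
    lineage = np.where(fate == "BC_fated", "BC", "SC").astype(object)
    n_rare = int(round(cfg.rare_sc_fraction * cfg.n_bc_cohort))
    if n_rare:
        rare_idx = rng.choice(cfg.n_bc_cohort, size=n_rare, replace=False)
        lineage[rare_idx] = "rare_SC"
    ages = np.asarray(cfg.ages, dtype=float)
    age = rng.choice(ages, size=n)
    progress = (age - ages.min()) / (ages.max() - ages.min())
    a = (0.0 - progress) / cfg.age_window_sd
    b = (1.0 - progress) / cfg.age_window_sd
    s = truncnorm.rvs(a, b, loc=progress, scale=cfg.age_window_sd,
                      random_state=rng)
    names = list(cfg.feature_names)
    Z = _dev_mu_matrix(names, s, lineage, cfg.s_div) \
        + rng.normal(0.0, cfg.noise_sd, size=(n, len(names)))
    data = np.empty_like(Z)
    for j, name in enumerate(names):
        loc, scale = _DEV_SCALES.get(name, (0.0, 1.0))
        data[:, j] = loc + scale * Z[:, j]
    stage = 1 + np.digitize(
        np.clip(s + rng.normal(0.0, cfg.stage_jitter_sd, size=n), 0, 1),
        [0.25, 0.5, 0.75])
    state = 1 + np.minimum((s * cfg.n_states).astype(int), cfg.n_states - 1)
    ids = pd.Index([f"dev{i:04d}" for i in range(n)], name="cell_id")
    features = pd.DataFrame(data, index=ids, columns=names)
    metadata = pd.DataFrame({
        "fate_label": fate,
        "expert_stage": stage,
        "dpi": age,
    }, index=ids)
    truth = pd.DataFrame({
        "s": s,
        "lineage": lineage,
        "state": state,
        "fate": fate,
    }, index=ids)
    return FeatureTable(features, metadata), truth


# ---------------------------------------------------------------------------
# SWC fixtures with analytic ground truth


@dataclass
class SwcFixtureConfig:
    """Randomized tree-fixture generator parameters (micrometres/degrees)."""

    ml_height: float = 120.0
    soma_height_range: tuple[float, float] = (20.0, 100.0)
    soma_radius: float = 4.0
    soma_diameter_range: tuple[float, float] = (6.0, 12.0)
    n_dendrites_range: tuple[int, int] = (2, 5)
    dendrite_length_range: tuple[float, float] = (20.0, 60.0)
    nodes_per_run: int = 4
    filopodia_count_range: tuple[int, int] = (0, 4)
    filopodia_length_range: tuple[float, float] = (0.5, 1.3)
    continuation_length_range: tuple[float, float] = (4.0, 8.0)
    main_axon_length_range: tuple[float, float] = (150.0, 350.0)
    n_collaterals_range: tuple[int, int] = (2, 6)
    included_angle_range: tuple[float, float] = (35.0, 85.0)
    excluded_angle_range: tuple[float, float] = (5.0, 25.0)
    p_excluded: float = 0.3
    collateral_length_range: tuple[float, float] = (20.0, 80.0)
    z_tilt_max_deg: float = 30.0
    p_down: float = 0.5
    p_axon_carrying_dendrite: float = 0.3
    acd_stub_length: float = 6.0
    filopodia_threshold: float = 1.5
    sholl_radii: tuple[float, ...] = DEFAULT_SHOLL_RADII

    def __post_init__(self) -> None:
        for name in ("dendrite_length_range", "main_axon_length_range",
                     "collateral_length_range", "filopodia_length_range",
                     "continuation_length_range", "soma_diameter_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered")
        for name in ("included_angle_range", "excluded_angle_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 180):
                raise ValueError(f"{name} must lie in [0, 180] degrees")
        if self.filopodia_length_range[1] >= self.filopodia_threshold:
            raise ValueError("filopodia must be shorter than the threshold")
        if self.continuation_length_range[0] <= self.filopodia_threshold:
            raise ValueError("continuations must exceed the filopodia threshold")
        lo_a, _ = self.main_axon_length_range
        if lo_a < 3 * self.collateral_length_range[0]:
            raise ValueError("main axon too short for the collateral lengths")


class _TreeBuilder:
    def __init__(self, cell_id: str):
        self.cell_id = cell_id
        self.ids: list[int] = []
        self.parents: list[int] = []
        self.structs: list[int] = []
        self.xyz: list[np.ndarray] = []
        self.radius: list[float] = []

    def add(self, parent_id: int, struct: int, point: np.ndarray,
            radius: float = 0.5) -> int:
        nid = len(self.ids) + 1
        self.ids.append(nid)
        self.parents.append(parent_id)
        self.structs.append(struct)
        self.xyz.append(np.asarray(point, dtype=float))
        self.radius.append(radius)
        return nid

    def build(self, annotations: AnnotationRecord | None = None,
              ) -> NeuronReconstruction:
        return NeuronReconstruction(
            cell_id=self.cell_id,
            ids=np.array(self.ids),
            parents=np.array(self.parents),
            structure=np.array(self.structs),
            xyz=np.array(self.xyz),
            radius=np.array(self.radius),
            annotations=annotations,
        )


def _polyline(builder: _TreeBuilder, parent_id: int, struct: int,
              start: np.ndarray, direction: np.ndarray, length: float,
              n_nodes: int) -> tuple[int, np.ndarray]:
    """Straight run of ``n_nodes`` nodes; returns (tip id, tip point)."""
    pid = parent_id
    for i in range(1, n_nodes + 1):
        pt = start + direction * (length * i / n_nodes)
        pid = builder.add(pid, struct, pt)
    return pid, start + direction * length


def _avoid_radii(value: float, radii: Sequence[float], margin: float = 0.05,
                 step: float = 0.17) -> float:
    """Nudge a length so no Sholl boundary sits within ``margin`` of it."""
    while any(abs(value - r) < margin for r in radii):
        value += step
    return value


def simulate_swc(config: SwcFixtureConfig | None = None, seed: int | None = 0,
                 cell_id: str | None = None,
                 ) -> tuple[NeuronReconstruction, LayerGeometry, dict[str, float]]:
    """Build a randomized reconstruction with analytic feature ground truth.

    The soma sits in a molecular layer of configured height; primary
    dendrites radiate upward (some bearing one sub-threshold terminal
    filopodium each); the main axon runs tangentially with straight
    collaterals at known angles, some below the inclusion threshold, some
    descending into the Purkinje-cell layer.  Geometry is constrained so
    distances from the soma grow monotonically along every run, which makes
    Sholl crossings, collateral classes and branch levels exact bookkeeping.

    Returns (reconstruction, layer geometry, ground-truth feature dict).
    """
    cfg = config or SwcFixtureConfig()
    rng = np.random.default_rng(seed)
    radii = cfg.sholl_radii
    name = cell_id or f"fixture{seed}"
    geom = LayerGeometry(pcl_top=0.0, ml_top=cfg.ml_height)
    soma_h = rng.uniform(*cfg.soma_height_range)
    soma = np.array([0.0, soma_h, 0.0])
    b = _TreeBuilder(name)
    soma_id = b.add(-1, SWC_SOMA, soma, radius=cfg.soma_radius)

    dendrite_length_total = 0.0
    n_filo = 0

    # optional axon-carrying dendrite: a straight tangential stub the axon
    # hangs from, so axonal arc length stays the distance from the soma
    acd = bool(rng.random() < cfg.p_axon_carrying_dendrite)
    axon_parent = soma_id
    axon_origin_offset = 0.0
    n_dend = int(rng.integers(cfg.n_dendrites_range[0],
                              cfg.n_dendrites_range[1] + 1))
    primary_dendrites = n_dend + (1 if acd else 0)
    if acd:
        delta = cfg.acd_stub_length
        tip_id, tip = _polyline(b, soma_id, SWC_DENDRITE, soma,
                                np.array([1.0, 0.0, 0.0]), delta, 2)
        dendrite_length_total += delta
        axon_parent = tip_id
        axon_origin_offset = delta

    # --- dendrites -----------------------------------------------------
    want_filo = int(rng.integers(cfg.filopodia_count_range[0],
                                 cfg.filopodia_count_range[1] + 1))
    want_filo = min(want_filo, n_dend)
    for d in range(n_dend):
        polar = rng.uniform(0.0, np.deg2rad(60.0))
        azim = rng.uniform(0.0, 2 * np.pi)
        direction = np.array([
            np.sin(polar) * np.cos(azim),
            np.cos(polar),
            np.sin(polar) * np.sin(azim),
        ])
        length = rng.uniform(*cfg.dendrite_length_range)
        tip_id, tip = _polyline(b, soma_id, SWC_DENDRITE, soma, direction,
                                length, cfg.nodes_per_run)
        dendrite_length_total += length
        if d < want_filo:
            # branch point at the tip: one filopodium + one continuation
            perp = np.cross(direction, np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(perp) < 1e-9:
                perp = np.cross(direction, np.array([1.0, 0.0, 0.0]))
            perp /= np.linalg.norm(perp)
            flen = rng.uniform(*cfg.filopodia_length_range)
            b.add(tip_id, SWC_DENDRITE, tip + perp * flen)
            clen = rng.uniform(*cfg.continuation_length_range)
            _polyline(b, tip_id, SWC_DENDRITE, tip, direction, clen, 2)
            dendrite_length_total += flen + clen
            n_filo += 1

    # --- axon ----------------------------------------------------------
    xhat = np.array([1.0, 0.0, 0.0])
    L = _avoid_radii(rng.uniform(*cfg.main_axon_length_range) - axon_origin_offset,
                     [r - axon_origin_offset for r in radii])
    n_coll = int(rng.integers(cfg.n_collaterals_range[0],
                              cfg.n_collaterals_range[1] + 1))
    while True:  # distinct, well-separated attach points off the Sholl radii
        attach_arcs = np.sort(rng.uniform(15.0, L - 40.0, size=n_coll))
        attach_arcs = np.sort([
            _avoid_radii(a, [r - axon_origin_offset for r in radii])
            for a in attach_arcs])
        if n_coll < 2 or np.min(np.diff(attach_arcs)) >= 2.0:
            break

    axon_start = soma + xhat * axon_origin_offset
    # shaft nodes: attach points plus regular fill plus the tip
    fill = [t for t in (L / 3, 2 * L / 3)
            if all(abs(t - a) > 1.0 for a in attach_arcs)]
    shaft_arcs = np.sort(np.concatenate([attach_arcs, fill, [L]]))
    node_at_arc: dict[float, int] = {}
    pid = axon_parent
    for t in shaft_arcs:
        pid = b.add(pid, SWC_AXON, axon_start + xhat * t)
        node_at_arc[t] = pid

    axon_length_total = L
    runs: list[tuple[float, float]] = [
        (axon_origin_offset, axon_origin_offset + L)]  # soma-distance spans
    up_count = down_count = 0
    up_len = down_len = 0.0
    tip_ys = [float(soma_h)]  # shaft tip height
    coll_levels: list[int] = []
    for i, a in enumerate(attach_arcs):
        excluded = rng.random() < cfg.p_excluded
        theta = np.deg2rad(rng.uniform(*(
            cfg.excluded_angle_range if excluded else cfg.included_angle_range)))
        sign = -1.0 if rng.random() < cfg.p_down else 1.0
        psi = np.deg2rad(rng.uniform(-cfg.z_tilt_max_deg, cfg.z_tilt_max_deg))
        direction = np.array([
            np.cos(theta),
            sign * np.sin(theta) * np.cos(psi),
            np.sin(theta) * np.sin(psi),
        ])
        max_len = L - a - 10.0
        clen = min(rng.uniform(*cfg.collateral_length_range), max_len)
        attach_dist = axon_origin_offset + a
        # nudge the run's outer Sholl boundary off the sampling radii
        while True:
            end = np.sqrt(attach_dist ** 2 + clen ** 2
                          + 2 * attach_dist * clen * np.cos(theta))
            if all(abs(end - r) > 0.05 for r in radii) or clen >= max_len:
                break
            clen = min(clen + 0.17, max_len)
        start_pt = axon_start + xhat * a
        _, tip = _polyline(b, node_at_arc[a], SWC_AXON, start_pt, direction,
                           clen, 3)
        axon_length_total += clen
        runs.append((attach_dist, float(end)))
        tip_ys.append(float(tip[1]))
        coll_levels.append(i + 1)
        if not excluded:
            if sign > 0:
                up_count += 1
                up_len += clen
            else:
                down_count += 1
                down_len += clen

    # --- bookkeeping ground truth --------------------------------------
    m = n_coll
    shaft_levels = list(range(0, m + 1))
    levels = shaft_levels + coll_levels
    sholl = [sum(1 for lo, hi in runs if lo < r <= hi) for r in radii]
    all_pts = np.array(b.xyz)
    all_st = np.array(b.structs)
    axon_pts = all_pts[all_st == SWC_AXON]
    dend_pts = all_pts[all_st == SWC_DENDRITE]
    coll_total = up_len + down_len
    dx, dy, dz = rng.uniform(*cfg.soma_diameter_range, size=3)
    truth: dict[str, float] = {
        "axon_length": axon_length_total,
        "dendrite_length": dendrite_length_total,
        "axon_mean_branch_level": float(np.mean(levels)),
        "axon_max_branch_level": float(max(levels)),
        "axon_straightness": 1.0,
        "axon_ml_height": float(axon_pts[:, 1].max() - axon_pts[:, 1].min()),
        "axon_span": float(axon_pts[:, 0].max() - axon_pts[:, 0].min()),
        "axon_z_depth": float(axon_pts[:, 2].max() - axon_pts[:, 2].min()),
        "dendrite_ml_height": float(dend_pts[:, 1].max() - dend_pts[:, 1].min()),
        "filopodia_count": float(n_filo),
        "filopodia_density": n_filo / dendrite_length_total,
        "collateral_up_count": float(up_count),
        "collateral_up_length": up_len,
        "collateral_up_percent": 100.0 * up_len / coll_total if coll_total else 0.0,
        "collateral_down_count": float(down_count),
        "collateral_down_length": down_len,
        "collateral_down_percent": 100.0 * down_len / coll_total if coll_total else 0.0,
        "primary_dendrites": float(primary_dendrites),
        "pcl_reaching_branches": float(sum(1 for y in tip_ys if y < 0.0)),
        "axon_carrying_dendrite": float(acd),
        "soma_height": soma_h,
        "relative_ml_position": soma_h / cfg.ml_height,
        "axon_terminal_count": float(m + 1),
        "axon_branch_point_count": float(m),
        "soma_x_diameter": float(dx),
        "soma_y_diameter": float(dy),
        "soma_z_diameter": float(dz),
        "soma_volume": 4.0 / 3.0 * np.pi * dx * dy * dz,
    }
    for r, c in zip(radii, sholl):
        truth[f"axon_sholl_{int(r)}"] = float(c)
    ann = AnnotationRecord(soma_diameters=(float(dx), float(dy), float(dz)))
    return b.build(annotations=ann), geom, truth


def fixture_schema() -> FeatureSchema:
    """Schema covering every feature :func:`simulate_swc` emits ground truth for."""
    dev = load_schema("developmental_28")
    extra = [
        FeatureDef("dendrite_length", "dendrite", "um"),
        FeatureDef("dendrite_ml_height", "dendrite", "um"),
        FeatureDef("filopodia_count", "dendrite", "count"),
        FeatureDef("filopodia_density", "dendrite", "per_um"),
        FeatureDef("axon_carrying_dendrite", "axon", "flag"),
    ]
    return FeatureSchema(name="swc_fixture",
                         features=dev.features + extra)
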