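"""Morphometric feature extraction from neuron reconstructions.

Implements the mature (27-feature) and developmental (28-feature) morphometric
repertoires for cerebellar molecular-layer interneurons: compartment lengths,
Sholl intersections, branch levels, straightness, filopodia, laminar spans and
positions, oriented axon collaterals, the weighted basket score, ellipsoid
soma volumes and structural counts.  Feature sets are described by editable
YAML schemas (``mature_27``, ``developmental_28``, ``clustering_19`` presets).

Conventions that the source data do not pin down are explicit parameters:
the main axon is the geodesically longest root-to-tip axonal path; branch
initial directions are secants over the first 5 um of arc; straightness is a
length-weighted mean of per-segment chord/path ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    SWC_AXON,
    SWC_DENDRITE,
    SWC_SOMA,
    STRUCTURE_CODES,
    AnnotationRecord,
    BasketCounts,
    LayerGeometry,
    MissingSomaError,
    NeuronReconstruction,
    soma_height,
)

__all__ = [
    "DEFAULT_SHOLL_RADII",
    "DEFAULT_FILOPODIA_THRESHOLD",
    "DEFAULT_COLLATERAL_ANGLE",
    "total_length",
    "sholl_counts",
    "branch_levels",
    "straightness",
    "filopodia",
    "spans",
    "classify_collaterals",
    "CollateralClass",
    "CollateralStats",
    "weighted_basket_score",
    "soma_volume_ellipsoid",
    "relative_ml_position",
    "structural_counts",
    "StructuralCounts",
    "FeatureSchema",
    "FeatureDef",
    "load_schema",
    "FeatureVector",
    "extract_features",
    "extract_feature_table",
]

DEFAULT_SHOLL_RADII = (10.0, 50.0, 100.0, 150.0, 200.0)
DEFAULT_FILOPODIA_THRESHOLD = 1.5  # um, terminal dendritic branches below this
DEFAULT_COLLATERAL_ANGLE = 30.0  # degrees off the main axon
DEFAULT_SECANT_LENGTH = 5.0  # um of initial arc used for branch directions


def _comp_code(compartment: str) -> int:
    try:
        return STRUCTURE_CODES[compartment]
    except KeyError:
        raise ValueError(
            f"unknown compartment {compartment!r}; expected one of "
            f"{sorted(STRUCTURE_CODES)}"
        )


# ---------------------------------------------------------------------------
# Segment decomposition

@dataclass
class _Segment:
    """A maximal unbranched chain within one compartment.

    ``nodes`` are positional indices from the anchor (the parent node the
    chain hangs from, possibly outside the compartment) down to a tip or
    branch point.  ``level`` counts branch points above the segment within
    the compartment.
    """

    nodes: list[int]
    level: int
    terminal: bool

    def length(self, xyz: np.ndarray) -> float:
        pts = xyz[self.nodes]
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def chord(self, xyz: np.ndarray) -> float:
        return float(np.linalg.norm(xyz[self.nodes[-1]] - xyz[self.nodes[0]]))


def _compartment_children(recon: NeuronReconstruction, code: int) -> list[list[int]]:
    out: list[list[int]] = [[] for _ in range(recon.n_nodes)]
    for pos in range(recon.n_nodes):
        for ch in recon.children_of(pos):
            if recon.structure[ch] == code:
                out[pos].append(ch)
    return out


def _compartment_roots(recon: NeuronReconstruction, code: int) -> list[int]:
    """Compartment nodes whose parent is the global root's absence or lies
    outside the compartment (e.g. each primary dendrite, the axon origin)."""
    ppos = recon.parent_positions()
    roots = []
    for pos in range(recon.n_nodes):
        if recon.structure[pos] != code:
            continue
        par = ppos[pos]
        if par < 0 or recon.structure[par] != code:
            roots.append(pos)
    return roots


def segments(recon: NeuronReconstruction, compartment: str) -> list[_Segment]:
    """Decompose a compartment into branch segments (anchor..tip/branch)."""
    code = _comp_code(compartment)
    children = _compartment_children(recon, code)
    ppos = recon.parent_positions()
    segs: list[_Segment] = []
    # (start_node, level); the anchor is the start node's parent when present
    stack: list[tuple[int, int]] = [(r, 0) for r in reversed(_compartment_roots(recon, code))]
    while stack:
        start, level = stack.pop()
        anchor = ppos[start]
        nodes = [anchor] if anchor >= 0 else []
        cur = start
        nodes.append(cur)
        while len(children[cur]) == 1:
            cur = children[cur][0]
            nodes.append(cur)
        kids = children[cur]
        segs.append(_Segment(nodes=nodes, level=level, terminal=not kids))
        for ch in reversed(kids):
            stack.append((ch, level + 1))
    return segs


# ---------------------------------------------------------------------------
# Elementary features


def total_length(recon: NeuronReconstruction, compartment: str) -> float:
    """Sum of Euclidean edge lengths over edges whose child is in ``compartment``."""
    code = _comp_code(compartment)
    child, parent = recon.edges()
    mask = recon.structure[child] == code
    if not mask.any():
        return 0.0
    d = np.linalg.norm(recon.xyz[child[mask]] - recon.xyz[parent[mask]], axis=1)
    return float(d.sum())


def sholl_counts(recon: NeuronReconstruction, compartment: str,
                 radii: Sequence[float] = DEFAULT_SHOLL_RADII) -> np.ndarray:
    """Sphere-crossing counts about the soma centroid.

    An edge crosses radius ``r`` when min(d0, d1) < r <= max(d0, d1) for its
    endpoint distances; a process that exits and re-enters a sphere is
    counted once per crossing edge.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing and positive")
    code = _comp_code(compartment)
    center = recon.soma_centroid()
    child, parent = recon.edges()
    mask = recon.structure[child] == code
    if not mask.any():
        return np.zeros(len(radii), dtype=int)
    d_child = np.linalg.norm(recon.xyz[child[mask]] - center, axis=1)
    d_parent = np.linalg.norm(recon.xyz[parent[mask]] - center, axis=1)
    lo = np.minimum(d_child, d_parent)
    hi = np.maximum(d_child, d_parent)
    return np.array([int(np.sum((lo < r) & (r <= hi))) for r in radii])


def branch_levels(recon: NeuronReconstruction, compartment: str) -> tuple[float, int]:
    """(mean, max) number of branch points above each branch segment."""
    segs = segments(recon, compartment)
    if not segs:
        return 0.0, 0
    levels = [s.level for s in segs]
    return float(np.mean(levels)), int(max(levels))


def straightness(recon: NeuronReconstruction, compartment: str,
                 weighted: bool = True) -> float:
    """Chord/path ratio per branch segment, aggregated over the compartment.

    Length-weighted mean by default (``weighted=False`` for the plain mean);
    zero-length segments are excluded with a warning.
    """
    segs = segments(recon, compartment)
    if not segs:
        raise ValueError(f"{recon.cell_id}: no {compartment} segments")
    lengths, ratios = [], []
    for s in segs:
        L = s.length(recon.xyz)
        if L == 0:
            warnings.warn(
                f"{recon.cell_id}: zero-length {compartment} segment excluded "
                "from straightness"
            )
            continue
        lengths.append(L)
        ratios.append(s.chord(recon.xyz) / L)
    if not lengths:
        raise ValueError(f"{recon.cell_id}: all {compartment} segments zero-length")
    lengths = np.asarray(lengths)
    ratios = np.asarray(ratios)
    if weighted:
        return float((ratios * lengths).sum() / lengths.sum())
    return float(ratios.mean())


def filopodia(recon: NeuronReconstruction,
              threshold: float = DEFAULT_FILOPODIA_THRESHOLD) -> tuple[int, float]:
    """Count and density of terminal dendritic branches shorter than ``threshold``.

    Density normalizes the count to total dendrite length.
    """
    segs = segments(recon, "dendrite")
    count = sum(1 for s in segs if s.terminal and s.length(recon.xyz) < threshold)
    dend_len = total_length(recon, "dendrite")
    if dend_len == 0:
        if count:
            raise ValueError(
                f"{recon.cell_id}: filopodia present but zero dendrite length"
            )
        return 0, 0.0
    return count, count / dend_len


def spans(recon: NeuronReconstruction, geom: LayerGeometry,
          compartment: str) -> tuple[float, float, float]:
    """(ML height covered, tangential span, z depth) coordinate extents."""
    code = _comp_code(compartment)
    mask = recon.structure == code
    if not mask.any():
        warnings.warn(f"{recon.cell_id}: empty {compartment} compartment, zero spans")
        return 0.0, 0.0, 0.0
    pts = recon.xyz[mask]
    out = []
    for axis in (geom.ml_normal_axis, geom.ml_tangential_axis, geom.z_axis):
        proj = pts @ axis
        out.append(float(proj.max() - proj.min()))
    return tuple(out)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Collateral classification


@dataclass(frozen=True)
class CollateralClass:
    count: int
    total_length: float
    percent: float


@dataclass(frozen=True)
class CollateralStats:
    up: CollateralClass
    down: CollateralClass


def _axon_root(recon: NeuronReconstruction) -> int:
    roots = _compartment_roots(recon, SWC_AXON)
    if not roots:
        raise ValueError(f"{recon.cell_id}: no axon")
    if len(roots) == 1:
        return roots[0]
    # multiple axonal subtrees: keep the largest by cable length
    children = _compartment_children(recon, SWC_AXON)

    def subtree_len(root: int) -> float:
        total, stack = 0.0, [root]
        while stack:
            pos = stack.pop()
            for ch in children[pos]:
                total += float(np.linalg.norm(recon.xyz[ch] - recon.xyz[pos]))
                stack.append(ch)
        return total

    warnings.warn(f"{recon.cell_id}: multiple axonal subtrees; using the longest")
    return max(roots, key=subtree_len)


def _main_axon_path(recon: NeuronReconstruction) -> list[int]:
    """Geodesically longest root-to-tip path within the axon compartment."""
    root = _axon_root(recon)
    children = _compartment_children(recon, SWC_AXON)
    best_len: dict[int, float] = {}
    best_child: dict[int, int] = {}
    order: list[int] = []
    stack = [root]
    while stack:  # postorder via two passes
        pos = stack.pop()
        order.append(pos)
        stack.extend(children[pos])
    for pos in reversed(order):
        best, arg = 0.0, -1
        for ch in children[pos]:
            d = float(np.linalg.norm(recon.xyz[ch] - recon.xyz[pos])) + best_len[ch]
            if d > best:
                best, arg = d, ch
        best_len[pos] = best
        best_child[pos] = arg
    path = [root]
    while best_child[path[-1]] != -1:
        path.append(best_child[path[-1]])
    return path


def _interp_at_arc(points: np.ndarray, target: float) -> np.ndarray:
    """Point at arc length ``target`` along a polyline (clamped to the end)."""
    acc = 0.0
    for i in range(1, len(points)):
        step = float(np.linalg.norm(points[i] - points[i - 1]))
        if acc + step >= target and step > 0:
            t = (target - acc) / step
            return points[i - 1] + t * (points[i] - points[i - 1])
        acc += step
    return points[-1]


def _initial_direction(recon: NeuronReconstruction, start: int, head: int,
                       children: list[list[int]],
                       secant_length: float) -> np.ndarray | None:
    """Secant direction over the first branch run from ``start`` via ``head``."""
    pts = [recon.xyz[start], recon.xyz[head]]
    cur = head
    while len(children[cur]) == 1:  # stop at branch points and tips
        cur = children[cur][0]
        pts.append(recon.xyz[cur])
    pts = np.asarray(pts)
    arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if arc == 0:
        return None
    target = min(secant_length, arc)
    vec = _interp_at_arc(pts, target) - pts[0]
    n = np.linalg.norm(vec)
    return vec / n if n > 0 else None


def classify_collaterals(recon: NeuronReconstruction, geom: LayerGeometry,
                         angle_threshold: float = DEFAULT_COLLATERAL_ANGLE,
                         secant_length: float = DEFAULT_SECANT_LENGTH,
                         ) -> CollateralStats:
    """Upward/downward axon collateral statistics under the angle rule.

    The main axon is the geodesically longest root-to-tip axonal path.  A
    side branch is counted only when its initial direction deviates from the
    local main-axon direction by more than ``angle_threshold`` degrees; it is
    classed up or down by the sign of its ML-normal component.
    """
    children = _compartment_children(recon, SWC_AXON)
    path = _main_axon_path(recon)
    on_path = set(path)
    up_count = down_count = 0
    up_len = down_len = 0.0
    for i, pos in enumerate(path):
        for head in children[pos]:
            if head in on_path:
                continue
            branch_dir = _initial_direction(recon, pos, head, children, secant_length)
            if branch_dir is None:
                continue
            main_pts = recon.xyz[path[i:]]
            if len(main_pts) < 2:
                # branch at the main-path tip: use the incoming shaft direction
                main_pts = recon.xyz[path[max(i - 1, 0):]]
            shaft_vec = _interp_at_arc(main_pts, secant_length) - main_pts[0]
            nrm = np.linalg.norm(shaft_vec)
            if nrm == 0:
                continue
            shaft_dir = shaft_vec / nrm
            cosang = float(np.clip(branch_dir @ shaft_dir, -1.0, 1.0))
            angle = np.degrees(np.arccos(cosang))
            if angle <= angle_threshold:
                continue
            # subtree cable length including the branch-point edge
            sub = float(np.linalg.norm(recon.xyz[head] - recon.xyz[pos]))
            stack = [head]
            while stack:
                p = stack.pop()
                for ch in children[p]:
                    sub += float(np.linalg.norm(recon.xyz[ch] - recon.xyz[p]))
                    stack.append(ch)
            if branch_dir @ geom.ml_normal_axis >= 0:
                up_count += 1
                up_len += sub
            else:
                down_count += 1
                down_len += sub
    total = up_len + down_len
    up_pct = 100.0 * up_len / total if total > 0 else 0.0
    down_pct = 100.0 * down_len / total if total > 0 else 0.0
    return CollateralStats(
        up=CollateralClass(up_count, up_len, up_pct),
        down=CollateralClass(down_count, down_len, down_pct),
    )


# ---------------------------------------------------------------------------
# Scalar features


def weighted_basket_score(counts: BasketCounts | tuple[int, int, int]) -> float:
    """Weighted count of Purkinje-soma-targeting terminals.

    Full baskets weigh 1, basket-like terminals 0.75, partial envelopments 0.5.
    """
    if not isinstance(counts, BasketCounts):
        counts = BasketCounts(*counts)
    return 1.0 * counts.full + 0.75 * counts.basket_like + 0.5 * counts.partial


def soma_volume_ellipsoid(dx: float, dy: float, dz: float,
                          formula: str = "as_printed") -> float:
    """Ellipsoid soma volume from the three calliper diameters.

    ``as_printed`` follows the source convention V = 4/3 pi * dx * dy * dz
    applied to diameters; ``geometric`` is the standard ellipsoid volume
    (pi/6 * dx * dy * dz, i.e. 4/3 pi over the semi-axes).
    """
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("diameters must be positive")
    if formula == "as_printed":
        return 4.0 / 3.0 * np.pi * dx * dy * dz
    if formula == "geometric":
        return np.pi / 6.0 * dx * dy * dz
    raise ValueError("formula must be 'as_printed' or 'geometric'")


def relative_ml_position(soma_h: float, geom: LayerGeometry) -> float:
    """Laminar position: soma height divided by ML height."""
    if geom.ml_height <= 0:
        raise ValueError("ML height must be positive")
    return soma_h / geom.ml_height


@dataclass(frozen=True)
class StructuralCounts:
    primary_dendrites: int
    pcl_reaching_branches: int
    axon_carrying_dendrite: bool


def structural_counts(recon: NeuronReconstruction,
                      geom: LayerGeometry) -> StructuralCounts:
    """Primary dendrites, PCL-reaching axon tips, axon-carrying dendrite flag."""
    ppos = recon.parent_positions()
    primary = 0
    for pos in range(recon.n_nodes):
        if recon.structure[pos] == SWC_DENDRITE and ppos[pos] >= 0 \
                and recon.structure[ppos[pos]] == SWC_SOMA:
            primary += 1
    children = _compartment_children(recon, SWC_AXON)
    pcl_reaching = 0
    for pos in range(recon.n_nodes):
        if recon.structure[pos] == SWC_AXON and not children[pos]:
            if float(recon.xyz[pos] @ geom.ml_normal_axis) < geom.pcl_top:
                pcl_reaching += 1
    acd = any(
        recon.structure[pos] == SWC_AXON and ppos[pos] >= 0
        and recon.structure[ppos[pos]] == SWC_DENDRITE
        for pos in range(recon.n_nodes)
    )
    return StructuralCounts(primary, pcl_reaching, acd)


# ---------------------------------------------------------------------------
# Schemas


@dataclass(frozen=True)
class FeatureDef:
    name: str
    compartment: str  # axon | dendrite | soma | location
    units: str = ""


@dataclass
class FeatureSchema:
    """Named, ordered feature repertoire plus the clustering subset/groups."""

    name: str
    features: list[FeatureDef]
    clustering_subset: list[str] = field(default_factory=list)
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError(f"schema {self.name}: duplicate feature names")
        unknown = [n for n in self.clustering_subset if n not in names]
        if unknown:
            raise ValueError(f"schema {self.name}: clustering subset not in "
                             f"features: {unknown}")
        for g, members in self.groups.items():
            bad = [n for n in members if n not in names]
            if bad:
                raise ValueError(f"schema {self.name}: group {g} has unknown "
                                 f"features {bad}")

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureSchema":
        doc = yaml.safe_load(Path(path).read_text())
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: Mapping) -> "FeatureSchema":
        feats = [FeatureDef(f["name"], f["compartment"], f.get("units", ""))
                 for f in doc["features"]]
        return cls(
            name=doc["name"],
            features=feats,
            clustering_subset=list(doc.get("clustering_subset", [])),
            groups={k: list(v) for k, v in doc.get("groups", {}).items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "name": self.name,
            "features": [
                {"name": f.name, "compartment": f.compartment, "units": f.units}
                for f in self.features
            ],
            "clustering_subset": list(self.clustering_subset),
            "groups": {k: list(v) for k, v in self.groups.items()},
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_schema(preset: str) -> FeatureSchema:
    """Load a packaged schema preset (mature_27, developmental_28, clustering_19)."""
    ref = resources.files("morphotime") / "schemas" / f"{preset}.yaml"
    with resources.as_file(ref) as path:
        if not Path(path).exists():
            raise ValueError(f"unknown schema preset {preset!r}")
        return FeatureSchema.from_yaml(path)


# ---------------------------------------------------------------------------
# Extraction


@dataclass
class FeatureVector:
    cell_id: str
    values: pd.Series
    provenance: pd.Series  # computed | annotated | missing


def _compute_registry(recon: NeuronReconstruction, geom: LayerGeometry,
                      sholl_radii: Sequence[float],
                      filopodia_threshold: float,
                      collateral_angle: float) -> dict[str, object]:
    """Lazily evaluated feature computations shared across schema entries."""
    cache: dict[str, object] = {}

    def coll() -> CollateralStats:
        if "coll" not in cache:
            cache["coll"] = classify_collaterals(recon, geom, collateral_angle)
        return cache["coll"]  # type: ignore[return-value]

    def sholl() -> np.ndarray:
        if "sholl" not in cache:
            cache["sholl"] = sholl_counts(recon, "axon", sholl_radii)
        return cache["sholl"]  # type: ignore[return-value]

    def struct() -> StructuralCounts:
        if "struct" not in cache:
            cache["struct"] = structural_counts(recon, geom)
        return cache["struct"]  # type: ignore[return-value]

    def axon_bl() -> tuple[float, int]:
        if "axon_bl" not in cache:
            cache["axon_bl"] = branch_levels(recon, "axon")
        return cache["axon_bl"]  # type: ignore[return-value]

    def filo() -> tuple[int, float]:
        if "filo" not in cache:
            cache["filo"] = filopodia(recon, filopodia_threshold)
        return cache["filo"]  # type: ignore[return-value]

    def axon_spans() -> tuple[float, float, float]:
        if "axon_spans" not in cache:
            cache["axon_spans"] = spans(recon, geom, "axon")
        return cache["axon_spans"]  # type: ignore[return-value]

    def sh() -> float:
        if "sh" not in cache:
            cache["sh"] = soma_height(recon, geom)
        return cache["sh"]  # type: ignore[return-value]

    def axon_segments_stats() -> tuple[int, int]:
        if "axseg" not in cache:
            segs = segments(recon, "axon")
            tips = sum(1 for s in segs if s.terminal)
            bps = sum(1 for s in segs if not s.terminal)
            cache["axseg"] = (tips, bps)
        return cache["axseg"]  # type: ignore[return-value]

    reg: dict[str, object] = {
        "axon_length": lambda: total_length(recon, "axon"),
        "dendrite_length": lambda: total_length(recon, "dendrite"),
        "axon_mean_branch_level": lambda: axon_bl()[0],
        "axon_max_branch_level": lambda: float(axon_bl()[1]),
        "axon_straightness": lambda: straightness(recon, "axon"),
        "filopodia_count": lambda: float(filo()[0]),
        "filopodia_density": lambda: filo()[1],
        "dendrite_ml_height": lambda: spans(recon, geom, "dendrite")[0],
        "axon_ml_height": lambda: axon_spans()[0],
        "axon_span": lambda: axon_spans()[1],
        "axon_z_depth": lambda: axon_spans()[2],
        "collateral_up_count": lambda: float(coll().up.count),
        "collateral_up_length": lambda: coll().up.total_length,
        "collateral_up_percent": lambda: coll().up.percent,
        "collateral_down_count": lambda: float(coll().down.count),
        "collateral_down_length": lambda: coll().down.total_length,
        "collateral_down_percent": lambda: coll().down.percent,
        "primary_dendrites": lambda: float(struct().primary_dendrites),
        "pcl_reaching_branches": lambda: float(struct().pcl_reaching_branches),
        "axon_carrying_dendrite": lambda: float(struct().axon_carrying_dendrite),
        "soma_height": sh,
        "relative_ml_position": lambda: relative_ml_position(sh(), geom),
        "axon_terminal_count": lambda: float(axon_segments_stats()[0]),
        "axon_branch_point_count": lambda: float(axon_segments_stats()[1]),
    }
    for i, r in enumerate(sholl_radii):
        reg[f"axon_sholl_{int(r)}"] = (lambda idx=i: float(sholl()[idx]))
    return reg


_DENDRITE_DEPENDENT = {
    "dendrite_length", "filopodia_count", "filopodia_density",
    "dendrite_ml_height", "primary_dendrites",
}
_AXON_DEPENDENT_PREFIX = ("axon_", "collateral_", "pcl_reaching")


def extract_features(recon: NeuronReconstruction, geom: LayerGeometry,
                     schema: FeatureSchema,
                     sholl_radii: Sequence[float] = DEFAULT_SHOLL_RADII,
                     filopodia_threshold: float = DEFAULT_FILOPODIA_THRESHOLD,
                     collateral_angle: float = DEFAULT_COLLATERAL_ANGLE,
                     soma_volume_formula: str = "as_printed") -> FeatureVector:
    """Evaluate a schema's features for one reconstruction.

    Computable features are evaluated from the tree and layer geometry;
    annotated features (basket terminal categories, measured soma volumes,
    arbitrary extras) are passed through with ``provenance='annotated'``.
    Features of an empty compartment come back NaN with ``provenance='missing'``;
    a feature that needs an absent annotation raises.
    """
    ann = recon.annotations or AnnotationRecord()
    reg = _compute_registry(recon, geom, sholl_radii, filopodia_threshold,
                            collateral_angle)
    has_dendrite = bool(np.any(recon.structure == SWC_DENDRITE))
    has_axon = bool(np.any(recon.structure == SWC_AXON))
    values: dict[str, float] = {}
    prov: dict[str, str] = {}
    for fdef in schema.features:
        name = fdef.name
        if name == "weighted_basket_score":
            values[name] = weighted_basket_score(ann.basket_terminal_counts)
            prov[name] = "annotated"
            continue
        if name == "soma_volume":
            if ann.soma_diameters is not None:
                values[name] = soma_volume_ellipsoid(
                    *ann.soma_diameters, formula=soma_volume_formula)
                prov[name] = "computed"
            elif ann.soma_volume is not None:
                values[name] = float(ann.soma_volume)
                prov[name] = "annotated"
            else:
                raise ValueError(
                    f"{recon.cell_id}: feature 'soma_volume' requires "
                    "soma_diameters or soma_volume annotation"
                )
            continue
        if name in ("soma_x_diameter", "soma_y_diameter", "soma_z_diameter"):
            if ann.soma_diameters is None:
                raise ValueError(
                    f"{recon.cell_id}: feature {name!r} requires the "
                    "soma_diameters annotation"
                )
            values[name] = float(ann.soma_diameters["xyz".index(name[5])])
            prov[name] = "annotated"
            continue
        if name in reg:
            if name in _DENDRITE_DEPENDENT and not has_dendrite:
                values[name], prov[name] = np.nan, "missing"
                continue
            if name.startswith(_AXON_DEPENDENT_PREFIX) and not has_axon:
                values[name], prov[name] = np.nan, "missing"
                continue
            values[name] = float(reg[name]())  # type: ignore[operator]
            prov[name] = "computed"
            continue
        if name in ann.extras:
            values[name] = float(ann.extras[name])
            prov[name] = "annotated"
            continue
        raise ValueError(
            f"{recon.cell_id}: feature {name!r} is neither computable nor "
            "annotated"
        )
    order = schema.feature_names
    return FeatureVector(
        cell_id=recon.cell_id,
        values=pd.Series(values).reindex(order),
        provenance=pd.Series(prov).reindex(order),
    )


def extract_feature_table(recons: Iterable[NeuronReconstruction],
                          geoms: LayerGeometry | Mapping[str, LayerGeometry],
                          schema: FeatureSchema,
                          **kwargs) -> "pd.DataFrame":
    """Stack per-cell feature vectors into a cells x features DataFrame."""
    rows = {}
    for recon in recons:
        geom = geoms[recon.cell_id] if isinstance(geoms, Mapping) else geoms
        rows[recon.cell_id] = extract_features(recon, geom, schema, **kwargs).values
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "cell_id"
    return frame
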