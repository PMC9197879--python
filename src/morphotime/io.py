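"""Reading, writing and validating neuron reconstructions and feature tables.

Reconstructions travel as SWC text (the NeuroMorpho interchange dialect:
seven whitespace-separated columns, ``#`` comments, 1-based node ids, parent
``-1`` for the root).  Per-cell annotations (fate cohort, expert maturation
stage, basket terminal counts, ...) and the molecular-layer coordinate frame
are carried alongside, because every laminar feature is measured relative to
the Purkinje-cell-layer (PCL) top and molecular-layer (ML) top of the section
the cell was imaged in.

Feature tables are plain CSV/TSV with a ``cell_id`` column plus a small set of
reserved metadata column names; everything else is treated as a numeric
feature column.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SWCFormatError",
    "ReconstructionError",
    "MissingSomaError",
    "AnnotationRecord",
    "BasketCounts",
    "NeuronReconstruction",
    "LayerGeometry",
    "FeatureTable",
    "read_swc",
    "write_swc",
    "soma_height",
    "read_feature_table",
    "write_feature_table",
    "RESERVED_METADATA",
]

# SWC structure codes (subset used here).
SWC_UNSPECIFIED = 0
SWC_SOMA = 1
SWC_AXON = 2
SWC_DENDRITE = 3

STRUCTURE_NAMES = {
    SWC_UNSPECIFIED: "unspecified",
    SWC_SOMA: "soma",
    SWC_AXON: "axon",
    SWC_DENDRITE: "dendrite",
}
STRUCTURE_CODES = {v: k for k, v in STRUCTURE_NAMES.items()}

RESERVED_METADATA = (
    "cell_id",
    "fate_label",
    "expert_stage",
    "dpi",
    "folium",
    "curated_class",
)

FATE_LABELS = ("BC_fated", "SC_fated", "unknown")
CURATED_CLASSES = ("canonical_BC", "canonical_SC", "non_canonical", "unassigned")


class SWCFormatError(ValueError):
    """Malformed SWC text (bad field, missing parent, multiple roots...)."""


class ReconstructionError(ValueError):
    """A reconstruction violating the tree invariants."""


class MissingSomaError(ReconstructionError):
    """Operation requires at least one soma node."""


@dataclass(frozen=True)
class BasketCounts:
    """Counts of Purkinje-soma-targeting axon terminals by completeness."""

    full: int = 0
    basket_like: int = 0
    partial: int = 0

    def __post_init__(self) -> None:
        for name in ("full", "basket_like", "partial"):
            if getattr(self, name) < 0:
                raise ValueError(f"basket terminal count {name!r} must be >= 0")


@dataclass
class AnnotationRecord:
    """Per-cell annotations that cannot be computed from the SWC tree.

    ``soma_diameters`` are the slice-mode X/Y/Z calliper measurements used for
    the developmental ellipsoid soma volume; ``soma_volume`` is a pre-measured
    render volume (mature dataset).  ``extras`` carries any additional
    annotated feature values by name.
    """

    fate_label: str = "unknown"
    expert_stage: int | None = None
    dpi: float | None = None
    folium: str | None = None
    curated_class: str = "unassigned"
    basket_terminal_counts: BasketCounts = field(default_factory=BasketCounts)
    soma_diameters: tuple[float, float, float] | None = None
    soma_volume: float | None = None
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fate_label not in FATE_LABELS:
            raise ValueError(f"fate_label must be one of {FATE_LABELS}")
        if self.curated_class not in CURATED_CLASSES:
            raise ValueError(f"curated_class must be one of {CURATED_CLASSES}")
        if self.expert_stage is not None and self.expert_stage not in (1, 2, 3, 4):
            raise ValueError("expert_stage must be in {1, 2, 3, 4} when present")


@dataclass
class NeuronReconstruction:
    """A single neuron as a typed tree of 3-D points.

    Exactly one connected tree with one root, at least one soma node, finite
    coordinates and non-negative radii; validated on construction.
    """

    cell_id: str
    ids: np.ndarray  # (n,) int node ids
    parents: np.ndarray  # (n,) int parent ids, -1 for the root
    structure: np.ndarray  # (n,) int SWC structure codes
    xyz: np.ndarray  # (n, 3) float, micrometres
    radius: np.ndarray  # (n,) float, micrometres
    annotations: AnnotationRecord | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.parents = np.asarray(self.parents, dtype=int)
        self.structure = np.asarray(self.structure, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self._validate()
        self._index = {int(i): pos for pos, i in enumerate(self.ids)}
        self._children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for pos, pid in enumerate(self.parents):
            if pid != -1:
                self._children[self._index[int(pid)]].append(pos)

    # -- invariants ----------------------------------------------------
    def _validate(self) -> None:
        n = len(self.ids)
        if n == 0:
            raise ReconstructionError(f"{self.cell_id}: empty reconstruction")
        if self.xyz.shape != (n, 3):
            raise ReconstructionError(f"{self.cell_id}: xyz must be (n, 3)")
        if len(set(int(i) for i in self.ids)) != n:
            raise ReconstructionError(f"{self.cell_id}: duplicate node ids")
        if not np.all(np.isfinite(self.xyz)):
            raise ReconstructionError(f"{self.cell_id}: non-finite coordinates")
        if np.any(self.radius < 0):
            raise ReconstructionError(f"{self.cell_id}: negative radius")
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) == 0:
            raise ReconstructionError(f"{self.cell_id}: no root node (parent -1)")
        if len(roots) > 1:
            raise SWCFormatError(
                f"{self.cell_id}: multiple roots (nodes "
                f"{[int(self.ids[r]) for r in roots]}); expected a single tree"
            )
        id_set = set(int(i) for i in self.ids)
        for pos, pid in enumerate(self.parents):
            if pid != -1 and int(pid) not in id_set:
                raise SWCFormatError(
                    f"{self.cell_id}: node {int(self.ids[pos])} references "
                    f"missing parent {int(pid)}"
                )
        if not np.any(self.structure == SWC_SOMA):
            raise MissingSomaError(f"{self.cell_id}: no soma node")
        # Connectivity/acyclicity: every node must be reachable from the root.
        index = {int(i): pos for pos, i in enumerate(self.ids)}
        children: list[list[int]] = [[] for _ in range(n)]
        for pos, pid in enumerate(self.parents):
            if pid != -1:
                children[index[int(pid)]].append(pos)
        seen = np.zeros(n, dtype=bool)
        stack = [int(roots[0])]
        while stack:
            pos = stack.pop()
            if seen[pos]:
                continue
            seen[pos] = True
            stack.extend(children[pos])
        if not seen.all():
            bad = [int(self.ids[i]) for i in np.flatnonzero(~seen)]
            raise ReconstructionError(
                f"{self.cell_id}: nodes {bad[:5]} unreachable from root "
                "(disconnected or cyclic)"
            )

    # -- helpers -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root(self) -> int:
        """Positional index of the root node."""
        return int(np.flatnonzero(self.parents == -1)[0])

    def position_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def children_of(self, pos: int) -> list[int]:
        return self._children[pos]

    def parent_positions(self) -> np.ndarray:
        """Per-node positional index of the parent (-1 for the root)."""
        out = np.full(self.n_nodes, -1, dtype=int)
        for pos, pid in enumerate(self.parents):
            if pid != -1:
                out[pos] = self._index[int(pid)]
        return out

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(child_pos, parent_pos) arrays over all non-root nodes."""
        ppos = self.parent_positions()
        child = np.flatnonzero(ppos >= 0)
        return child, ppos[child]

    def edge_lengths(self) -> np.ndarray:
        child, parent = self.edges()
        return np.linalg.norm(self.xyz[child] - self.xyz[parent], axis=1)

    def soma_centroid(self) -> np.ndarray:
        """Unweighted centroid of all soma nodes (point or contour somas)."""
        mask = self.structure == SWC_SOMA
        if not mask.any():
            raise MissingSomaError(f"{self.cell_id}: no soma node")
        return self.xyz[mask].mean(axis=0)

    def translated(self, offset: Sequence[float]) -> "NeuronReconstruction":
        return replace(self, xyz=self.xyz + np.asarray(offset, dtype=float))


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path: str | Path, cell_id: str | None = None,
             annotations: AnnotationRecord | None = None) -> NeuronReconstruction:
    """Parse an SWC file into a validated :class:`NeuronReconstruction`.

    Structure codes 1/2/3 map to soma/axon/dendrite; any other code is kept
    as ``unspecified``.  Node order is preserved.
    """
    path = Path(path)
    name = cell_id if cell_id is not None else path.stem
    ids, parents, structs, coords, radii = [], [], [], [], []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCFormatError(
                    f"{path}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            try:
                nid = int(fields[0])
                stype = int(fields[1])
                x, y, z, r = (float(v) for v in fields[2:6])
                pid = int(fields[6])
            except ValueError as exc:
                raise SWCFormatError(f"{path}:{lineno}: non-numeric field ({exc})")
            ids.append(nid)
            structs.append(stype if stype in STRUCTURE_NAMES else SWC_UNSPECIFIED)
            coords.append((x, y, z))
            radii.append(r)
            parents.append(pid)
    if not ids:
        raise SWCFormatError(f"{path}: no data lines")
    return NeuronReconstruction(
        cell_id=name,
        ids=np.array(ids),
        parents=np.array(parents),
        structure=np.array(structs),
        xyz=np.array(coords),
        radius=np.array(radii),
        annotations=annotations,
    )


def write_swc(recon: NeuronReconstruction, path: str | Path) -> None:
    """Write canonical 7-column SWC (coordinates at micro-metre precision)."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# {recon.cell_id}\n")
    buf.write("# id type x y z radius parent\n")
    for pos in range(recon.n_nodes):
        x, y, z = recon.xyz[pos]
        buf.write(
            f"{int(recon.ids[pos])} {int(recon.structure[pos])} "
            f"{x:.6f} {y:.6f} {z:.6f} {recon.radius[pos]:.6f} "
            f"{int(recon.parents[pos])}\n"
        )
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Layer geometry


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length axis vector")
    return v / n


@dataclass
class LayerGeometry:
    """Molecular-layer coordinate frame of one sagittal section.

    ``pcl_top``/``ml_top`` are positions on the ML-normal axis (micrometres);
    ``ml_normal_axis`` points from the Purkinje layer towards the pia,
    ``ml_tangential_axis`` runs sagittally along the PCL, and ``z_axis``
    follows the parallel fibres.  Defaults take the image frame's +y as the
    ML normal.
    """

    pcl_top: float
    ml_top: float
    ml_normal_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    ml_tangential_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    z_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.ml_normal_axis = _unit(self.ml_normal_axis)
        self.ml_tangential_axis = _unit(self.ml_tangential_axis)
        self.z_axis = _unit(self.z_axis)
        if self.ml_top <= self.pcl_top:
            raise ValueError("ml_top must exceed pcl_top")
        G = np.stack([self.ml_normal_axis, self.ml_tangential_axis, self.z_axis])
        if not np.allclose(G @ G.T, np.eye(3), atol=1e-8):
            raise ValueError("layer axes must be mutually orthogonal unit vectors")

    @property
    def ml_height(self) -> float:
        return self.ml_top - self.pcl_top

    def normal_coord(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.ml_normal_axis

    def tangential_coord(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.ml_tangential_axis

    def z_coord(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.z_axis

    # YAML round-trip, one document per section
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "pcl_top": float(self.pcl_top),
            "ml_top": float(self.ml_top),
            "ml_normal_axis": [float(v) for v in self.ml_normal_axis],
            "ml_tangential_axis": [float(v) for v in self.ml_tangential_axis],
            "z_axis": [float(v) for v in self.z_axis],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LayerGeometry":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            pcl_top=float(doc["pcl_top"]),
            ml_top=float(doc["ml_top"]),
            ml_normal_axis=np.asarray(doc.get("ml_normal_axis", [0, 1, 0]), float),
            ml_tangential_axis=np.asarray(doc.get("ml_tangential_axis", [1, 0, 0]), float),
            z_axis=np.asarray(doc.get("z_axis", [0, 0, 1]), float),
        )


def soma_height(recon: NeuronReconstruction, geom: LayerGeometry) -> float:
    """Distance from the PCL top to the soma centroid along the ML normal."""
    centroid = recon.soma_centroid()
    return float(centroid @ geom.ml_normal_axis - geom.pcl_top)


# ---------------------------------------------------------------------------
# Feature tables


class FeatureTable:
    """Cells x named-features matrix plus split-out metadata columns.

    ``features`` is a numeric DataFrame indexed by ``cell_id``; ``metadata``
    holds the reserved columns (fate label, expert stage, dpi, ...) for the
    same index.
    """

    def __init__(self, features: pd.DataFrame, metadata: pd.DataFrame | None = None):
        if features.index.has_duplicates:
            dups = features.index[features.index.duplicated()].tolist()
            raise ValueError(f"duplicate cell_id values: {dups[:5]}")
        for col in features.columns:
            if not pd.api.types.is_numeric_dtype(features[col]):
                coerced = pd.to_numeric(features[col], errors="coerce")
                bad = features.index[coerced.isna() & features[col].notna()]
                raise ValueError(
                    f"non-numeric feature value in column {col!r}, "
                    f"row {bad[0] if len(bad) else '?'}"
                )
        self.features = features.astype(float)
        if metadata is None:
            metadata = pd.DataFrame(index=features.index)
        self.metadata = metadata.loc[features.index]
        self.features.index.name = "cell_id"
        self.metadata.index.name = "cell_id"

    # -- basic protocol -------------------------------------------------
    @property
    def cell_ids(self) -> pd.Index:
        return self.features.index

    @property
    def n_cells(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def __len__(self) -> int:
        return self.n_cells

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.metadata.copy())

    def subset_features(self, names: Iterable[str]) -> "FeatureTable":
        names = list(names)
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise KeyError(f"unknown features: {missing}")
        return FeatureTable(self.features[names].copy(), self.metadata.copy())

    def subset_cells(self, cell_ids: Iterable[str]) -> "FeatureTable":
        idx = pd.Index(cell_ids)
        return FeatureTable(self.features.loc[idx].copy(), self.metadata.loc[idx].copy())

    def values(self) -> np.ndarray:
        return self.features.to_numpy()

    # -- frame conversion ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.metadata, self.features], axis=1).reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        if "cell_id" not in frame.columns:
            raise ValueError("feature table requires a 'cell_id' column")
        frame = frame.set_index("cell_id")
        meta_cols = [c for c in RESERVED_METADATA if c in frame.columns]
        metadata = frame[meta_cols]
        features = frame.drop(columns=meta_cols)
        return cls(features, metadata)


_ANNOTATION_COLUMNS = (
    "fate_label", "expert_stage", "dpi", "folium", "curated_class",
    "basket_full", "basket_like", "basket_partial",
    "soma_x_diameter", "soma_y_diameter", "soma_z_diameter", "soma_volume",
)


def read_annotations(path: str | Path,
                     sep: str | None = None) -> dict[str, AnnotationRecord]:
    """Read a per-cell annotation table into :class:`AnnotationRecord` objects.

    Recognized columns: the reserved metadata names, basket terminal counts
    (``basket_full``/``basket_like``/``basket_partial``), soma calliper
    diameters and a measured ``soma_volume``; any other numeric column goes
    into ``extras`` under its own name.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    frame = pd.read_csv(path, sep=sep)
    if "cell_id" not in frame.columns:
        raise ValueError("annotation table requires a 'cell_id' column")
    frame = frame.set_index("cell_id")
    records: dict[str, AnnotationRecord] = {}
    for cid, row in frame.iterrows():
        def get(col, default=None):
            v = row.get(col)
            return default if v is None or (isinstance(v, float) and np.isnan(v)) else v

        diam = tuple(
            get(f"soma_{ax}_diameter") for ax in "xyz")
        extras = {
            c: float(row[c]) for c in frame.columns
            if c not in _ANNOTATION_COLUMNS and pd.notna(row[c])
            and isinstance(row[c], (int, float, np.integer, np.floating))
        }
        stage = get("expert_stage")
        records[str(cid)] = AnnotationRecord(
            fate_label=str(get("fate_label", "unknown")),
            expert_stage=int(stage) if stage is not None else None,
            dpi=float(get("dpi")) if get("dpi") is not None else None,
            folium=str(get("folium")) if get("folium") is not None else None,
            curated_class=str(get("curated_class", "unassigned")),
            basket_terminal_counts=BasketCounts(
                int(get("basket_full", 0)), int(get("basket_like", 0)),
                int(get("basket_partial", 0))),
            soma_diameters=(tuple(float(d) for d in diam)
                            if all(d is not None for d in diam) else None),
            soma_volume=(float(get("soma_volume"))
                         if get("soma_volume") is not None else None),
            extras=extras,
        )
    return records


def write_annotations(records: Mapping[str, AnnotationRecord],
                      path: str | Path) -> None:
    """Write annotation records as a CSV sidecar (inverse of read_annotations)."""
    rows = []
    for cid, ann in records.items():
        row: dict[str, object] = {
            "cell_id": cid,
            "fate_label": ann.fate_label,
            "expert_stage": ann.expert_stage,
            "dpi": ann.dpi,
            "folium": ann.folium,
            "curated_class": ann.curated_class,
            "basket_full": ann.basket_terminal_counts.full,
            "basket_like": ann.basket_terminal_counts.basket_like,
            "basket_partial": ann.basket_terminal_counts.partial,
            "soma_volume": ann.soma_volume,
        }
        if ann.soma_diameters is not None:
            for ax, d in zip("xyz", ann.soma_diameters):
                row[f"soma_{ax}_diameter"] = d
        row.update(ann.extras)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_table(path: str | Path, sep: str | None = None) -> FeatureTable:
    """Read a delimited feature table (CSV by default, TSV for .tsv/.txt)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    frame = pd.read_csv(path, sep=sep)
    return FeatureTable.from_frame(frame)


def write_feature_table(table: FeatureTable, path: str | Path,
                        sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table.to_frame().to_csv(path, sep=sep, index=False)
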