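"""Layer lattices, connectivity generators and graph-file round trip.

A simulation's structure is a set of named layers — each a 2-D grid of
cells of one declarative cell type, sharing parameters and a vertical
coordinate z — plus directed, typed, weighted (and possibly delayed)
edges between cells.  Six connectivity generators build the edge sets:
one-to-one, nearest neighbours, 4+1, radius, Gaussian-weighted and fully
connected.  Distances are always the 2-D Euclidean distance in the common
(x, y) frame; the vertical separation between layers is ignored.

Graphs serialise to a documented JSON file (structure + initial values);
model parameters live in a separate JSON keyed by layer and synapse type.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ValidationError",
    "LayerSpec",
    "Edge",
    "Graph",
    "cell_position",
    "euclidean_distance",
    "gaussian_weight",
    "connect",
    "CONNECTIVITY_KINDS",
    "save_graph",
    "load_graph",
]


class ValidationError(ValueError):
    """Schema violation; ``fields`` lists the offending entries."""

    def __init__(self, message: str, fields: list[str] | None = None):
        self.fields = fields or []
        if self.fields:
            message = f"{message}: {', '.join(self.fields)}"
        super().__init__(message)


@dataclass
class LayerSpec:
    """A rectangular grid of cells of a single type.

    Cells are indexed row-major from the origin corner (0-based); cell k
    sits at ``origin + spacing * (k % nx, k // nx)``.
    """
    name: str
    cell_type: str
    nx: int
    ny: int
    spacing: float = 1.0
    modality: str = "mm"  # mm | degrees | pixels
    origin: tuple[float, float] = (0.0, 0.0)
    z: float = 0.0

    def __post_init__(self):
        bad = []
        if self.nx < 1:
            bad.append("nx")
        if self.ny < 1:
            bad.append("ny")
        if self.spacing <= 0:
            bad.append("spacing")
        if self.modality not in ("mm", "degrees", "pixels"):
            bad.append("modality")
        if bad:
            raise ValidationError(f"invalid layer {self.name!r}", bad)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def positions(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) positions, row-major order."""
        cols = np.arange(self.n_cells) % self.nx
        rows = np.arange(self.n_cells) // self.nx
        x0, y0 = self.origin
        return np.column_stack([x0 + self.spacing * cols, y0 + self.spacing * rows])


@dataclass
class Edge:
    """A directed synaptic connection between two cells."""
    pre: tuple[str, int]   # (layer name, cell index)
    post: tuple[str, int]
    synapse_type: str
    weight: float = 1.0
    delay_steps: int = 0


@dataclass
class Graph:
    layers: list[LayerSpec] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    #: layer name -> state var name -> list of per-cell initial values
    initial_values: dict[str, dict[str, list[float]]] = field(default_factory=dict)

    def layer(self, name: str) -> LayerSpec:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(f"no layer named {name!r}")

    def validate(self) -> None:
        bad = []
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate layer names", sorted(names))
        by_name = {l.name: l for l in self.layers}
        for k, e in enumerate(self.edges):
            for end, (lname, idx) in (("pre", e.pre), ("post", e.post)):
                if lname not in by_name:
                    bad.append(f"edges[{k}].{end} layer {lname!r}")
                elif not 0 <= idx < by_name[lname].n_cells:
                    bad.append(f"edges[{k}].{end} index {idx}")
            if not math.isfinite(e.weight):
                bad.append(f"edges[{k}].weight")
            if e.delay_steps < 0:
                bad.append(f"edges[{k}].delay_steps")
        for lname, vars_ in self.initial_values.items():
            if lname not in by_name:
                bad.append(f"initial_values[{lname!r}]")
                continue
            n = by_name[lname].n_cells
            for var, vals in vars_.items():
                if len(vals) != n:
                    bad.append(f"initial_values[{lname!r}][{var!r}] length")
        if bad:
            raise ValidationError("invalid graph", bad)


def cell_position(layer: LayerSpec, index: int) -> tuple[float, float]:
    """Position of cell ``index`` on the layer's row-major grid."""
    if not 0 <= index < layer.n_cells:
        raise IndexError(f"cell index {index} out of range for {layer.name!r}")
    col, row = index % layer.nx, index // layer.nx
    return (layer.origin[0] + layer.spacing * col,
            layer.origin[1] + layer.spacing * row)


def euclidean_distance(pos_a, pos_b) -> float:
    """2-D Euclidean distance; vertical (inter-layer) separation is ignored."""
    return math.hypot(pos_a[0] - pos_b[0], pos_a[1] - pos_b[1])


def gaussian_weight(d, sigma_p: float):
    """Normalised 2-D Gaussian profile exp(−d²/2σ_p²)/(2πσ_p²)."""
    if sigma_p <= 0:
        raise ValidationError("sigma_p must be > 0", ["sigma_p"])
    d = np.asarray(d, dtype=float)
    return np.exp(-(d ** 2) / (2.0 * sigma_p ** 2)) / (2.0 * math.pi * sigma_p ** 2)


CONNECTIVITY_KINDS = (
    "one_to_one",
    "nearest_neighbors",
    "neighbor_4_plus_1",
    "radius",
    "gaussian",
    "fully_connected",
)

_EPS = 1e-9  # tolerance for distance ties on float grids


def connect(
    pre_layer: LayerSpec,
    post_layer: LayerSpec,
    kind: str,
    synapse_type: str,
    *,
    radius: float | None = None,
    sigma_p: float | None = None,
    weight_const: float = 1.0,
    truncation_sigmas: float = 4.0,
) -> list[Edge]:
    """Generate the edges of one connectivity pattern between two layers.

    ``pre_layer is post_layer`` gives intra-layer connectivity; self-edges
    (distance 0 within one layer) are produced only by the ``gaussian``
    kind, which includes the zero-distance cell by definition.

    Kinds
    -----
    one_to_one:
        each cell to the zero-distance cell of the other layer (grids must
        have equal counts).
    nearest_neighbors:
        each cell to every cell at the minimal strictly-positive distance
        (4 in the interior of a square lattice; fewer at boundaries; all
        tied cells are connected).
    neighbor_4_plus_1:
        nearest neighbours plus the zero-distance cell (equal grids).
    radius:
        all cells with 0 < d <= radius, constant weights.
    gaussian:
        all cells with d <= truncation_sigmas * sigma_p, weight from the
        normalised Gaussian profile (the d = 0 cell included).
    fully_connected:
        every cell pair (excluding self-pairs intra-layer), constant
        weights.
    """
    if kind not in CONNECTIVITY_KINDS:
        raise ValidationError(f"unknown connectivity kind {kind!r}", ["kind"])
    same_layer = pre_layer.name == post_layer.name
    if kind in ("one_to_one", "neighbor_4_plus_1"):
        if (pre_layer.nx, pre_layer.ny) != (post_layer.nx, post_layer.ny):
            raise ValidationError(
                f"{kind} requires equal grid counts "
                f"({pre_layer.nx}x{pre_layer.ny} vs {post_layer.nx}x{post_layer.ny})",
                ["nx", "ny"])

    pre_pos = pre_layer.positions()
    post_pos = post_layer.positions()
    edges: list[Edge] = []

    def add(i, j, w):
        edges.append(Edge((pre_layer.name, int(i)), (post_layer.name, int(j)),
                          synapse_type, float(w)))

    if kind == "one_to_one":
        for i in range(pre_layer.n_cells):
            add(i, i, weight_const)
        return edges

    # pairwise distances pre -> post
    diff = pre_pos[:, None, :] - post_pos[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])

    if kind in ("nearest_neighbors", "neighbor_4_plus_1"):
        for i in range(pre_layer.n_cells):
            d = dist[i]
            positive = d[d > _EPS]
            if positive.size:
                dmin = positive.min()
                for j in np.nonzero(np.abs(d - dmin) <= _EPS)[0]:
                    add(i, j, weight_const)
            if kind == "neighbor_4_plus_1":
                for j in np.nonzero(d <= _EPS)[0]:
                    add(i, j, weight_const)
        return edges

    if kind == "radius":
        if radius is None or radius <= 0:
            raise ValidationError("radius kind requires radius > 0", ["radius"])
        for i in range(pre_layer.n_cells):
            for j in np.nonzero((dist[i] > _EPS) & (dist[i] <= radius + _EPS))[0]:
                add(i, j, weight_const)
        return edges

    if kind == "gaussian":
        if sigma_p is None or sigma_p <= 0:
            raise ValidationError("gaussian kind requires sigma_p > 0", ["sigma_p"])
        cutoff = truncation_sigmas * sigma_p
        w = gaussian_weight(dist, sigma_p)
        for i in range(pre_layer.n_cells):
            for j in np.nonzero(dist[i] <= cutoff + _EPS)[0]:
                add(i, j, w[i, j])
        return edges

    # fully_connected
    for i in range(pre_layer.n_cells):
        for j in range(post_layer.n_cells):
            if same_layer and i == j:
                continue
            add(i, j, weight_const)
    return edges


# ---------------------------------------------------------------------------
# JSON round trip


def _graph_to_dict(graph: Graph) -> dict:
    return {
        "layers": [
            {
                "name": l.name, "cell_type": l.cell_type, "nx": l.nx, "ny": l.ny,
                "spacing": l.spacing, "modality": l.modality,
                "origin": list(l.origin), "z": l.z,
            }
            for l in graph.layers
        ],
        "edges": [
            {
                "pre": [e.pre[0], e.pre[1]], "post": [e.post[0], e.post[1]],
                "synapse_type": e.synapse_type, "weight": e.weight,
                "delay_steps": e.delay_steps,
            }
            for e in graph.edges
        ],
        "initial_values": graph.initial_values,
    }


def save_graph(graph: Graph, path: str | Path) -> None:
    """Write a graph to its JSON file (validating first)."""
    graph.validate()
    Path(path).write_text(json.dumps(_graph_to_dict(graph), indent=1))


def load_graph(path: str | Path, registry=None) -> Graph:
    """Load and validate a graph JSON file.

    If a model registry is given, every edge's synapse type and every
    layer's cell type must exist in it, and initial values must be present
    for each state variable of each layer's cell type.
    """
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"not valid JSON: {exc}") from exc
    missing = [k for k in ("layers", "edges", "initial_values") if k not in data]
    if missing:
        raise ValidationError("graph file missing sections", missing)

    layers = []
    for k, ld in enumerate(data["layers"]):
        need = {"name", "cell_type", "nx", "ny"}
        absent = sorted(need - set(ld))
        if absent:
            raise ValidationError(f"layers[{k}] missing fields", absent)
        layers.append(LayerSpec(
            name=ld["name"], cell_type=ld["cell_type"], nx=int(ld["nx"]),
            ny=int(ld["ny"]), spacing=float(ld.get("spacing", 1.0)),
            modality=ld.get("modality", "mm"),
            origin=tuple(ld.get("origin", (0.0, 0.0))), z=float(ld.get("z", 0.0))))

    edges = []
    for k, ed in enumerate(data["edges"]):
        absent = sorted({"pre", "post", "synapse_type"} - set(ed))
        if absent:
            raise ValidationError(f"edges[{k}] missing fields", absent)
        edges.append(Edge(
            pre=(ed["pre"][0], int(ed["pre"][1])),
            post=(ed["post"][0], int(ed["post"][1])),
            synapse_type=ed["synapse_type"], weight=float(ed.get("weight", 1.0)),
            delay_steps=int(ed.get("delay_steps", 0))))

    graph = Graph(layers=layers, edges=edges, initial_values=data["initial_values"])
    graph.validate()

    if registry is not None:
        bad = []
        for l in layers:
            if l.cell_type not in registry:
                bad.append(f"layer {l.name!r} cell type {l.cell_type!r}")
        for st in sorted({e.synapse_type for e in edges}):
            if st not in registry:
                bad.append(f"synapse type {st!r}")
        for l in layers:
            if l.cell_type not in registry:
                continue
            ctype = registry[l.cell_type]
            got = set(graph.initial_values.get(l.name, {}))
            want = {sv.name for sv in ctype.state_vars}
            lacking = sorted(want - got)
            if lacking:
                bad.append(f"initial values for {l.name!r}: missing {lacking}")
        if bad:
            raise ValidationError("graph references unknown or incomplete types", bad)
    return graph
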