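"""Queen-contiguity adjacency and the Besag intrinsic CAR (ICAR) prior.

The spatial unit of analysis is a small set of areas (e.g. local government
areas) whose contiguity defines an undirected graph.  Two areas are Queen-1
neighbors when their boundaries share at least one point (a common edge or a
single common vertex both count).  Each neighbor contributes an equal, binary
weight ``w_ij = 1``.

The structured spatial random effect ``u`` follows the intrinsic conditional
autoregressive model of Besag: conditionally on its neighbors, each ``u_i`` is
normal around the neighbor average with variance ``tau_u2 / n_i`` where
``n_i`` is the neighbor count.  The joint (improper) density is, up to a
constant,

    log p(u) = -(1 / (2 tau_u2)) * sum_{i<j, w_ij=1} (u_i - u_j)^2
             = -(1 / (2 tau_u2)) * u' L u

with ``L`` the graph Laplacian.  The impropriety (flat directions along the
per-component constants) is resolved by a sum-to-zero constraint per connected
component; isolated areas get ``u_i = 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AdjacencyStructure",
    "build_adjacency_from_polygons",
    "icar_conditional",
    "icar_logdensity_unnorm",
    "icar_sample",
    "read_gal",
    "write_gal",
    "read_neighbors_json",
    "write_neighbors_json",
    "read_geojson_polygons",
    "write_geojson_polygons",
]


@dataclass(frozen=True)
class AdjacencyStructure:
    """Symmetric, binary-weight neighbor structure over ``n_areas`` areas.

    ``neighbor_lists[i]`` is the sorted tuple of areas adjacent to area
    ``i``.  Weights are implicitly 1 for every listed pair (equal
    contribution), 0 otherwise, with a zero diagonal.
    """

    n_areas: int
    neighbor_lists: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise ValueError("n_areas must be positive")
        if len(self.neighbor_lists) != self.n_areas:
            raise ValueError(
                f"expected {self.n_areas} neighbor lists, got {len(self.neighbor_lists)}"
            )
        for i, nbrs in enumerate(self.neighbor_lists):
            if list(nbrs) != sorted(set(nbrs)):
                raise ValueError(f"neighbor list of area {i} must be sorted and unique")
            for j in nbrs:
                if j == i:
                    raise ValueError(f"area {i} lists itself as a neighbor")
                if not 0 <= j < self.n_areas:
                    raise ValueError(f"area {i} lists out-of-range neighbor {j}")
                if i not in self.neighbor_lists[j]:
                    raise ValueError(f"asymmetric adjacency: {i}->{j} but not {j}->{i}")

    @classmethod
    def from_edges(cls, n_areas: int, edges) -> "AdjacencyStructure":
        lists: list[set[int]] = [set() for _ in range(n_areas)]
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop on area {i}")
            lists[int(i)].add(int(j))
            lists[int(j)].add(int(i))
        return cls(n_areas, tuple(tuple(sorted(s)) for s in lists))

    @property
    def neighbor_counts(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbor_lists], dtype=np.int64)

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with i < j."""
        out = [(i, j) for i, nbrs in enumerate(self.neighbor_lists) for j in nbrs if i < j]
        return np.array(out, dtype=np.int64).reshape(-1, 2)

    @cached_property
    def components(self) -> np.ndarray:
        """Connected-component label per area."""
        rows, cols = [], []
        for i, nbrs in enumerate(self.neighbor_lists):
            rows.extend([i] * len(nbrs))
            cols.extend(nbrs)
        mat = sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n_areas, self.n_areas)
        )
        _, labels = connected_components(mat, directed=False)
        return labels

    @property
    def n_components(self) -> int:
        return int(self.components.max()) + 1 if self.n_areas else 0

    @property
    def rank(self) -> int:
        """Rank of the ICAR precision (Laplacian): areas minus components."""
        return self.n_areas - self.n_components

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian L = D - W (the unscaled ICAR precision)."""
        lap = np.zeros((self.n_areas, self.n_areas))
        for i, nbrs in enumerate(self.neighbor_lists):
            lap[i, i] = len(nbrs)
            for j in nbrs:
                lap[i, j] = -1.0
        return lap

    def weight_matrix(self) -> np.ndarray:
        w = np.zeros((self.n_areas, self.n_areas))
        for i, nbrs in enumerate(self.neighbor_lists):
            w[i, list(nbrs)] = 1.0
        return w


def build_adjacency_from_polygons(polygons) -> AdjacencyStructure:
    """Queen-1 adjacency from a sequence of shapely polygons.

    Two areas are adjacent iff their boundaries share at least one point
    (``touches``): a shared vertex suffices.  Polygons must be valid and
    non-overlapping; an invalid or interior-overlapping geometry raises a
    ``ValueError`` naming the offending polygon index.
    """
    polys = list(polygons)
    for idx, p in enumerate(polys):
        if p is None or p.is_empty or not p.is_valid:
            raise ValueError(f"invalid geometry for polygon {idx}")
    edges = []
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            if polys[i].overlaps(polys[j]) or polys[i].equals(polys[j]):
                raise ValueError(f"polygons {i} and {j} overlap; expected contiguity only")
            if polys[i].touches(polys[j]):
                edges.append((i, j))
    return AdjacencyStructure.from_edges(len(polys), edges)


def icar_conditional(
    u: np.ndarray, i: int, adj: AdjacencyStructure, tau_u2: float
) -> tuple[float, float]:
    """Full conditional of ``u_i`` given the rest under the ICAR prior.

    Returns ``(mean, variance)`` with mean the neighbor average of ``u`` and
    variance ``tau_u2 / n_i``.
    """
    if tau_u2 <= 0:
        raise ValueError("tau_u2 must be positive")
    nbrs = adj.neighbor_lists[i]
    if not nbrs:
        raise ValueError(
            f"area {i} has no neighbors; isolated areas take u_i = 0 by convention"
        )
    u = np.asarray(u, dtype=float)
    mean = float(u[list(nbrs)].mean())
    var = float(tau_u2) / len(nbrs)
    return mean, var


def icar_logdensity_unnorm(u: np.ndarray, adj: AdjacencyStructure, tau_u2: float) -> float:
    """Unnormalized ICAR log-density, the pairwise-difference quadratic form.

    Equal to ``-(1/(2 tau_u2)) * u' L u``; invariant to adding a constant
    within any connected component, maximal (zero) for locally constant ``u``.
    """
    if tau_u2 <= 0:
        raise ValueError("tau_u2 must be positive")
    u = np.asarray(u, dtype=float)
    if u.shape != (adj.n_areas,):
        raise ValueError(f"u must have length {adj.n_areas}")
    e = adj.edges
    if len(e) == 0:
        return 0.0
    diffs = u[e[:, 0]] - u[e[:, 1]]
    return float(-0.5 / tau_u2 * np.sum(diffs**2))


def icar_sample(
    adj: AdjacencyStructure,
    tau_u2: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw from the sum-to-zero-constrained ICAR distribution.

    Sampling uses the eigendecomposition of the Laplacian: draws live in the
    span of eigenvectors with nonzero eigenvalue (which automatically sum to
    zero per connected component), with variance ``tau_u2 / lambda_k`` along
    each.  ``tau_u2 = 0`` returns the zero field.  Isolated areas are fixed
    at zero.  Returns shape ``(n_areas,)`` or ``(size, n_areas)``.
    """
    if tau_u2 < 0:
        raise ValueError("tau_u2 must be nonnegative")
    n = adj.n_areas
    shape = (n,) if size is None else (size, n)
    if tau_u2 == 0 or adj.rank == 0:
        return np.zeros(shape)
    lam, q = np.linalg.eigh(adj.laplacian())
    keep = lam > 1e-10 * max(1.0, lam.max())
    scale = np.sqrt(tau_u2 / lam[keep])
    z = rng.standard_normal((1 if size is None else size, keep.sum()))
    draws = (z * scale) @ q[:, keep].T
    # exact re-centering per component guards against round-off drift
    for c in range(adj.n_components):
        mask = adj.components == c
        if mask.sum() > 1:
            draws[:, mask] -= draws[:, mask].mean(axis=1, keepdims=True)
        else:
            draws[:, mask] = 0.0
    return draws[0] if size is None else draws


# ---------------------------------------------------------------------------
# serialization


def write_gal(adj: AdjacencyStructure, path) -> None:
    """Write a GAL-style neighbor list: header line with the area count, then
    per area a ``id count`` line followed by the neighbor ids."""
    lines = [str(adj.n_areas)]
    for i, nbrs in enumerate(adj.neighbor_lists):
        lines.append(f"{i} {len(nbrs)}")
        lines.append(" ".join(map(str, nbrs)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gal(path) -> AdjacencyStructure:
    tokens = Path(path).read_text().split()
    pos = 0
    n = int(tokens[pos]); pos += 1
    lists: list[tuple[int, ...]] = [()] * n
    for _ in range(n):
        i = int(tokens[pos]); cnt = int(tokens[pos + 1]); pos += 2
        lists[i] = tuple(int(t) for t in tokens[pos : pos + cnt])
        pos += cnt
    return AdjacencyStructure(n, tuple(lists))


def write_neighbors_json(adj: AdjacencyStructure, path) -> None:
    obj = {
        "n_areas": adj.n_areas,
        "neighbors": {str(i): list(n) for i, n in enumerate(adj.neighbor_lists)},
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def read_neighbors_json(path) -> AdjacencyStructure:
    obj = json.loads(Path(path).read_text())
    n = int(obj["n_areas"])
    lists = [tuple(obj["neighbors"][str(i)]) for i in range(n)]
    return AdjacencyStructure(n, tuple(lists))


def write_geojson_polygons(polygons, path, properties: list[dict] | None = None) -> None:
    """Write polygons (with optional per-feature properties) as GeoJSON."""
    from shapely.geometry import mapping

    feats = []
    for i, poly in enumerate(polygons):
        props = {"area_id": i}
        if properties is not None:
            props.update(properties[i])
        feats.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_geojson_polygons(path):
    """Read polygons from GeoJSON, ordered by the ``area_id`` property when
    present, else by feature order."""
    from shapely.geometry import shape

    obj = json.loads(Path(path).read_text())
    feats = obj["features"]
    if all("area_id" in f.get("properties", {}) for f in feats):
        feats = sorted(feats, key=lambda f: f["properties"]["area_id"])
    return [shape(f["geometry"]) for f in feats]
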