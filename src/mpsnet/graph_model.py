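"""Multi-pathway spatial network (MPSN) construction.

An MPSN instance lives on a sqrt(n) x sqrt(n) integer lattice partitioned into
``k`` square regions, each containing one square *locality* of ``s`` vertices
centered in its region.  Three edge layers are superposed:

* ``S``  -- short-range layer: all pairs within Euclidean distance ``r``;
* ``L``  -- intra-locality layer: one copy of a template graph per locality;
* ``LD`` -- long-distance layer: cross pairs between localities adjacent in a
  (typically random) inter-locality graph.

All builders are deterministic functions of their arguments; the only random
component is the Erdos-Renyi inter-locality sampler, which is a pure function
of ``(k, epsilon, rng_seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PathwayLabel",
    "MPSNParams",
    "ValidationResult",
    "LocalityMap",
    "TemplateGraph",
    "InterLocalityGraph",
    "MultiPathwayGraph",
    "validate_params",
    "make_lattice",
    "assign_localities",
    "build_short_range",
    "build_template",
    "build_intra_locality",
    "sample_interlocality",
    "build_long_distance",
    "assemble",
]


class PathwayLabel(str, Enum):
    """Closed enumeration of dispersal pathways."""

    S = "S"
    L = "L"
    LD = "LD"


def _isqrt_exact(x: int) -> int | None:
    """Integer square root if ``x`` is a perfect square, else ``None``."""
    if x < 0:
        return None
    root = math.isqrt(x)
    return root if root * root == x else None


@dataclass(frozen=True)
class MPSNParams:
    """Parameter tuple of the network model.

    Attributes
    ----------
    n : total vertex count (positive perfect square).
    r : dispersal range in lattice units (positive).
    k : number of regions (positive perfect square; sqrt(k) divides sqrt(n)).
    s : locality size in vertices (positive perfect square; the locality side
        sqrt(s) must fit in the region side and share its parity so that
        centering is integral).
    template_kind : intra-locality template, one of {complete, star, custom}.
    epsilon : inter-locality edge-probability factor; each locality pair is an
        edge with probability min(1, epsilon / k).
    rng_seed : seed for the network random stream.
    """

    n: int
    r: float
    k: int
    s: int
    template_kind: str = "complete"
    epsilon: float = 1.0
    rng_seed: int = 0

    @property
    def side(self) -> int:
        return math.isqrt(self.n)

    @property
    def region_side(self) -> int:
        return self.side // max(math.isqrt(self.k), 1)

    @property
    def locality_side(self) -> int:
        return math.isqrt(self.s)

    @property
    def edge_probability(self) -> float:
        return min(1.0, self.epsilon / self.k)

    def with_seed(self, rng_seed: int) -> "MPSNParams":
        return replace(self, rng_seed=rng_seed)


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.valid


TEMPLATE_KINDS = ("complete", "star", "custom")


def validate_params(p: MPSNParams) -> ValidationResult:
    """Check every model invariant; returns a verdict, never raises.

    Invalid verdicts enumerate all violated rules, not just the first.
    """
    reasons: list[str] = []
    sqrt_n = _isqrt_exact(p.n) if p.n > 0 else None
    sqrt_k = _isqrt_exact(p.k) if p.k > 0 else None
    sqrt_s = _isqrt_exact(p.s) if p.s > 0 else None

    if p.n <= 0 or sqrt_n is None:
        reasons.append(f"n = {p.n} is not a positive perfect square")
    if p.k <= 0 or sqrt_k is None:
        reasons.append(f"k = {p.k} is not a positive perfect square")
    if p.s <= 0 or sqrt_s is None:
        reasons.append(f"s = {p.s} is not a positive perfect square")
    if p.r <= 0:
        reasons.append(f"range r = {p.r} must be positive")
    if p.epsilon < 0:
        reasons.append(f"epsilon = {p.epsilon} must be nonnegative")
    if p.template_kind not in TEMPLATE_KINDS:
        reasons.append(f"unknown template kind {p.template_kind!r}")

    if sqrt_n is not None and sqrt_k is not None:
        if sqrt_n % sqrt_k != 0:
            reasons.append(f"lattice side {sqrt_n} is not a multiple of sqrt(k) = {sqrt_k}")
        elif sqrt_s is not None:
            region_side = sqrt_n // sqrt_k
            if sqrt_s > region_side:
                reasons.append(f"locality side {sqrt_s} exceeds region side {region_side}")
            elif (region_side - sqrt_s) % 2 != 0:
                reasons.append(
                    f"locality side {sqrt_s} and region side {region_side} have unequal parity"
                )

    return ValidationResult(valid=not reasons, reasons=tuple(reasons))


def make_lattice(n: int) -> np.ndarray:
    """Integer coordinates of the ``n`` lattice vertices in row-major id order.

    Returns an ``(n, 2)`` array; vertex ``id`` has ``coord = (id // side,
    id % side)``, so the id <-> coord map is a bijection by construction.
    """
    side = _isqrt_exact(n)
    if n <= 0 or side is None:
        raise ValueError(f"n = {n} is not a positive perfect square")
    ids = np.arange(n)
    return np.column_stack((ids // side, ids % side))


@dataclass(frozen=True)
class LocalityMap:
    """Region/locality partition of the lattice.

    ``region_of[v]`` is the region index of every vertex; ``locality_of[v]``
    is the locality index or -1; ``members[l]`` lists the locality's vertices
    in row-major order within its subgrid.
    """

    region_of: np.ndarray
    locality_of: np.ndarray
    members: tuple[np.ndarray, ...]

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def s(self) -> int:
        return len(self.members[0]) if self.members else 0


def assign_localities(n: int, k: int, s: int) -> LocalityMap:
    """Tile ``k`` regions row-major and center one locality in each.

    The locality of each region is offset ``(region_side - sqrt(s)) / 2`` from
    the region's top-left corner in both axes; the parity invariant of the
    parameters guarantees the offset is integral.
    """
    verdict = validate_params(MPSNParams(n=n, r=1.0, k=k, s=s))
    if not verdict.valid:
        raise ValueError("; ".join(verdict.reasons))

    side = math.isqrt(n)
    sqrt_k = math.isqrt(k)
    sqrt_s = math.isqrt(s)
    region_side = side // sqrt_k
    offset = (region_side - sqrt_s) // 2

    coords = make_lattice(n)
    region_of = (coords[:, 0] // region_side) * sqrt_k + coords[:, 1] // region_side
    locality_of = np.full(n, -1, dtype=np.int64)
    members: list[np.ndarray] = []
    for loc in range(k):
        ri, rj = divmod(loc, sqrt_k)
        top, left = ri * region_side + offset, rj * region_side + offset
        rows = np.arange(top, top + sqrt_s)
        cols = np.arange(left, left + sqrt_s)
        ids = (rows[:, None] * side + cols[None, :]).ravel()  # row-major in the subgrid
        locality_of[ids] = loc
        members.append(ids)
    return LocalityMap(region_of=region_of, locality_of=locality_of, members=tuple(members))


def build_short_range(coords: np.ndarray, r: float) -> np.ndarray:
    """Short-range edges: pairs with squared Euclidean distance <= r^2.

    Membership is decided by the exact integer comparison
    ``di^2 + dj^2 <= r^2`` (left side integral, so no float ambiguity for the
    ranges used here).  Returns an ``(m, 2)`` array with ``u < v`` per row.
    """
    if r <= 0:
        raise ValueError(f"range r = {r} must be positive")
    n = len(coords)
    side = math.isqrt(n)
    r_sq = float(r) * float(r)
    max_d = int(math.floor(r))

    # Enumerate lexicographically-positive integer offsets inside the disk;
    # each offset applied to the full grid yields each undirected pair once.
    reach = min(max_d, side - 1)  # larger offsets cannot stay on the lattice
    offsets = [
        (di, dj)
        for di in range(0, reach + 1)
        for dj in range(-reach, reach + 1)
        if (di > 0 or dj > 0) and di * di + dj * dj <= r_sq
    ]
    ids = np.arange(n).reshape(side, side)
    chunks = []
    for di, dj in offsets:
        rows = slice(0, side - di)
        cols = slice(-dj, side) if dj < 0 else slice(0, side - dj)
        u = ids[rows, cols].ravel()
        chunks.append(np.column_stack((u, u + di * side + dj)))
    if not chunks:
        return np.empty((0, 2), dtype=np.int64)
    edges = np.concatenate(chunks)
    edges = np.sort(edges, axis=1)
    return edges[np.lexsort((edges[:, 1], edges[:, 0]))]


@dataclass(frozen=True)
class TemplateGraph:
    """Simple graph on ``s`` vertices indexed row-major on a sqrt(s) grid."""

    kind: str
    s: int
    edges: np.ndarray  # (m, 2), u < v

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_template(kind: str, s: int, edges: Sequence[tuple[int, int]] | None = None) -> TemplateGraph:
    """Build an intra-locality template: complete, star (hub at index 0), or custom."""
    if _isqrt_exact(s) is None or s <= 0:
        raise ValueError(f"template size s = {s} is not a positive perfect square")
    if kind == "complete":
        u, v = np.triu_indices(s, k=1)
        edge_arr = np.column_stack((u, v))
    elif kind == "star":
        edge_arr = np.column_stack((np.zeros(s - 1, dtype=np.int64), np.arange(1, s)))
    elif kind == "custom":
        edge_arr = np.asarray(list(edges or []), dtype=np.int64).reshape(-1, 2)
        if len(edge_arr):
            if edge_arr.min() < 0 or edge_arr.max() >= s:
                raise ValueError("custom template edge references a vertex index outside [0, s)")
            if np.any(edge_arr[:, 0] == edge_arr[:, 1]):
                raise ValueError("custom template contains a self-loop")
            edge_arr = np.unique(np.sort(edge_arr, axis=1), axis=0)
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    return TemplateGraph(kind=kind, s=s, edges=edge_arr.astype(np.int64))


def build_intra_locality(locality_map: LocalityMap, template: TemplateGraph) -> np.ndarray:
    """One disjoint isomorphic copy of the template per locality.

    The isomorphism maps template index ``i`` to the ``i``-th row-major member
    of each locality.
    """
    if locality_map.s != template.s:
        raise ValueError(
            f"template size {template.s} does not match locality size {locality_map.s}"
        )
    if template.n_edges == 0:
        return np.empty((0, 2), dtype=np.int64)
    chunks = [np.sort(members[template.edges], axis=1) for members in locality_map.members]
    edges = np.concatenate(chunks)
    return edges[np.lexsort((edges[:, 1], edges[:, 0]))]


@dataclass(frozen=True)
class InterLocalityGraph:
    """Simple graph on the ``k`` localities with nonnegative flow weights."""

    k: int
    edges: np.ndarray  # (m, 2), u < v
    weights: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        if len(self.edges) and (self.edges.min() < 0 or self.edges.max() >= self.k):
            raise ValueError("inter-locality edge references a locality index outside [0, k)")
        if np.any(self.weights < 0):
            raise ValueError("inter-locality flow weights must be nonnegative")

    @classmethod
    def from_edges(cls, k: int, edges: Iterable[tuple[int, int]], weights=None) -> "InterLocalityGraph":
        edge_arr = np.asarray(list(edges), dtype=np.int64).reshape(-1, 2)
        edge_arr = np.sort(edge_arr, axis=1)
        w = np.ones(len(edge_arr)) if weights is None else np.asarray(weights, dtype=float)
        return cls(k=k, edges=edge_arr, weights=w)


def sample_interlocality(k: int, epsilon: float, rng_seed: int) -> InterLocalityGraph:
    """Erdos-Renyi inter-locality graph with edge probability min(1, epsilon/k).

    Locality pairs are visited in lexicographic order with one uniform draw
    each, so the output is a pure function of ``(k, epsilon, rng_seed)``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    p = min(1.0, epsilon / k)
    u, v = np.triu_indices(k, k=1)  # row-major == lexicographic pair order
    rng = np.random.default_rng(rng_seed)
    keep = rng.random(len(u)) < p
    edges = np.column_stack((u[keep], v[keep]))
    return InterLocalityGraph(k=k, edges=edges, weights=np.ones(len(edges)))


LD_VARIANTS = ("definitional", "kronecker")


def build_long_distance(
    locality_map: LocalityMap,
    f_ld: InterLocalityGraph,
    variant: str = "definitional",
) -> tuple[np.ndarray, np.ndarray]:
    """Long-distance edges induced by the inter-locality graph.

    definitional
        every cross pair ``L_u x L_v`` per inter-locality edge (s^2 pairs);
    kronecker
        only cross pairs whose row-major template indices differ
        (s^2 - s pairs), i.e. the Kronecker product with a clique.

    Each vertex-level edge inherits the flow weight of its inter-locality
    edge.  Returns ``(edges, weights)``.
    """
    if variant not in LD_VARIANTS:
        raise ValueError(f"unknown long-distance variant {variant!r}")
    if f_ld.k != locality_map.k:
        raise ValueError(f"inter-locality graph has k = {f_ld.k}, locality map has k = {locality_map.k}")
    s = locality_map.s
    chunks, weight_chunks = [], []
    for (lu, lv), w in zip(f_ld.edges, f_ld.weights):
        mu, mv = locality_map.members[lu], locality_map.members[lv]
        iu, iv = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")
        if variant == "kronecker":
            mask = iu != iv
            iu, iv = iu[mask], iv[mask]
        pairs = np.column_stack((mu[iu.ravel()], mv[iv.ravel()]))
        chunks.append(np.sort(pairs, axis=1))
        weight_chunks.append(np.full(len(pairs), w))
    if not chunks:
        return np.empty((0, 2), dtype=np.int64), np.empty(0)
    edges = np.concatenate(chunks)
    weights = np.concatenate(weight_chunks)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    return edges[order], weights[order]


@dataclass(frozen=True)
class MultiPathwayGraph:
    """Labeled multigraph holding the three pathway layers of one instance."""

    params: MPSNParams
    coords: np.ndarray
    locality_map: LocalityMap
    template: TemplateGraph
    f_ld: InterLocalityGraph
    edges_s: np.ndarray
    edges_l: np.ndarray
    edges_ld: np.ndarray
    ld_weights: np.ndarray
    ld_variant: str = "definitional"

    @property
    def n(self) -> int:
        return len(self.coords)

    def layer_edges(self, label: PathwayLabel | str) -> np.ndarray:
        label = PathwayLabel(label)
        return {
            PathwayLabel.S: self.edges_s,
            PathwayLabel.L: self.edges_l,
            PathwayLabel.LD: self.edges_ld,
        }[label]

    def layer_weights(self, label: PathwayLabel | str) -> np.ndarray:
        label = PathwayLabel(label)
        if label is PathwayLabel.LD:
            return self.ld_weights
        return np.ones(len(self.layer_edges(label)))

    def edge_table(self) -> np.ndarray:
        """All labeled edges as a structured-ish object array (u, v, label, w)."""
        rows = []
        for label in PathwayLabel:
            edges = self.layer_edges(label)
            weights = self.layer_weights(label)
            for (u, v), w in zip(edges, weights):
                rows.append((int(u), int(v), label.value, float(w)))
        return np.array(rows, dtype=object)


def assemble(
    p: MPSNParams,
    template: TemplateGraph | None = None,
    f_ld: InterLocalityGraph | None = None,
    ld_variant: str = "definitional",
) -> MultiPathwayGraph:
    """Construct a full MPSN instance; pure function of (params, inputs).

    When ``f_ld`` is omitted it is sampled from the Erdos-Renyi model using
    the network stream seeded by ``p.rng_seed``.
    """
    verdict = validate_params(p)
    if not verdict.valid:
        raise ValueError("invalid parameters: " + "; ".join(verdict.reasons))

    coords = make_lattice(p.n)
    locality_map = assign_localities(p.n, p.k, p.s)
    if template is None:
        if p.template_kind == "custom":
            raise ValueError("custom template kind requires an explicit template")
        template = build_template(p.template_kind, p.s)
    if template.s != p.s:
        raise ValueError(f"template size {template.s} does not match s = {p.s}")
    if f_ld is None:
        f_ld = sample_interlocality(p.k, p.epsilon, p.rng_seed)

    edges_s = build_short_range(coords, p.r)
    edges_l = build_intra_locality(locality_map, template)
    edges_ld, ld_weights = build_long_distance(locality_map, f_ld, ld_variant)
    return MultiPathwayGraph(
        params=p,
        coords=coords,
        locality_map=locality_map,
        template=template,
        f_ld=f_ld,
        edges_s=edges_s,
        edges_l=edges_l,
        edges_ld=edges_ld,
        ld_weights=ld_weights,
        ld_variant=ld_variant,
    )
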