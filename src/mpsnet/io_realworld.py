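"""Graph file I/O and temporal directed weighted commodity-flow networks.

File dialect (all plain TSV):

* node table: columns ``id  i  j  region  locality`` (locality -1 when the
  vertex belongs to none);
* edge list: columns ``src  dst  pathway  weight`` with pathway in
  ``{S, L, LD}``, undirected edges written once with ``src < dst``;
* temporal networks: a node table ``id  x  y  group``, per-month edge tables
  ``src  dst  pathway  weight`` (or one long-format file with a ``month``
  column), a group-flow table ``src_group  dst_group  month  F`` and an
  infectivity table ``id  month  rho``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import cKDTree

from .graph_model import (
    InterLocalityGraph,
    LocalityMap,
    MPSNParams,
    MultiPathwayGraph,
    PathwayLabel,
    TemplateGraph,
    make_lattice,
)
from .structure import spectral_radius

__all__ = [
    "write_graph",
    "read_graph",
    "TemporalFlowNetwork",
    "MonthlyMatrices",
    "load_temporal_network",
    "write_temporal_network",
    "monthly_matrices",
    "temporal_profile",
    "synth_temporal_flow",
]

N_MONTHS = 12


# ---------------------------------------------------------------------------
# MPSN instance round trip


def write_graph(g: MultiPathwayGraph, prefix: str | Path) -> list[Path]:
    """Write ``<prefix>_nodes.tsv``, ``<prefix>_edges.tsv``, ``<prefix>_params.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {
            "id": np.arange(g.n),
            "i": g.coords[:, 0],
            "j": g.coords[:, 1],
            "region": g.locality_map.region_of,
            "locality": g.locality_map.locality_of,
        }
    )
    edge_frames = []
    for label in PathwayLabel:
        edges = g.layer_edges(label)
        if len(edges) == 0:
            continue
        edge_frames.append(
            pd.DataFrame(
                {
                    "src": edges[:, 0],
                    "dst": edges[:, 1],
                    "pathway": label.value,
                    "weight": g.layer_weights(label),
                }
            )
        )
    edges_df = (
        pd.concat(edge_frames, ignore_index=True)
        if edge_frames
        else pd.DataFrame(columns=["src", "dst", "pathway", "weight"])
    )
    meta = {
        "n": g.params.n,
        "r": g.params.r,
        "k": g.params.k,
        "s": g.params.s,
        "template_kind": g.params.template_kind,
        "epsilon": g.params.epsilon,
        "rng_seed": g.params.rng_seed,
        "ld_variant": g.ld_variant,
        "template_edges": g.template.edges.tolist(),
        "f_ld_edges": g.f_ld.edges.tolist(),
        "f_ld_weights": g.f_ld.weights.tolist(),
    }
    paths = [
        Path(f"{prefix}_nodes.tsv"),
        Path(f"{prefix}_edges.tsv"),
        Path(f"{prefix}_params.json"),
    ]
    nodes.to_csv(paths[0], sep="\t", index=False)
    edges_df.to_csv(paths[1], sep="\t", index=False)
    paths[2].write_text(json.dumps(meta, indent=1))
    return paths


def _parse_edge_file(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["src", "dst", "pathway", "weight"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    valid_labels = {label.value for label in PathwayLabel}
    for offset, row in enumerate(df.itertuples(index=False)):
        line = offset + 2  # 1-based, after the header
        if row.pathway not in valid_labels:
            raise ValueError(f"{path}:{line}: unknown pathway label {row.pathway!r}")
        if row.weight < 0:
            raise ValueError(f"{path}:{line}: negative weight {row.weight}")
    return df


def read_graph(prefix: str | Path) -> MultiPathwayGraph:
    """Inverse of :func:`write_graph`; validates rows and names bad lines."""
    prefix = Path(prefix)
    nodes = pd.read_csv(Path(f"{prefix}_nodes.tsv"), sep="\t")
    edges_df = _parse_edge_file(Path(f"{prefix}_edges.tsv"))
    meta = json.loads(Path(f"{prefix}_params.json").read_text())

    params = MPSNParams(
        n=meta["n"],
        r=meta["r"],
        k=meta["k"],
        s=meta["s"],
        template_kind=meta["template_kind"],
        epsilon=meta["epsilon"],
        rng_seed=meta["rng_seed"],
    )
    coords = nodes[["i", "j"]].to_numpy()
    locality_of = nodes["locality"].to_numpy()
    members = tuple(
        np.sort(np.flatnonzero(locality_of == loc)) for loc in range(params.k)
    )
    locality_map = LocalityMap(
        region_of=nodes["region"].to_numpy(),
        locality_of=locality_of,
        members=members,
    )
    template = TemplateGraph(
        kind=meta["template_kind"],
        s=params.s,
        edges=np.asarray(meta["template_edges"], dtype=np.int64).reshape(-1, 2),
    )
    f_ld = InterLocalityGraph(
        k=params.k,
        edges=np.asarray(meta["f_ld_edges"], dtype=np.int64).reshape(-1, 2),
        weights=np.asarray(meta["f_ld_weights"], dtype=float),
    )

    def _layer(label: str) -> np.ndarray:
        sub = edges_df[edges_df["pathway"] == label]
        return sub[["src", "dst"]].to_numpy(dtype=np.int64).reshape(-1, 2)

    ld = edges_df[edges_df["pathway"] == "LD"]
    return MultiPathwayGraph(
        params=params,
        coords=coords,
        locality_map=locality_map,
        template=template,
        f_ld=f_ld,
        edges_s=_layer("S"),
        edges_l=_layer("L"),
        edges_ld=_layer("LD"),
        ld_weights=ld["weight"].to_numpy(dtype=float),
        ld_variant=meta["ld_variant"],
    )


# ---------------------------------------------------------------------------
# Temporal directed weighted flow networks


@dataclass(frozen=True)
class TemporalFlowNetwork:
    """Twelve monthly snapshots of a directed weighted flow network.

    ``rho`` is an ``(n, 12)`` infectivity array; ``flows`` is a
    ``(12, g, g)`` array of directed inter-group flow weights; ``edges``
    optionally stores explicit per-month edge tables (src, dst, pathway,
    weight) as loaded from disk.
    """

    name: str
    node_ids: np.ndarray
    coords: np.ndarray  # (n, 2) float
    group_of: np.ndarray  # (n,), -1 for ungrouped nodes
    rho: np.ndarray  # (n, 12)
    flows: np.ndarray  # (12, g, g)
    edges: dict[int, pd.DataFrame] | None = None

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_groups(self) -> int:
        return self.flows.shape[1]

    def month_index(self, month: int) -> int:
        """1-based month, 12-periodic (month 13 == month 1)."""
        return (month - 1) % N_MONTHS

    def counts(self) -> dict:
        """Size report: nodes, groups, group edges, and edge counts.

        Edge counts are reported both as the union over months and per
        snapshot, since either convention may be the published one.
        """
        group_edges = int((self.flows.sum(axis=0) > 0).sum())
        report = {
            "nodes": int(self.n),
            "groups": int(self.n_groups),
            "group_edges": group_edges,
        }
        if self.edges:
            per_month = {m: len(df) for m, df in sorted(self.edges.items())}
            union = pd.concat(
                [df[["src", "dst", "pathway"]] for df in self.edges.values()], ignore_index=True
            ).drop_duplicates()
            report["edges_union"] = int(len(union))
            report["edges_per_month"] = per_month
        return report


@dataclass(frozen=True)
class MonthlyMatrices:
    """Weighted and binarized directed adjacency of one monthly snapshot."""

    weighted: sp.csr_matrix
    unweighted: sp.csr_matrix
    month: int
    r: float


def load_temporal_network(path: str | Path, dialect: str = "multi", name: str = "") -> TemporalFlowNetwork:
    """Load a temporal network directory.

    ``multi`` dialect expects ``nodes.tsv``, ``edges_month_<m>.tsv`` for m in
    1..12, ``group_flows.tsv``, and optionally ``rho.tsv``; the ``long``
    dialect replaces the per-month files with one ``edges.tsv`` holding a
    ``month`` column.
    """
    path = Path(path)
    nodes = pd.read_csv(path / "nodes.tsv", sep="\t")
    node_ids = nodes["id"].to_numpy()
    id_to_pos = {int(v): i for i, v in enumerate(node_ids)}
    coords = nodes[["x", "y"]].to_numpy(dtype=float)
    group_of = nodes["group"].to_numpy(dtype=np.int64)
    n_groups = int(group_of.max()) + 1 if (group_of >= 0).any() else 0

    if dialect == "multi":
        edges = {}
        for m in range(1, N_MONTHS + 1):
            f = path / f"edges_month_{m}.tsv"
            if not f.exists():
                raise FileNotFoundError(f"missing monthly edge table {f}")
            edges[m] = _parse_edge_file(f)
    elif dialect == "long":
        long_df = pd.read_csv(path / "edges.tsv", sep="\t")
        missing = {"src", "dst", "pathway", "weight", "month"} - set(long_df.columns)
        if missing:
            raise ValueError(f"long-format edge table is missing columns {sorted(missing)}")
        edges = {
            m: long_df[long_df["month"] == m][["src", "dst", "pathway", "weight"]].reset_index(drop=True)
            for m in range(1, N_MONTHS + 1)
        }
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for m, df in edges.items():
        for col in ("src", "dst"):
            unknown = set(df[col]) - set(id_to_pos)
            if unknown:
                raise ValueError(f"month {m}: undeclared node ids {sorted(unknown)[:5]}")

    flows = np.zeros((N_MONTHS, n_groups, n_groups))
    flow_file = path / "group_flows.tsv"
    if flow_file.exists():
        flow_df = pd.read_csv(flow_file, sep="\t")
        for row in flow_df.itertuples(index=False):
            flows[int(row.month) - 1, int(row.src_group), int(row.dst_group)] = float(row.F)

    rho = np.ones((len(node_ids), N_MONTHS))
    rho_file = path / "rho.tsv"
    if rho_file.exists():
        rho_df = pd.read_csv(rho_file, sep="\t")
        for row in rho_df.itertuples(index=False):
            rho[id_to_pos[int(row.id)], int(row.month) - 1] = float(row.rho)

    return TemporalFlowNetwork(
        name=name or path.name,
        node_ids=node_ids,
        coords=coords,
        group_of=group_of,
        rho=rho,
        flows=flows,
        edges=edges,
    )


def write_temporal_network(net: TemporalFlowNetwork, path: str | Path) -> None:
    """Write the ``multi`` dialect files for a temporal network."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "id": net.node_ids,
            "x": net.coords[:, 0],
            "y": net.coords[:, 1],
            "group": net.group_of,
        }
    ).to_csv(path / "nodes.tsv", sep="\t", index=False)
    edges = net.edges or {
        m: _derive_month_edges(net, m, r=1.0) for m in range(1, N_MONTHS + 1)
    }
    for m in range(1, N_MONTHS + 1):
        edges[m].to_csv(path / f"edges_month_{m}.tsv", sep="\t", index=False)
    flow_rows = []
    for m in range(N_MONTHS):
        src, dst = np.nonzero(net.flows[m])
        for a, b in zip(src, dst):
            flow_rows.append({"src_group": a, "dst_group": b, "month": m + 1, "F": net.flows[m, a, b]})
    pd.DataFrame(flow_rows, columns=["src_group", "dst_group", "month", "F"]).to_csv(
        path / "group_flows.tsv", sep="\t", index=False
    )
    rho_rows = [
        {"id": net.node_ids[i], "month": m + 1, "rho": net.rho[i, m]}
        for i in range(net.n)
        for m in range(N_MONTHS)
    ]
    pd.DataFrame(rho_rows).to_csv(path / "rho.tsv", sep="\t", index=False)


def _short_range_pairs(coords: np.ndarray, r: float) -> np.ndarray:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r, output_type="ndarray")
    return pairs.reshape(-1, 2)


def _derive_month_edges(net: TemporalFlowNetwork, month: int, r: float) -> pd.DataFrame:
    """Directed edge table of one month, rebuilt from coordinates and groups."""
    m = net.month_index(month)
    rho_m = net.rho[:, m]
    rows = []

    pairs = _short_range_pairs(net.coords, r)
    for u, v in pairs:
        rows.append((net.node_ids[u], net.node_ids[v], "S", rho_m[u]))
        rows.append((net.node_ids[v], net.node_ids[u], "S", rho_m[v]))

    for group in range(net.n_groups):
        members = np.flatnonzero(net.group_of == group)
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                rows.append((net.node_ids[u], net.node_ids[v], "L", rho_m[u]))
                rows.append((net.node_ids[v], net.node_ids[u], "L", rho_m[v]))

    src_groups, dst_groups = np.nonzero(net.flows[m])
    for ga, gb in zip(src_groups, dst_groups):
        f = net.flows[m, ga, gb]
        for u in np.flatnonzero(net.group_of == ga):
            for v in np.flatnonzero(net.group_of == gb):
                rows.append((net.node_ids[u], net.node_ids[v], "LD", rho_m[u] * f))
    return pd.DataFrame(rows, columns=["src", "dst", "pathway", "weight"])


def monthly_matrices(net: TemporalFlowNetwork, month: int, r: float) -> MonthlyMatrices:
    """Summed weighted adjacency of the three directed layers for one month.

    Short-range and intra-group edges carry weight ``rho(source, month)``;
    cross-group edges carry ``rho(source, month) * F(group(src), group(dst),
    month)``.  The unweighted matrix binarizes the support.
    """
    if not 1 <= ((month - 1) % N_MONTHS) + 1 <= N_MONTHS:  # pragma: no cover
        raise ValueError("month must be a positive integer")
    m = net.month_index(month)
    n = net.n
    rho_m = net.rho[:, m]

    src_list, dst_list, w_list = [], [], []

    pairs = _short_range_pairs(net.coords, r)
    if len(pairs):
        u, v = pairs[:, 0], pairs[:, 1]
        src_list += [u, v]
        dst_list += [v, u]
        w_list += [rho_m[u], rho_m[v]]

    for group in range(net.n_groups):
        members = np.flatnonzero(net.group_of == group)
        if len(members) < 2:
            continue
        iu, iv = np.triu_indices(len(members), k=1)
        u, v = members[iu], members[iv]
        src_list += [u, v]
        dst_list += [v, u]
        w_list += [rho_m[u], rho_m[v]]

    src_groups, dst_groups = np.nonzero(net.flows[m])
    for ga, gb in zip(src_groups, dst_groups):
        f = net.flows[m, ga, gb]
        mu = np.flatnonzero(net.group_of == ga)
        mv = np.flatnonzero(net.group_of == gb)
        if len(mu) == 0 or len(mv) == 0:
            continue
        uu, vv = np.meshgrid(mu, mv, indexing="ij")
        src_list.append(uu.ravel())
        dst_list.append(vv.ravel())
        w_list.append(rho_m[uu.ravel()] * f)

    if src_list:
        src = np.concatenate(src_list)
        dst = np.concatenate(dst_list)
        w = np.concatenate(w_list)
        keep = src != dst
        weighted = sp.coo_matrix((w[keep], (src[keep], dst[keep])), shape=(n, n)).tocsr()
    else:
        weighted = sp.csr_matrix((n, n))
    unweighted = weighted.copy()
    unweighted.data = (unweighted.data > 0).astype(float)
    unweighted.eliminate_zeros()
    return MonthlyMatrices(weighted=weighted, unweighted=unweighted, month=month, r=r)


def _directed_diameter(unweighted: sp.csr_matrix, strict: bool = False) -> tuple[float, float]:
    """(diameter, largest-component diameter) of the unweighted snapshot.

    Default treats the digraph as undirected (weak connectivity); strict mode
    keeps directions.  A disconnected graph reports inf alongside the
    largest-component value.
    """
    a = unweighted if strict else (unweighted + unweighted.T)
    n_comp, labels = connected_components(a, directed=strict, connection="strong" if strict else "weak")
    dist = shortest_path(a, method="D", directed=strict, unweighted=True)
    finite = dist[np.isfinite(dist)]
    largest = float(finite.max()) if len(finite) else 0.0
    if n_comp > 1:
        return math.inf, largest
    return largest, largest


def temporal_profile(net: TemporalFlowNetwork, r_values=(1.0, 2.0), strict_directed_diameter: bool = False) -> pd.DataFrame:
    """Weighted/unweighted spectral radius and diameter per month per range."""
    rows = []
    for r in r_values:
        for month in range(1, N_MONTHS + 1):
            mats = monthly_matrices(net, month, r)
            diam, diam_largest = _directed_diameter(mats.unweighted, strict=strict_directed_diameter)
            rows.append(
                {
                    "name": net.name,
                    "month": month,
                    "r": r,
                    "lambda1_weighted": spectral_radius(mats.weighted),
                    "lambda1_unweighted": spectral_radius(mats.unweighted),
                    "diameter": diam,
                    "diameter_largest_component": diam_largest,
                }
            )
    return pd.DataFrame(rows)


def synth_temporal_flow(
    n_nodes: int,
    n_groups: int,
    seasonality: float = 0.5,
    hub_concentration: float = 0.5,
    rng_seed: int = 0,
    production_fraction: float = 0.3,
    base_rho: float = 0.5,
    jitter: float = 0.2,
    flow_density: float = 0.5,
    name: str = "synthetic",
) -> TemporalFlowNetwork:
    """Synthetic temporal flow network emulating seasonal commodity trade.

    Nodes sit on a jittered lattice; groups are spatial clusters around
    ``n_groups`` centers; the infectivity of "production" nodes follows
    ``base + seasonality * max(0, sin(2 pi (m - phase)/12))``; outgoing
    inter-group flows concentrate on a few source groups as
    ``hub_concentration`` approaches 1.  Deterministic under ``rng_seed``.
    """
    if n_groups > n_nodes:
        raise ValueError("n_groups cannot exceed n_nodes")
    rng = np.random.default_rng(rng_seed)
    side = int(math.ceil(math.sqrt(n_nodes)))
    base_coords = np.array([(i // side, i % side) for i in range(n_nodes)], dtype=float)
    coords = base_coords + rng.uniform(-jitter, jitter, size=(n_nodes, 2))

    centers = coords[rng.choice(n_nodes, size=n_groups, replace=False)]
    dist_to_center = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
    group_of = dist_to_center.argmin(axis=1).astype(np.int64)

    producers = rng.random(n_nodes) < production_fraction
    phase = rng.integers(0, N_MONTHS, size=n_nodes)
    months = np.arange(N_MONTHS)
    seasonal = np.maximum(0.0, np.sin(2 * np.pi * (months[None, :] - phase[:, None]) / N_MONTHS))
    rho = np.full((n_nodes, N_MONTHS), base_rho)
    rho[producers] += seasonality * seasonal[producers]

    # Hub-concentrated flows: out-edges originate only from a few hub groups.
    # The support is drawn once, so months share edge structure; only the
    # weights breathe with the season (none at all when seasonality is 0).
    n_hubs = max(1, int(round((1 - hub_concentration) * n_groups))) if hub_concentration < 1 else 1
    hubs = rng.permutation(n_groups)[:n_hubs]
    base_flow = np.zeros((n_groups, n_groups))
    for ga in hubs:
        for gb in range(n_groups):
            if ga != gb and rng.random() < flow_density:
                base_flow[ga, gb] = rng.uniform(0.5, 2.0)
    group_phase = rng.integers(0, N_MONTHS, size=n_groups)
    flows = np.zeros((N_MONTHS, n_groups, n_groups))
    for m in range(N_MONTHS):
        factor = 1.0 + seasonality * np.maximum(
            0.0, np.sin(2 * np.pi * (m - group_phase) / N_MONTHS)
        )
        flows[m] = base_flow * factor[:, None]
    net = TemporalFlowNetwork(
        name=name,
        node_ids=np.arange(n_nodes),
        coords=coords,
        group_of=group_of,
        rho=rho,
        flows=flows,
        edges=None,
    )
    edges = {m: _derive_month_edges(net, m, r=1.0) for m in range(1, N_MONTHS + 1)}
    return replace(net, edges=edges)
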