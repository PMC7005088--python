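"""Randomized axon representative-volume (RV) geometry.

An RV is a cylindrical axon segment containing a hexagonally packed
microtubule (MT) bundle cross-linked by tau proteins, a neurofilament
(NF) network that fills the lumen and anchors the bundle to the cortex,
and a thin cortical shell tiled by quadrilateral facets on the lateral
surface.  Randomness enters only through the axial placement of MT
discontinuities (and the structural NF wiring, which is fixed per
configuration so that ensemble members differ *only* in discontinuity
placement).

Coordinate convention: the axon axis is +x, the cross-section lives in
(y, z), and all lengths are stored in micrometres.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RVConfig",
    "AxonRV",
    "SymmetrySpec",
    "generate_rv",
    "make_ensemble",
    "quarter_model",
    "hex_lattice",
]

#: node kind codes
KIND_CORTEX = 0
KIND_MT = 1


class GeometryError(ValueError):
    """Raised for invalid RV configurations or meshes."""


@dataclass(frozen=True)
class RVConfig:
    """Geometric parameters of an axon representative volume.

    Lengths are micrometres except ``cortex_thickness`` and
    ``tau_spacing`` which are nanometres.
    """

    length: float = 8.0
    diameter: float = 1.15
    n_mt_rows: int = 19
    discontinuities_per_row: int = 2
    mean_mt_length: float = 4.02
    cortex_thickness: float = 50.0  # nm
    n_axial: int = 24  # axial element count (mesh resolution)
    n_circ: int = 12   # circumferential element count
    nf_density: float = 600.0  # NF links per um^3 (lumen fill + anchor chains)
    tau_spacing: float = 990.0  # nm, axial spacing of tau cross-link stations
    mt_pitch: float | None = None  # um, hex lattice pitch; None -> auto
    nf_seed: int = 0  # structural wiring seed (shared across an ensemble)

    def __post_init__(self):
        if self.length <= 0:
            raise GeometryError("length must be > 0")
        if self.diameter <= 0:
            raise GeometryError("diameter must be > 0")
        if self.n_mt_rows < 1:
            raise GeometryError("n_mt_rows must be >= 1")
        if self.discontinuities_per_row < 0:
            raise GeometryError("discontinuities_per_row must be >= 0")
        if self.cortex_thickness <= 0:
            raise GeometryError("cortex_thickness must be > 0")
        if self.n_axial < 2 or self.n_circ < 3:
            raise GeometryError("mesh resolution too coarse")
        if self.discontinuities_per_row > self.n_axial - 1:
            raise GeometryError(
                "more discontinuities per row than removable mesh elements"
            )
        if self.n_mt_rows > 19:
            raise GeometryError("hex lattice supports at most 19 MT rows (3 rings)")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def dx(self) -> float:
        """Axial mesh spacing (um)."""
        return self.length / self.n_axial

    def periodic_mean_mt_length(self) -> float:
        """Mean continuous MT segment length when each row is counted as
        axially periodic: ``d`` gaps split the periodic row into ``d``
        segments, so the mean is ``length / d``."""
        d = max(1, self.discontinuities_per_row)
        return self.length / d


@dataclass(frozen=True)
class SymmetrySpec:
    """Quarter-symmetry bookkeeping.

    ``constraints`` is an (n, 2) int array of (node index, dof axis)
    pairs whose normal displacement is fixed to zero; axis is 1 for the
    z=0 plane (u_y is free, u_z... see below) -- concretely, axis is the
    *constrained* displacement component: nodes on the z=0 plane get
    axis 2 (u_z = 0), nodes on the y=0 plane get axis 1 (u_y = 0).
    """

    quadrant: str  # e.g. "+y+z"
    constraints: np.ndarray  # (n, 2) int: (node, axis)


@dataclass
class AxonRV:
    """A generated axon representative volume (node + element tables)."""

    config: RVConfig
    seed: int
    nodes: np.ndarray          # (N, 3) float, um
    node_kind: np.ndarray      # (N,) int8, KIND_CORTEX / KIND_MT
    mt_row_of_node: np.ndarray  # (N,) int32, -1 for cortex nodes
    mt_segments: np.ndarray    # (n_seg, 3) int32: (row, n1, n2)
    tau_links: np.ndarray      # (n, 2) int32 node pairs
    nf_links: np.ndarray       # (n, 2) int32
    anchor_links: np.ndarray   # (n, 2) int32
    anchor_mult: np.ndarray    # (n,) float: parallel NF-chain multiplicity
    cortex_quads: np.ndarray   # (nq, 4) int32, ordered (j,k),(j+1,k),(j+1,k+1),(j,k+1)
    discontinuities: np.ndarray  # (n_rows, d) float axial positions, um
    row_centers: np.ndarray    # (n_rows, 2) float (y, z), um
    meta: dict = field(default_factory=dict)

    # ---------------------------------------------------------------- helpers

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def rest_length(self, links: np.ndarray) -> np.ndarray:
        d = self.nodes[links[:, 1]] - self.nodes[links[:, 0]]
        return np.linalg.norm(d, axis=1)

    def all_links(self):
        """Yield (kind, links, mult) triples for every discrete link family."""
        yield "tau", self.tau_links, np.ones(len(self.tau_links))
        yield "nf", self.nf_links, np.ones(len(self.nf_links))
        yield "anchor", self.anchor_links, self.anchor_mult

    def connectivity_components(self) -> int:
        """Number of connected components of the element graph."""
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        pairs = [self.mt_segments[:, 1:3]]
        for _, links, _ in self.all_links():
            if len(links):
                pairs.append(links)
        q = self.cortex_quads
        pairs.append(np.stack([q[:, 0], q[:, 1]], axis=1))
        pairs.append(np.stack([q[:, 1], q[:, 2]], axis=1))
        pairs.append(np.stack([q[:, 2], q[:, 3]], axis=1))
        e = np.concatenate(pairs, axis=0)
        n = self.n_nodes
        m = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        ncomp, _ = connected_components(m, directed=False)
        return ncomp

    # ------------------------------------------------------------ serialization

    def to_dict(self) -> dict:
        d = {
            "config": dataclasses.asdict(self.config),
            "seed": int(self.seed),
            "nodes": self.nodes.tolist(),
            "node_kind": self.node_kind.tolist(),
            "mt_row_of_node": self.mt_row_of_node.tolist(),
            "mt_segments": self.mt_segments.tolist(),
            "tau_links": self.tau_links.tolist(),
            "nf_links": self.nf_links.tolist(),
            "anchor_links": self.anchor_links.tolist(),
            "anchor_mult": self.anchor_mult.tolist(),
            "cortex_quads": self.cortex_quads.tolist(),
            "discontinuities": self.discontinuities.tolist(),
            "row_centers": self.row_centers.tolist(),
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "AxonRV":
        cfg = RVConfig(**d["config"])
        return cls(
            config=cfg,
            seed=d["seed"],
            nodes=np.asarray(d["nodes"], dtype=float),
            node_kind=np.asarray(d["node_kind"], dtype=np.int8),
            mt_row_of_node=np.asarray(d["mt_row_of_node"], dtype=np.int32),
            mt_segments=np.asarray(d["mt_segments"], dtype=np.int32).reshape(-1, 3),
            tau_links=np.asarray(d["tau_links"], dtype=np.int32).reshape(-1, 2),
            nf_links=np.asarray(d["nf_links"], dtype=np.int32).reshape(-1, 2),
            anchor_links=np.asarray(d["anchor_links"], dtype=np.int32).reshape(-1, 2),
            anchor_mult=np.asarray(d["anchor_mult"], dtype=float),
            cortex_quads=np.asarray(d["cortex_quads"], dtype=np.int32).reshape(-1, 4),
            discontinuities=np.asarray(d["discontinuities"], dtype=float).reshape(
                cfg.n_mt_rows, -1
            ),
            row_centers=np.asarray(d["row_centers"], dtype=float).reshape(-1, 2),
        )

    @classmethod
    def from_json(cls, s: str) -> "AxonRV":
        return cls.from_dict(json.loads(s))


# --------------------------------------------------------------------------- #
# lattice and wiring
# --------------------------------------------------------------------------- #

def hex_lattice(n_rows: int, pitch: float) -> np.ndarray:
    """(y, z) centers of up to 19 MT rows on a centered hexagonal lattice
    (rings 0..2 give 1 + 6 + 12 = 19 sites), ordered center outwards."""
    pts = [(0.0, 0.0)]
    # ring 1: 6 sites at radius `pitch`
    for k in range(6):
        a = np.pi / 3 * k
        pts.append((pitch * np.cos(a), pitch * np.sin(a)))
    # ring 2: 6 corners at 2*pitch and 6 edge midpoints at sqrt(3)*pitch,
    # interleaved every 30 degrees
    for k in range(12):
        a = np.pi / 6 * k
        r = 2 * pitch if k % 2 == 0 else np.sqrt(3) * pitch
        pts.append((r * np.cos(a), r * np.sin(a)))
    return np.asarray(pts[:n_rows], dtype=float)


def _draw_discontinuities(rng: np.random.Generator, config: RVConfig) -> np.ndarray:
    """Uniform axial positions, redrawn so no two share a mesh element."""
    n_rows, d = config.n_mt_rows, config.discontinuities_per_row
    out = np.zeros((n_rows, d))
    if d == 0:
        return out
    for r in range(n_rows):
        while True:
            pos = rng.uniform(0.0, config.length, size=d)
            elems = np.minimum((pos / config.dx).astype(int), config.n_axial - 1)
            if len(np.unique(elems)) == d:
                break
        out[r] = np.sort(pos)
    return out


def generate_rv(config: RVConfig, seed: int) -> AxonRV:
    """Build one randomized RV.

    The ``seed`` drives only the discontinuity placement; the NF wiring
    is drawn from ``config.nf_seed`` so that ensemble members share one
    structural network.
    """
    if not isinstance(config, RVConfig):
        raise GeometryError("config must be an RVConfig")
    rng = np.random.default_rng(seed)

    L, R = config.length, config.radius
    n_ax, n_circ = config.n_axial, config.n_circ
    n_stations = n_ax + 1
    xs = np.linspace(0.0, L, n_stations)

    # --- cortex nodes: ring of n_circ nodes per axial station
    theta = 2 * np.pi * np.arange(n_circ) / n_circ
    cortex = np.zeros((n_stations * n_circ, 3))
    for j in range(n_stations):
        cortex[j * n_circ:(j + 1) * n_circ, 0] = xs[j]
        cortex[j * n_circ:(j + 1) * n_circ, 1] = R * np.cos(theta)
        cortex[j * n_circ:(j + 1) * n_circ, 2] = R * np.sin(theta)
    n_cortex = len(cortex)

    # --- MT rows on hex lattice; pitch sized so ring 2 stays inside cortex
    pitch = config.mt_pitch if config.mt_pitch is not None else 0.35 * R
    centers = hex_lattice(config.n_mt_rows, pitch)
    n_rows = config.n_mt_rows
    mt = np.zeros((n_rows * n_stations, 3))
    for r in range(n_rows):
        s = r * n_stations
        mt[s:s + n_stations, 0] = xs
        mt[s:s + n_stations, 1] = centers[r, 0]
        mt[s:s + n_stations, 2] = centers[r, 1]

    nodes = np.concatenate([cortex, mt], axis=0)
    node_kind = np.concatenate(
        [np.zeros(n_cortex, dtype=np.int8), np.ones(len(mt), dtype=np.int8)]
    )
    mt_row_of_node = np.full(len(nodes), -1, dtype=np.int32)
    for r in range(n_rows):
        mt_row_of_node[n_cortex + r * n_stations: n_cortex + (r + 1) * n_stations] = r

    def mtid(r, j):
        return n_cortex + r * n_stations + j

    def ctid(j, k):
        return j * n_circ + (k % n_circ)

    # --- MT segments minus discontinuity gaps
    disc = _draw_discontinuities(rng, config)
    segs = []
    for r in range(n_rows):
        gap_elems = set(
            np.minimum((disc[r] / config.dx).astype(int), n_ax - 1).tolist()
        ) if config.discontinuities_per_row else set()
        for j in range(n_ax):
            if j in gap_elems:
                continue
            segs.append((r, mtid(r, j), mtid(r, j + 1)))
    mt_segments = np.asarray(segs, dtype=np.int32).reshape(-1, 3)

    # --- tau cross-links between nearest-neighbour rows, diagonal in x so
    #     that axial shear is transferred in the linear regime
    dmat = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    pairs = [(a, b) for a in range(n_rows) for b in range(a + 1, n_rows)
             if dmat[a, b] <= 1.05 * pitch]
    stride = max(1, int(round((config.tau_spacing * 1e-3) / config.dx)))
    tau = []
    for (a, b) in pairs:
        for j in range(0, n_ax, stride):
            tau.append((mtid(a, j), mtid(b, j + 1)))
            tau.append((mtid(b, j), mtid(a, j + 1)))
    tau_links = np.asarray(tau, dtype=np.int32).reshape(-1, 2)

    # --- NF anchors: every cortex node to the angularly nearest outer-row
    #     MT node one axial station off (both diagonals where available).
    #     Multiplicity = number of parallel NF chains in the node's
    #     tributary lumen volume at the configured nf_density.
    lumen_volume = np.pi * R * R * L
    trib = lumen_volume / max(1, n_cortex)
    chains = max(1.0, round(config.nf_density * trib))
    outer_rows = _outermost_rows(centers)
    row_angles = np.arctan2(centers[outer_rows, 1], centers[outer_rows, 0])
    anchors = []
    amult = []
    for j in range(n_stations):
        for k in range(n_circ):
            ang = theta[k]
            dd = np.angle(np.exp(1j * (row_angles - ang)))
            r = outer_rows[int(np.argmin(np.abs(dd)))]
            tgt = []
            if j + 1 <= n_ax:
                tgt.append(mtid(r, j + 1))
            if j - 1 >= 0:
                tgt.append(mtid(r, j - 1))
            for t in tgt:
                anchors.append((ctid(j, k), t))
                amult.append(chains / len(tgt))
    anchor_links = np.asarray(anchors, dtype=np.int32).reshape(-1, 2)
    anchor_mult = np.asarray(amult, dtype=float)

    # --- lumen-filling NF links: random geometric graph on MT nodes,
    #     structural wiring seeded independently of the member seed
    nf_rng = np.random.default_rng(config.nf_seed)
    n_lumen = int(round(0.02 * config.nf_density * lumen_volume))
    nf = []
    n_mt_nodes = len(mt)
    cutoff = 3.0 * pitch + 2.0 * config.dx
    guard = 0
    while len(nf) < n_lumen and guard < 50 * max(1, n_lumen):
        guard += 1
        i = int(nf_rng.integers(n_mt_nodes))
        j = int(nf_rng.integers(n_mt_nodes))
        if i == j:
            continue
        a, b = n_cortex + i, n_cortex + j
        if np.linalg.norm(nodes[a] - nodes[b]) <= cutoff:
            nf.append((min(a, b), max(a, b)))
    nf_links = np.asarray(nf, dtype=np.int32).reshape(-1, 2)

    # --- cortex facets
    quads = []
    for j in range(n_ax):
        for k in range(n_circ):
            quads.append((ctid(j, k), ctid(j + 1, k),
                          ctid(j + 1, k + 1), ctid(j, k + 1)))
    cortex_quads = np.asarray(quads, dtype=np.int32)

    rv = AxonRV(
        config=config, seed=int(seed), nodes=nodes, node_kind=node_kind,
        mt_row_of_node=mt_row_of_node, mt_segments=mt_segments,
        tau_links=tau_links, nf_links=nf_links, anchor_links=anchor_links,
        anchor_mult=anchor_mult, cortex_quads=cortex_quads,
        discontinuities=disc, row_centers=centers,
        meta={"n_cortex_nodes": n_cortex, "n_stations": n_stations,
              "anchor_chains": chains},
    )
    return rv


def _outermost_rows(centers: np.ndarray) -> np.ndarray:
    """Indices of rows on the outermost occupied hex ring."""
    r = np.linalg.norm(centers, axis=1)
    rmax = r.max()
    if rmax == 0:
        return np.arange(len(centers))
    return np.flatnonzero(r >= 0.8 * rmax)


def make_ensemble(config: RVConfig, n: int, base_seed: int) -> list[AxonRV]:
    """n RVs sharing structure, differing only in discontinuity placement."""
    if n < 1:
        raise GeometryError("ensemble size must be >= 1")
    return [generate_rv(config, base_seed + i) for i in range(n)]


# --------------------------------------------------------------------------- #
# quarter symmetry
# --------------------------------------------------------------------------- #

def quarter_model(rv: AxonRV, tol: float = 1e-9) -> tuple[AxonRV, SymmetrySpec]:
    """Cut the RV to the (+y, +z) quadrant and emit symmetry constraints.

    Requires ``n_circ`` divisible by 4 so the cortex mesh splits exactly
    on the two symmetry planes.  MT rows whose centers fall outside the
    closed quadrant are dropped.
    """
    cfg = rv.config
    if cfg.n_circ % 4 != 0:
        raise GeometryError("cortex mesh not splittable: n_circ must be divisible by 4")

    keep = (rv.nodes[:, 1] >= -tol) & (rv.nodes[:, 2] >= -tol)
    old2new = np.full(rv.n_nodes, -1, dtype=np.int64)
    old2new[keep] = np.arange(int(keep.sum()))

    def remap(links):
        links = np.asarray(links).reshape(-1, links.shape[-1]) if len(links) else links
        if len(links) == 0:
            return links
        ok = keep[links].all(axis=1)
        return old2new[links[ok]].astype(np.int32), ok

    mt_ok = keep[rv.mt_segments[:, 1]] & keep[rv.mt_segments[:, 2]]
    mt_segments = rv.mt_segments[mt_ok].copy()
    mt_segments[:, 1] = old2new[mt_segments[:, 1]]
    mt_segments[:, 2] = old2new[mt_segments[:, 2]]

    tau_links, _ = remap(rv.tau_links) if len(rv.tau_links) else (rv.tau_links, None)
    nf_links, _ = remap(rv.nf_links) if len(rv.nf_links) else (rv.nf_links, None)
    if len(rv.anchor_links):
        ok = keep[rv.anchor_links].all(axis=1)
        anchor_links = old2new[rv.anchor_links[ok]].astype(np.int32)
        anchor_mult = rv.anchor_mult[ok]
    else:
        anchor_links, anchor_mult = rv.anchor_links, rv.anchor_mult

    # keep only facets wholly within the quadrant sector [0, pi/2]
    q = rv.cortex_quads
    ok = keep[q].all(axis=1)
    # exclude the facet bridging theta just below 0 (its k+1 wraps to 0)
    n_circ = cfg.n_circ
    k_of = q[:, 0] % n_circ
    ok &= k_of < n_circ // 4
    cortex_quads = old2new[q[ok]].astype(np.int32)

    nodes = rv.nodes[keep]
    spec_rows = []
    on_z0 = np.abs(nodes[:, 2]) <= tol
    on_y0 = np.abs(nodes[:, 1]) <= tol
    for i in np.flatnonzero(on_z0):
        spec_rows.append((i, 2))
    for i in np.flatnonzero(on_y0):
        spec_rows.append((i, 1))
    sym = SymmetrySpec(
        quadrant="+y+z",
        constraints=np.asarray(spec_rows, dtype=np.int64).reshape(-1, 2),
    )

    qrv = AxonRV(
        config=cfg, seed=rv.seed, nodes=nodes,
        node_kind=rv.node_kind[keep],
        mt_row_of_node=rv.mt_row_of_node[keep],
        mt_segments=mt_segments, tau_links=tau_links, nf_links=nf_links,
        anchor_links=anchor_links, anchor_mult=anchor_mult,
        cortex_quads=cortex_quads, discontinuities=rv.discontinuities,
        row_centers=rv.row_centers,
        meta=dict(rv.meta, quarter=True),
    )
    return qrv, sym
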