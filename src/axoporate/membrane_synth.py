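"""Synthetic coarse-grained membrane configurations.

Stands in for the CG-MD system: builds a two-leaflet bead configuration
at the axolemmal composition, embeds a channel footprint, plants pores,
interdigitation and core water with known ground truth, applies affine
strain, and fabricates surface-tension time series.  There is no force
field and no dynamics; the generator exists so the membrane metrics can
be exercised against planted truths.

Geometry convention: the bilayer slab is centred at z = Lz/2; the outer
leaflet occupies z above the midplane.  Coordinates are nm.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "LeafletComposition",
    "BeadConfiguration",
    "TensionSeries",
    "largest_remainder",
    "build_membrane",
    "embed_protein",
    "plant_pore",
    "plant_interdigitation",
    "set_core_water",
    "apply_strain",
    "synth_tension_series",
]

AVOGADRO = 6.02214076e23
#: CG water bead cutoff used to define "core" water (nm)
CORE_CUTOFF = 0.52
#: water molecules represented by one CG bead
WATERS_PER_BEAD = 4
#: bulk water concentration, mol/L
BULK_WATER = 55.5

OUTER_DEFAULT = {"PC": 0.36, "PE": 0.06, "CHOL": 0.31, "SM": 0.19,
                 "GM": 0.06, "OTHER": 0.02}
INNER_DEFAULT = {"PC": 0.17, "PE": 0.25, "CHOL": 0.29, "SM": 0.09,
                 "PS": 0.11, "PIP": 0.02, "OTHER": 0.07}

#: tail beads per lipid species (1 head bead each)
TAIL_BEADS = {"CHOL": 2, "GM": 4}
DEFAULT_TAILS = 3

HEAD_Z = 2.0     # |z - midplane| of head beads, nm
TAIL_Z_MIN = 0.5
TAIL_Z_MAX = 1.7
WATER_MARGIN = 0.2  # gap between head plane and solvent slab


class MembraneError(ValueError):
    pass


@dataclass(frozen=True)
class LeafletComposition:
    outer: dict = field(default_factory=lambda: dict(OUTER_DEFAULT))
    inner: dict = field(default_factory=lambda: dict(INNER_DEFAULT))

    def __post_init__(self):
        for name, frac in (("outer", self.outer), ("inner", self.inner)):
            total = sum(frac.values())
            if abs(total - 1.0) > 1e-9:
                raise MembraneError(f"{name} leaflet fractions sum to {total}, not 1")
            if any(v < 0 for v in frac.values()):
                raise MembraneError(f"{name} leaflet has a negative fraction")


@dataclass
class BeadConfiguration:
    """Flat bead table plus box and planted-truth metadata."""

    coords: np.ndarray        # (N, 3) nm
    kind: np.ndarray          # (N,) str: head|tail|water|ion|protein
    leaflet: np.ndarray       # (N,) str: outer|inner|none
    species: np.ndarray       # (N,) str lipid class or W/ION/PRO
    lipid_id: np.ndarray      # (N,) int, -1 for non-lipid beads
    box: np.ndarray           # (3,) nm
    waters_per_bead: int = WATERS_PER_BEAD
    protein: dict | None = None  # {"center": (x, y), "radius": r, "volume": nm^3}
    metadata: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def n_lipids(self) -> int:
        ids = self.lipid_id[self.lipid_id >= 0]
        return len(np.unique(ids))

    @property
    def midplane(self) -> float:
        return float(self.box[2]) / 2.0

    def select(self, **eq) -> np.ndarray:
        mask = np.ones(self.n_beads, dtype=bool)
        for k, v in eq.items():
            mask &= getattr(self, k) == v
        return mask

    def leaflet_fractions(self, leaflet: str) -> dict:
        m = self.select(kind="head", leaflet=leaflet)
        sp, counts = np.unique(self.species[m], return_counts=True)
        total = counts.sum()
        return {s: c / total for s, c in zip(sp, counts)}

    def copy(self) -> "BeadConfiguration":
        return BeadConfiguration(
            coords=self.coords.copy(), kind=self.kind.copy(),
            leaflet=self.leaflet.copy(), species=self.species.copy(),
            lipid_id=self.lipid_id.copy(), box=self.box.copy(),
            waters_per_bead=self.waters_per_bead,
            protein=dict(self.protein) if self.protein else None,
            metadata=dict(self.metadata),
        )


@dataclass
class TensionSeries:
    steps: np.ndarray    # strictly increasing ints
    gamma: np.ndarray    # surface tension, mN/m
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.steps = np.asarray(self.steps)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if np.any(np.diff(self.steps) <= 0):
            raise MembraneError("steps must be strictly increasing")
        if not np.all(np.isfinite(self.gamma)):
            raise MembraneError("surface tension values must be finite")


# --------------------------------------------------------------------------- #


def largest_remainder(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Integer counts summing to ``total`` via largest-remainder rounding."""
    keys = sorted(fractions)
    raw = np.array([fractions[k] * total for k in keys])
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return {k: int(c) for k, c in zip(keys, base)}


def _append(cfg_arrays, coords, kind, leaflet, species, lipid_id):
    cfg_arrays["coords"].append(coords)
    n = len(coords)
    cfg_arrays["kind"].append(np.full(n, kind, dtype=object))
    cfg_arrays["leaflet"].append(np.full(n, leaflet, dtype=object))
    cfg_arrays["species"].append(np.full(n, species, dtype=object))
    cfg_arrays["lipid_id"].append(np.full(n, lipid_id, dtype=int))


def build_membrane(comp: LeafletComposition | None = None,
                   box: tuple = (42.0, 42.0, 12.0),
                   n_lipids: int = 6700,
                   hydration_beads: int = 100_000,
                   salt_mM: float = 150.0,
                   seed: int = 0,
                   min_area_per_lipid: float = 0.35) -> BeadConfiguration:
    """Generate a two-leaflet bead configuration.

    Lipids split 50/50 by count between leaflets; species counts per
    leaflet follow largest-remainder rounding of the mole fractions.
    Head beads sit at the leaflet surfaces, tail beads between surface
    and midplane, water beads in the two solvent slabs, ion beads at the
    stated molarity.
    """
    comp = comp or LeafletComposition()
    box = np.asarray(box, dtype=float)
    if n_lipids < 2:
        raise MembraneError("need at least 2 lipids")
    n_outer = n_lipids // 2 + n_lipids % 2
    n_inner = n_lipids // 2
    area = box[0] * box[1]
    if area / max(n_outer, n_inner) < min_area_per_lipid:
        raise MembraneError(
            f"box too small: {area / max(n_outer, n_inner):.3f} nm^2/lipid "
            f"< {min_area_per_lipid} nm^2")

    rng = np.random.default_rng(seed)
    z0 = box[2] / 2.0
    arrays = {k: [] for k in ("coords", "kind", "leaflet", "species", "lipid_id")}
    lipid_counter = 0

    for leaflet, n_leaf, frac, sign in (
            ("outer", n_outer, comp.outer, +1.0),
            ("inner", n_inner, comp.inner, -1.0)):
        counts = largest_remainder(frac, n_leaf)
        labels = np.concatenate([np.full(c, s, dtype=object)
                                 for s, c in sorted(counts.items())])
        rng.shuffle(labels)
        # jittered grid in xy
        g = int(np.ceil(np.sqrt(n_leaf)))
        gx, gy = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
        cell = np.stack([gx.ravel(), gy.ravel()], axis=1)[:n_leaf]
        xy = (cell + 0.5 + rng.uniform(-0.3, 0.3, size=(n_leaf, 2))) \
            * (box[:2] / g)
        xy %= box[:2]
        for i in range(n_leaf):
            sp = str(labels[i])
            ntail = TAIL_BEADS.get(sp, DEFAULT_TAILS)
            zs_head = z0 + sign * HEAD_Z
            # tail depths drawn uniformly over the band so the leaflet
            # z-densities are continuous (not interleaved combs)
            rel = np.sort(rng.uniform(TAIL_Z_MIN, TAIL_Z_MAX, ntail))[::-1]
            zt = z0 + sign * rel
            pos = np.zeros((1 + ntail, 3))
            pos[:, 0] = xy[i, 0]
            pos[:, 1] = xy[i, 1]
            pos[0, 2] = zs_head
            pos[1:, 2] = zt
            pos[1:, :2] += rng.uniform(-0.1, 0.1, size=(ntail, 2))
            pos[:, :2] %= box[:2]
            _append(arrays, pos[:1], "head", leaflet, sp, lipid_counter)
            _append(arrays, pos[1:], "tail", leaflet, sp, lipid_counter)
            lipid_counter += 1

    # solvent slabs
    z_hi_min = z0 + HEAD_Z + WATER_MARGIN
    z_lo_max = z0 - HEAD_Z - WATER_MARGIN
    slab_hi = box[2] - z_hi_min
    slab_lo = z_lo_max
    vol_hi = area * slab_hi
    vol_lo = area * slab_lo
    n_hi = int(round(hydration_beads * vol_hi / (vol_hi + vol_lo)))
    n_lo = hydration_beads - n_hi
    for n_w, zlo, zhi in ((n_hi, z_hi_min, box[2]), (n_lo, 0.0, z_lo_max)):
        if n_w <= 0:
            continue
        w = np.empty((n_w, 3))
        w[:, 0] = rng.uniform(0, box[0], n_w)
        w[:, 1] = rng.uniform(0, box[1], n_w)
        w[:, 2] = rng.uniform(zlo, zhi, n_w)
        _append(arrays, w, "water", "none", "W", -1)

    # ions at the stated molarity over the solvent volume
    solvent_L = (vol_hi + vol_lo) * 1e-24
    n_ion = int(round(2 * salt_mM * 1e-3 * AVOGADRO * solvent_L))
    if n_ion > 0:
        w = np.empty((n_ion, 3))
        w[:, 0] = rng.uniform(0, box[0], n_ion)
        w[:, 1] = rng.uniform(0, box[1], n_ion)
        upper = rng.random(n_ion) < vol_hi / (vol_hi + vol_lo)
        w[:, 2] = np.where(upper,
                           rng.uniform(z_hi_min, box[2], n_ion),
                           rng.uniform(0.0, z_lo_max, n_ion))
        _append(arrays, w, "ion", "none", "ION", -1)

    cfg = BeadConfiguration(
        coords=np.concatenate(arrays["coords"]),
        kind=np.concatenate(arrays["kind"]),
        leaflet=np.concatenate(arrays["leaflet"]),
        species=np.concatenate(arrays["species"]),
        lipid_id=np.concatenate(arrays["lipid_id"]),
        box=box,
        metadata={"seed": int(seed), "n_lipids": int(n_lipids),
                  "salt_mM": float(salt_mM)},
    )
    return cfg


def _xy_periodic_dist(coords_xy, center, box_xy):
    d = np.abs(coords_xy - np.asarray(center))
    d = np.minimum(d, box_xy - d)
    return np.hypot(d[:, 0], d[:, 1])


def _remove_lipids_in_footprint(cfg: BeadConfiguration, center, radius):
    heads = cfg.select(kind="head")
    dist = _xy_periodic_dist(cfg.coords[:, :2], center, cfg.box[:2])
    doomed_ids = np.unique(cfg.lipid_id[heads & (dist <= radius)])
    doomed_ids = doomed_ids[doomed_ids >= 0]
    keep = ~np.isin(cfg.lipid_id, doomed_ids)
    return keep, len(doomed_ids)


def embed_protein(config: BeadConfiguration, footprint_radius: float,
                  center: tuple | None = None) -> BeadConfiguration:
    """Carve a transmembrane cylinder and fill it with protein beads."""
    if footprint_radius < 0:
        raise MembraneError("footprint radius must be >= 0")
    if 2 * footprint_radius > min(config.box[0], config.box[1]):
        raise MembraneError("footprint larger than box")
    cfg = config.copy()
    if footprint_radius == 0:
        cfg.protein = {"center": center, "radius": 0.0, "volume": 0.0}
        return cfg
    center = center or (cfg.box[0] / 2, cfg.box[1] / 2)
    keep, n_removed = _remove_lipids_in_footprint(cfg, center, footprint_radius)

    z0 = cfg.midplane
    z_lo, z_hi = z0 - HEAD_Z, z0 + HEAD_Z
    spacing = 0.5
    r_grid = np.arange(0, footprint_radius + 1e-9, spacing)
    pts = []
    for r in r_grid:
        n_ang = max(1, int(np.ceil(2 * np.pi * r / spacing)))
        ang = 2 * np.pi * np.arange(n_ang) / n_ang
        for z in np.arange(z_lo, z_hi + 1e-9, spacing):
            pts.append(np.stack([center[0] + r * np.cos(ang),
                                 center[1] + r * np.sin(ang),
                                 np.full(n_ang, z)], axis=1))
    prot = np.concatenate(pts)
    prot[:, :2] %= cfg.box[:2]

    volume = np.pi * footprint_radius ** 2 * (z_hi - z_lo)
    new = BeadConfiguration(
        coords=np.concatenate([cfg.coords[keep], prot]),
        kind=np.concatenate([cfg.kind[keep],
                             np.full(len(prot), "protein", dtype=object)]),
        leaflet=np.concatenate([cfg.leaflet[keep],
                                np.full(len(prot), "none", dtype=object)]),
        species=np.concatenate([cfg.species[keep],
                                np.full(len(prot), "PRO", dtype=object)]),
        lipid_id=np.concatenate([cfg.lipid_id[keep],
                                 np.full(len(prot), -1, dtype=int)]),
        box=cfg.box.copy(), waters_per_bead=cfg.waters_per_bead,
        protein={"center": tuple(center), "radius": float(footprint_radius),
                 "volume": float(volume)},
        metadata=dict(cfg.metadata, protein_removed_lipids=int(n_removed)),
    )
    return new


def plant_pore(config: BeadConfiguration, radius: float,
               seed: int = 0) -> BeadConfiguration:
    """Clear a transmembrane cylinder and fill it with a water column."""
    if radius < 0:
        raise MembraneError("pore radius must be >= 0")
    if radius > min(config.box[0], config.box[1]) / 2:
        raise MembraneError("pore radius exceeds half the box")
    cfg = config.copy()
    if radius == 0:
        return cfg
    rng = np.random.default_rng(seed)
    center = (cfg.box[0] / 2, cfg.box[1] / 2)
    keep, n_removed = _remove_lipids_in_footprint(cfg, center, radius)

    z0 = cfg.midplane
    spacing = 0.4
    zcol = np.arange(z0 - HEAD_Z - 0.4, z0 + HEAD_Z + 0.4 + 1e-9, spacing)
    pts = []
    for r in np.arange(0, radius, spacing):
        n_ang = max(1, int(np.ceil(2 * np.pi * r / spacing)))
        ang = 2 * np.pi * np.arange(n_ang) / n_ang + rng.uniform(0, 0.1)
        for z in zcol:
            pts.append(np.stack([center[0] + r * np.cos(ang),
                                 center[1] + r * np.sin(ang),
                                 np.full(n_ang, z)], axis=1))
    col = np.concatenate(pts)
    col[:, :2] %= cfg.box[:2]

    new = BeadConfiguration(
        coords=np.concatenate([cfg.coords[keep], col]),
        kind=np.concatenate([cfg.kind[keep],
                             np.full(len(col), "water", dtype=object)]),
        leaflet=np.concatenate([cfg.leaflet[keep],
                                np.full(len(col), "none", dtype=object)]),
        species=np.concatenate([cfg.species[keep],
                                np.full(len(col), "W", dtype=object)]),
        lipid_id=np.concatenate([cfg.lipid_id[keep],
                                 np.full(len(col), -1, dtype=int)]),
        box=cfg.box.copy(), waters_per_bead=cfg.waters_per_bead,
        protein=dict(cfg.protein) if cfg.protein else None,
        metadata=dict(cfg.metadata,
                      pore={"center": center, "radius": float(radius),
                            "removed_lipids": int(n_removed),
                            "column_beads": int(len(col))}),
    )
    return new


def plant_interdigitation(config: BeadConfiguration,
                          depth: float) -> BeadConfiguration:
    """Stretch each leaflet's tails toward/past the midplane.

    The terminal (deepest) tail bead moves the full ``depth`` toward the
    opposing leaflet while beads near the headgroup stay put, so the
    tail distributions increasingly overlap as ``depth`` grows (monotone
    over the whole sweep, unlike a rigid translation, which would pass
    the leaflets through each other).
    """
    if not (0 <= depth < HEAD_Z):
        raise MembraneError("depth must lie in [0, bilayer half-thickness)")
    cfg = config.copy()
    z0 = cfg.midplane
    span = TAIL_Z_MAX - TAIL_Z_MIN
    for leaflet, sign in (("outer", +1.0), ("inner", -1.0)):
        m = cfg.select(kind="tail", leaflet=leaflet)
        rel = sign * (cfg.coords[m, 2] - z0)  # distance above midplane
        weight = np.clip((TAIL_Z_MAX - rel) / span, 0.0, 1.0)
        cfg.coords[m, 2] -= sign * depth * weight
    cfg.metadata = dict(cfg.metadata, interdigitation_depth=float(depth))
    return cfg


def membrane_volume_nm3(config: BeadConfiguration) -> float:
    """Slab volume between the leaflet head surfaces, protein-corrected."""
    outer = config.select(kind="head", leaflet="outer")
    inner = config.select(kind="head", leaflet="inner")
    if not outer.any() or not inner.any():
        raise MembraneError("both leaflets must be present")
    z_hi = config.coords[outer, 2].mean()
    z_lo = config.coords[inner, 2].mean()
    vol = config.box[0] * config.box[1] * (z_hi - z_lo)
    if config.protein:
        vol -= config.protein.get("volume", 0.0)
    if vol <= 0:
        raise MembraneError("non-positive membrane volume")
    return float(vol)


def set_core_water(config: BeadConfiguration, target_log_k: float,
                   seed: int = 0) -> BeadConfiguration:
    """Move bulk water beads into the hydrophobic core so the membrane
    water concentration equals ``10**target_log_k * 55.5`` mol/L.

    Placement puts each moved bead within the core cutoff of a tail
    bead, so the partition estimator recovers the planted value up to
    one bead's quantization.
    """
    cfg = config.copy()
    vol_L = membrane_volume_nm3(cfg) * 1e-24
    if np.isneginf(target_log_k):
        n_needed = 0
    else:
        conc = 10.0 ** target_log_k * BULK_WATER
        n_molecules = conc * AVOGADRO * vol_L
        n_needed = int(round(n_molecules / cfg.waters_per_bead))

    rng = np.random.default_rng(seed)
    waters = np.flatnonzero(cfg.kind == "water")
    tails = np.flatnonzero(cfg.kind == "tail")
    if len(tails) == 0:
        raise MembraneError("no tail beads")
    if n_needed > len(waters):
        raise MembraneError("target core-water count exceeds available beads")

    movers = waters[:n_needed]
    hosts = tails[rng.integers(0, len(tails), size=n_needed)]
    offs = rng.normal(size=(n_needed, 3))
    offs /= np.linalg.norm(offs, axis=1, keepdims=True)
    offs *= rng.uniform(0.05, 0.45, size=(n_needed, 1))
    cfg.coords[movers] = (cfg.coords[hosts] + offs) % cfg.box
    cfg.metadata = dict(cfg.metadata,
                        planted_log_k=float(target_log_k),
                        core_water_beads=int(n_needed))
    return cfg


def apply_strain(config: BeadConfiguration, eps_x: float,
                 eps_y: float = 0.0) -> BeadConfiguration:
    """Affine in-plane stretch; z coordinates and Lz untouched."""
    if eps_x <= -1 or eps_y <= -1:
        raise MembraneError("strains must exceed -1")
    cfg = config.copy()
    cfg.coords[:, 0] *= (1 + eps_x)
    cfg.coords[:, 1] *= (1 + eps_y)
    cfg.box = cfg.box * np.array([1 + eps_x, 1 + eps_y, 1.0])
    areal = (1 + eps_x) * (1 + eps_y) - 1
    cfg.metadata = dict(cfg.metadata, eps_x=float(eps_x), eps_y=float(eps_y),
                        areal_strain=float(areal))
    return cfg


def synth_tension_series(K_A: float,
                         areal_strain_schedule: np.ndarray,
                         noise_sd: float = 0.0,
                         pore_step: int | None = None,
                         post_pore_drop: float = 0.0,
                         seed: int = 0) -> TensionSeries:
    """gamma(step) = K_A * eps_A(step) + noise, with an optional planted
    tension drop from ``pore_step`` onward."""
    if K_A <= 0:
        raise MembraneError("K_A must be > 0")
    eps = np.asarray(areal_strain_schedule, dtype=float)
    rng = np.random.default_rng(seed)
    gamma = K_A * eps
    if noise_sd > 0:
        gamma = gamma + rng.normal(0.0, noise_sd, size=len(eps))
    meta = {"K_A": float(K_A), "noise_sd": float(noise_sd)}
    if pore_step is not None:
        if not (0 <= pore_step < len(eps)):
            raise MembraneError("pore_step outside schedule")
        gamma[pore_step:] -= post_pore_drop
        meta["pore_step"] = int(pore_step)
        meta["post_pore_drop"] = float(post_pore_drop)
    return TensionSeries(steps=np.arange(len(eps)), gamma=gamma, metadata=meta)
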