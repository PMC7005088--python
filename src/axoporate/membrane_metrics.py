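"""Membrane-level analyses.

Area compressibility fit (through-origin, 5-block error), pore
detection (surface-tension jump and geometric water-column search),
interdigitation index, water partition coefficient and the derived
permeability change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .membrane_synth import (
    AVOGADRO,
    BULK_WATER,
    CORE_CUTOFF,
    BeadConfiguration,
    MembraneError,
    TensionSeries,
    membrane_volume_nm3,
)

__all__ = [
    "PartitionResult",
    "PoreCall",
    "CompressibilityFit",
    "fit_area_compressibility",
    "detect_tension_jump",
    "detect_pore_geometric",
    "interdigitation_index",
    "partition_coefficient",
    "permeability_change",
]


@dataclass
class PartitionResult:
    core_water_molecules: int
    membrane_volume_L: float
    conc_mem: float        # mol/L
    K: float               # K_mem/water
    log10_K: float         # -inf when K == 0

    def __post_init__(self):
        if self.K < 0 or self.membrane_volume_L <= 0:
            raise ValueError("invalid partition result")


@dataclass
class PoreCall:
    method: str            # "tension_jump" | "geometric"
    positive: bool
    location: object = None   # step index or (x, y) centre
    magnitude: float | None = None  # drop (mN/m) or radius (nm)

    def __post_init__(self):
        if self.positive and (self.location is None or self.magnitude is None):
            raise ValueError("positive call requires location and magnitude")


@dataclass
class CompressibilityFit:
    K_A: float             # mN/m
    se: float              # 5-block standard error, mN/m
    n: int                 # usable pairs
    strain_range: tuple


MAX_FIT_STRAIN = 0.05
N_BLOCKS = 5


def fit_area_compressibility(pairs) -> CompressibilityFit:
    """Through-origin slope of surface tension vs areal strain.

    Pairs with areal strain >= 0.05 are excluded; the error is the
    standard deviation of the five contiguous-block slopes over
    sqrt(5).
    """
    arr = np.asarray(list(pairs), dtype=float).reshape(-1, 2)
    eps, gamma = arr[:, 0], arr[:, 1]
    use = eps < MAX_FIT_STRAIN
    eps, gamma = eps[use], gamma[use]
    if len(eps) < N_BLOCKS:
        raise MembraneError(
            f"need at least {N_BLOCKS} pairs below strain {MAX_FIT_STRAIN}")
    denom = float(np.dot(eps, eps))
    if denom == 0:
        raise MembraneError("all strains are zero")
    slope = float(np.dot(eps, gamma) / denom)
    blocks = np.array_split(np.arange(len(eps)), N_BLOCKS)
    bslopes = []
    for b in blocks:
        d = float(np.dot(eps[b], eps[b]))
        bslopes.append(np.dot(eps[b], gamma[b]) / d if d > 0 else slope)
    se = float(np.std(bslopes, ddof=1) / np.sqrt(N_BLOCKS))
    return CompressibilityFit(K_A=slope, se=se, n=len(eps),
                              strain_range=(float(eps.min()), float(eps.max())))


def detect_tension_jump(series: TensionSeries,
                        min_drop: float | None = None,
                        window: int = 50) -> PoreCall:
    """Pore call from a sustained surface-tension drop.

    The statistic at step i is mean(gamma[i-w:i]) - mean(gamma[i:i+w]);
    the call is positive when the maximum exceeds ``min_drop`` (default
    five times the leading-window noise sd) and the reported location is
    the maximizing step.
    """
    g = series.gamma
    n = len(g)
    if window >= n / 2:
        raise MembraneError("window must be shorter than half the series")
    if min_drop is None:
        lead = g[:window]
        # noise estimate robust to the deterministic ramp: sd of first
        # differences over sqrt(2)
        min_drop = 5.0 * float(np.std(np.diff(lead)) / np.sqrt(2.0))
        min_drop = max(min_drop, 1e-12)
    c = np.cumsum(np.insert(g, 0, 0.0))
    idx = np.arange(window, n - window + 1)
    before = (c[idx] - c[idx - window]) / window
    after = (c[idx + window] - c[idx]) / window
    drop = before - after
    k = int(np.argmax(drop))
    if drop[k] > min_drop:
        return PoreCall(method="tension_jump", positive=True,
                        location=int(idx[k]), magnitude=float(drop[k]))
    return PoreCall(method="tension_jump", positive=False)


def detect_pore_geometric(config: BeadConfiguration,
                          grid: float = 0.5) -> PoreCall:
    """Pore call from a 26-connected water-voxel path crossing the
    hydrophobic core band; magnitude is the equivalent circular radius
    of the crossing column at the midplane."""
    if grid > min(config.box[:2]) / 4:
        raise MembraneError("grid coarser than box/4")
    tails = config.select(kind="tail")
    if not tails.any():
        raise MembraneError("configuration has no tail beads")
    z0 = config.midplane
    tz = config.coords[tails, 2]
    half = float(np.mean(np.abs(tz - z0)))
    band_lo, band_hi = z0 - half, z0 + half

    waters = config.coords[config.select(kind="water")]
    if len(waters) == 0:
        return PoreCall(method="geometric", positive=False)
    nx = max(1, int(np.ceil(config.box[0] / grid)))
    ny = max(1, int(np.ceil(config.box[1] / grid)))
    nz = max(1, int(np.ceil(config.box[2] / grid)))
    ii = np.minimum((waters[:, 0] % config.box[0] / grid).astype(int), nx - 1)
    jj = np.minimum((waters[:, 1] % config.box[1] / grid).astype(int), ny - 1)
    kk = np.minimum((waters[:, 2] % config.box[2] / grid).astype(int), nz - 1)
    occ = np.zeros((nx, ny, nz), dtype=bool)
    occ[ii, jj, kk] = True

    labels, n_lab = ndimage.label(occ, structure=np.ones((3, 3, 3)))
    if n_lab == 0:
        return PoreCall(method="geometric", positive=False)
    k_lo = int(band_lo / grid)
    k_hi = min(int(band_hi / grid), nz - 1)
    k_mid = int(z0 / grid)
    for lab in range(1, n_lab + 1):
        where = labels == lab
        ks = np.flatnonzero(where.any(axis=(0, 1)))
        if ks.min() <= k_lo and ks.max() >= k_hi:
            mid = where[:, :, min(max(k_mid, 0), nz - 1)]
            area = mid.sum() * grid * grid
            r = float(np.sqrt(area / np.pi))
            iy, jy = np.nonzero(mid)
            cx = float((iy.mean() + 0.5) * grid) if len(iy) else None
            cy = float((jy.mean() + 0.5) * grid) if len(jy) else None
            return PoreCall(method="geometric", positive=True,
                            location=(cx, cy), magnitude=r)
    return PoreCall(method="geometric", positive=False)


def interdigitation_index(config: BeadConfiguration,
                          bin_width: float = 0.1) -> float:
    """Overlap coefficient of the leaflets' tail z-density histograms.

    0 for fully separated tails, 1 for identical distributions.
    """
    outer = config.coords[config.select(kind="tail", leaflet="outer"), 2]
    inner = config.coords[config.select(kind="tail", leaflet="inner"), 2]
    if len(outer) == 0 or len(inner) == 0:
        raise MembraneError("both leaflets must contribute tail beads")
    lo = min(outer.min(), inner.min())
    hi = max(outer.max(), inner.max())
    edges = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    p, _ = np.histogram(outer, bins=edges)
    q, _ = np.histogram(inner, bins=edges)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.minimum(p, q).sum())


def partition_coefficient(config: BeadConfiguration,
                          cutoff: float = CORE_CUTOFF,
                          bulk: float = BULK_WATER) -> PartitionResult:
    """Water partition coefficient K_mem/water.

    Core waters are water beads within ``cutoff`` of any tail bead
    (periodic minimum-image distances); each bead counts as
    ``waters_per_bead`` molecules.  The membrane volume is the slab
    between the leaflet head surfaces minus any protein volume.
    """
    tails = np.flatnonzero(config.select(kind="tail"))
    if len(tails) == 0:
        raise MembraneError("configuration has no tail beads")
    vol_L = membrane_volume_nm3(config) * 1e-24

    waters = np.flatnonzero(config.select(kind="water"))
    if len(waters):
        box = config.box
        tree = cKDTree(config.coords[tails] % box, boxsize=box)
        d, _ = tree.query(config.coords[waters] % box,
                          distance_upper_bound=cutoff)
        n_core = int(np.sum(np.isfinite(d)))
    else:
        n_core = 0
    molecules = n_core * config.waters_per_bead
    conc = molecules / (AVOGADRO * vol_L)
    K = conc / bulk
    logK = float(np.log10(K)) if K > 0 else float("-inf")
    return PartitionResult(core_water_molecules=molecules,
                           membrane_volume_L=vol_L, conc_mem=conc,
                           K=K, log10_K=logK)


def permeability_change(result: PartitionResult,
                        reference: PartitionResult) -> float:
    """Relative permeability change, percent.

    log Pm is proportional to log K with proportionality constant 1
    here, so relative K changes are reported as relative Pm changes.
    """
    if reference.K <= 0:
        raise MembraneError("reference partition coefficient must be > 0")
    return (result.K / reference.K - 1.0) * 100.0
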