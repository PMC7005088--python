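"""Green-Lagrange strain extraction on the cortical shell.

Per-facet in-plane strain tensors are computed from reference and
deformed facet coordinates in the facet's local tangent frame, reduced
to principal values, and aggregated into max-strain curves, ensemble
statistics, iso-strain tables and a material sensitivity scan.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .axon_geometry import AxonRV
from .axon_mechanics import LoadCase, MaterialTable, MechTrajectory, run_stretch

__all__ = [
    "StrainCurve",
    "EnsembleCurve",
    "green_lagrange",
    "principal_strains",
    "facet_strain_field",
    "max_strain_curve",
    "ensemble_stats",
    "iso_strain",
    "sensitivity_scan",
]


@dataclass
class StrainCurve:
    """Max in-plane principal cortex strain versus applied axonal strain."""

    rate: float
    eps_axon: np.ndarray   # strictly increasing grid
    eps_x: np.ndarray      # max 1st principal Green-Lagrange strain
    eps_y: np.ndarray      # 2nd principal strain at the argmax facet
    fields: list | None = None  # optional per-snapshot (n_facet, 2) principal values

    def __post_init__(self):
        self.eps_axon = np.asarray(self.eps_axon, dtype=float)
        self.eps_x = np.asarray(self.eps_x, dtype=float)
        self.eps_y = np.asarray(self.eps_y, dtype=float)
        if np.any(np.diff(self.eps_axon) <= 0):
            raise ValueError("eps_axon grid must be strictly increasing")
        if np.any(self.eps_x + 1e-12 < self.eps_y):
            raise ValueError("eps_x must dominate eps_y")


@dataclass
class EnsembleCurve:
    rate: float
    eps_axon: np.ndarray
    mean_eps_x: np.ndarray
    sd_eps_x: np.ndarray
    mean_eps_y: np.ndarray
    n_members: int


def green_lagrange(reference_facet: np.ndarray,
                   deformed_facet: np.ndarray) -> np.ndarray:
    """In-plane Green-Lagrange tensor E = (F^T F - I)/2 of a triangle.

    Both arguments are (3, 3) vertex coordinate arrays.  The deformation
    gradient maps the reference edge vectors, expressed in the reference
    tangent frame, onto the deformed edges in the deformed tangent
    frame; E is invariant to the frame choices and to rigid motion.
    """
    p = np.asarray(reference_facet, dtype=float)
    q = np.asarray(deformed_facet, dtype=float)
    if p.shape != (3, 3) or q.shape != (3, 3):
        raise ValueError("facets must be (3, 3) vertex arrays")

    def frame(coords):
        e1 = coords[1] - coords[0]
        n = np.cross(e1, coords[2] - coords[0])
        a2 = np.linalg.norm(n)
        if a2 <= 1e-300:
            raise ValueError("degenerate (zero-area) facet")
        e1 = e1 / np.linalg.norm(e1)
        e3 = n / a2
        return np.stack([e1, np.cross(e3, e1)])  # (2, 3)

    Tp = frame(p)
    Tq = frame(q)
    A = Tp @ np.stack([p[1] - p[0], p[2] - p[0]], axis=1)  # (2,2) ref edges
    G = Tq @ np.stack([q[1] - q[0], q[2] - q[0]], axis=1)
    F = G @ np.linalg.inv(A)
    return 0.5 * (F.T @ F - np.eye(2))


def principal_strains(tensor: np.ndarray) -> tuple[float, float]:
    """Sorted eigenvalues (e1 >= e2) of a symmetric 2x2 tensor."""
    t = np.asarray(tensor, dtype=float)
    m = 0.5 * (t[0, 0] + t[1, 1])
    r = np.hypot(0.5 * (t[0, 0] - t[1, 1]), 0.5 * (t[0, 1] + t[1, 0]))
    return m + r, m - r


def _tri_strains(X: np.ndarray, x: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Vectorized per-triangle principal GL strains -> (n_tris, 2)."""
    out = np.zeros((len(tris), 2))
    P = X[tris]  # (n,3,3)
    Q = x[tris]

    def frames(Pc):
        e1 = Pc[:, 1] - Pc[:, 0]
        n = np.cross(e1, Pc[:, 2] - Pc[:, 0])
        a2 = np.linalg.norm(n, axis=1, keepdims=True)
        e1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        e3 = n / a2
        e2 = np.cross(e3, e1)
        return np.stack([e1, e2], axis=1)  # (n,2,3)

    Tp = frames(P)
    Tq = frames(Q)
    A = Tp @ np.stack([P[:, 1] - P[:, 0], P[:, 2] - P[:, 0]], axis=2)
    G = Tq @ np.stack([Q[:, 1] - Q[:, 0], Q[:, 2] - Q[:, 0]], axis=2)
    F = G @ np.linalg.inv(A)
    C = np.swapaxes(F, 1, 2) @ F
    E = 0.5 * (C - np.eye(2))
    m = 0.5 * (E[:, 0, 0] + E[:, 1, 1])
    r = np.hypot(0.5 * (E[:, 0, 0] - E[:, 1, 1]), E[:, 0, 1])
    out[:, 0] = m + r
    out[:, 1] = m - r
    return out


def facet_strain_field(traj: MechTrajectory, snapshot: int,
                       exclude_end_rings: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """(tris, principal strains) for one snapshot.

    Facet = triangle (two per cortex quad).  End-ring facets, whose
    strains are boundary-condition artifacts, are optionally excluded.
    """
    rv = traj.rv
    q = rv.cortex_quads
    tris = np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]], axis=0)
    if exclude_end_rings:
        # axial band of each facet from its reference coordinates (works
        # for quarter models too)
        n_ax = rv.config.n_axial
        dx = rv.config.dx
        xmin = rv.nodes[tris, 0].min(axis=1)
        ring = np.rint(xmin / dx).astype(int)
        keep = (ring > 0) & (ring < n_ax - 1)
        tris = tris[keep]
    X = rv.nodes
    x = traj.deformed_nodes(snapshot)
    return tris, _tri_strains(X, x, tris)


def max_strain_curve(traj: MechTrajectory, keep_fields: bool = False) -> StrainCurve:
    """Maximum principal cortex strain over facets, per output strain."""
    if not traj.states:
        raise ValueError("empty trajectory")
    eps_axon, ex, ey = [], [], []
    fields = [] if keep_fields else None
    for i, st in enumerate(traj.states):
        _, pr = facet_strain_field(traj, i)
        k = int(np.argmax(pr[:, 0]))
        eps_axon.append(st.eps_axon)
        ex.append(pr[k, 0])
        ey.append(pr[k, 1])
        if keep_fields:
            fields.append(pr)
    return StrainCurve(rate=traj.load.strain_rate,
                       eps_axon=np.asarray(eps_axon),
                       eps_x=np.asarray(ex), eps_y=np.asarray(ey),
                       fields=fields)


def ensemble_stats(curves: list[StrainCurve]) -> EnsembleCurve:
    """Pointwise mean and (population) standard deviation over members."""
    if not curves:
        raise ValueError("no curves")
    rate = curves[0].rate
    grid = curves[0].eps_axon
    for c in curves[1:]:
        if c.rate != rate or len(c.eps_axon) != len(grid) \
                or not np.allclose(c.eps_axon, grid):
            raise ValueError("curves must share rate and eps_axon grid")
    ex = np.stack([c.eps_x for c in curves])
    ey = np.stack([c.eps_y for c in curves])
    return EnsembleCurve(rate=rate, eps_axon=grid.copy(),
                         mean_eps_x=ex.mean(axis=0), sd_eps_x=ex.std(axis=0),
                         mean_eps_y=ey.mean(axis=0), n_members=len(curves))


def iso_strain(ensembles: dict[float, EnsembleCurve], eps_axon: float) -> pd.DataFrame:
    """Mean max cortex strain at fixed applied strain, one row per rate."""
    rows = []
    for rate in sorted(ensembles):
        e = ensembles[rate]
        g = e.eps_axon
        if not (g[0] - 1e-12 <= eps_axon <= g[-1] + 1e-12):
            raise ValueError(f"eps_axon={eps_axon} outside grid [{g[0]}, {g[-1]}]")
        rows.append({"rate": rate,
                     "mean_eps_x": float(np.interp(eps_axon, g, e.mean_eps_x)),
                     "sd_eps_x": float(np.interp(eps_axon, g, e.sd_eps_x))})
    return pd.DataFrame(rows)


def plot_strain_field(traj: MechTrajectory, snapshot: int, ax=None,
                      vmin: float = 0.0, vmax: float = 0.40):
    """Unrolled-cylinder fringe plot of the first principal cortex strain.

    Convenience visualization only (not validated against any reference
    rendering).  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    tris, pr = facet_strain_field(traj, snapshot, exclude_end_rings=False)
    rv = traj.rv
    X = rv.nodes
    theta = np.arctan2(X[:, 2], X[:, 1])
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    cx = X[tris, 0].mean(axis=1)
    cy = np.degrees(theta[tris]).mean(axis=1)
    sc = ax.scatter(cx, cy, c=np.clip(pr[:, 0], vmin, vmax), s=28,
                    marker="s", cmap="jet", vmin=vmin, vmax=vmax)
    ax.set_xlabel("axial position (um)")
    ax.set_ylabel("angle (deg)")
    ax.set_title(f"eps_axon = {traj.states[snapshot].eps_axon:.2f}, "
                 f"rate = {traj.load.strain_rate:g}/s")
    plt.colorbar(sc, ax=ax, label="1st principal strain")
    return ax


def sensitivity_scan(rv: AxonRV, load: LoadCase,
                     param_grid: dict[str, list[float]] | None = None,
                     materials: MaterialTable | None = None) -> pd.DataFrame:
    """Max-strain curves under multiplicative material perturbations.

    ``param_grid`` maps MaterialTable field names to lists of positive
    factors; the default scans tau viscosity x {0, 0.5, 1, 2}.
    """
    materials = materials or MaterialTable()
    if param_grid is None:
        param_grid = {"tau_mu": [0.0, 0.5, 1.0, 2.0]}
    rows = []
    for name, factors in param_grid.items():
        base = getattr(materials, name)
        for f in factors:
            if f < 0:
                raise ValueError("perturbation factors must be >= 0")
            m = materials.replace(**{name: base * f})
            curve = max_strain_curve(run_stretch(rv, m, load))
            for ea, ex in zip(curve.eps_axon, curve.eps_x):
                rows.append({"param": name, "factor": f, "rate": load.strain_rate,
                             "eps_axon": float(ea), "max_eps_x": float(ex)})
    return pd.DataFrame(rows)
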