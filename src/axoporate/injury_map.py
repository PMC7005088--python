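"""Local-strain state map and axonal-strain injury report.

Maps ensemble cortex-strain curves through configured membrane-state
thresholds (interdigitation onset, poration onset, permeability cap,
with and without an embedded channel) and reports the applied axonal
strains at which each membrane state is first reached.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cortex_strain import EnsembleCurve

__all__ = [
    "StateMap",
    "InjuryReport",
    "classify_local_strain",
    "threshold_crossings",
    "build_report",
]

NOT_REACHED = "not_reached"


@dataclass(frozen=True)
class StateMap:
    """Membrane-state thresholds in local cortex strain eps_x.

    Defaults are the MD-derived values this package treats as
    configuration: bare bilayer 0.27 / 0.34 with a 40 % permeability
    cap; protein-embedded 0.34 / 0.47 with 51 %.  Poration thresholds
    are inclusive.
    """

    bare_interdigitation: float = 0.27
    bare_poration: float = 0.34
    bare_dpm_max: float = 40.0
    protein_interdigitation: float = 0.34
    protein_poration: float = 0.47
    protein_dpm_max: float = 51.0

    def __post_init__(self):
        for a, b in ((self.bare_interdigitation, self.bare_poration),
                     (self.protein_interdigitation, self.protein_poration)):
            if not (0 < a < b):
                raise ValueError(
                    "interdigitation onset must lie in (0, poration onset)")

    def thresholds(self, protein: bool) -> tuple[float, float, float]:
        if protein:
            return (self.protein_interdigitation, self.protein_poration,
                    self.protein_dpm_max)
        return self.bare_interdigitation, self.bare_poration, self.bare_dpm_max

    def to_dict(self) -> dict:
        return {
            "bare": {"interdigitation": self.bare_interdigitation,
                     "poration": self.bare_poration,
                     "dpm_max": self.bare_dpm_max},
            "protein": {"interdigitation": self.protein_interdigitation,
                        "poration": self.protein_poration,
                        "dpm_max": self.protein_dpm_max},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateMap":
        return cls(
            bare_interdigitation=d["bare"]["interdigitation"],
            bare_poration=d["bare"]["poration"],
            bare_dpm_max=d["bare"]["dpm_max"],
            protein_interdigitation=d["protein"]["interdigitation"],
            protein_poration=d["protein"]["poration"],
            protein_dpm_max=d["protein"]["dpm_max"],
        )


def classify_local_strain(eps_x: float, protein: bool,
                          state_map: StateMap | None = None
                          ) -> tuple[str, float]:
    """(state label, permeability change %) for one local strain.

    Permeability change rises linearly from 0 at eps_x = 0 to the cap at
    the poration onset, and stays capped beyond.
    """
    if eps_x < 0:
        raise ValueError("eps_x must be >= 0")
    sm = state_map or StateMap()
    interdig, pore, dpm_max = sm.thresholds(protein)
    dpm = dpm_max * min(eps_x / pore, 1.0)
    if eps_x >= pore:
        return "porated", dpm
    if eps_x > interdig:
        return "interdigitated", dpm
    return "intact", dpm


def _first_crossing(grid: np.ndarray, mean: np.ndarray,
                    threshold: float) -> float | None:
    """Linearly interpolated first crossing of a monotone curve."""
    if mean[0] >= threshold:
        return float(grid[0])
    above = np.flatnonzero(mean >= threshold)
    if len(above) == 0:
        return None
    i = above[0]
    x0, x1 = grid[i - 1], grid[i]
    y0, y1 = mean[i - 1], mean[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (threshold - y0) * (x1 - x0) / (y1 - y0))


def threshold_crossings(ensemble: EnsembleCurve, state_map: StateMap,
                        protein: bool) -> tuple[float | None, float | None]:
    """(eps_axon at interdigitation onset, eps_axon at poration onset).

    Uses the ensemble mean curve; a non-monotone mean is projected to
    its running maximum with a warning.  ``None`` marks a threshold the
    curve never reaches.
    """
    if len(ensemble.eps_axon) == 0:
        raise ValueError("empty ensemble curve")
    mean = np.asarray(ensemble.mean_eps_x, dtype=float)
    mono = np.maximum.accumulate(mean)
    if not np.allclose(mono, mean):
        warnings.warn("ensemble mean curve was not monotone; "
                      "projected to running maximum")
    interdig, pore, _ = state_map.thresholds(protein)
    grid = ensemble.eps_axon
    return (_first_crossing(grid, mono, interdig),
            _first_crossing(grid, mono, pore))


@dataclass
class InjuryReport:
    """Per (rate, protein flag) onset strains and permeability schedule."""

    state_map: StateMap
    rows: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"state_map": self.state_map.to_dict(),
                "rows": self.rows, "provenance": self.provenance}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)

    @classmethod
    def from_json(cls, s: str) -> "InjuryReport":
        d = json.loads(s)
        return cls(state_map=StateMap.from_dict(d["state_map"]),
                   rows=d["rows"], provenance=d["provenance"])

    def to_markdown(self) -> str:
        lines = ["| rate (1/s) | protein | interdigitation onset (% eps_axon) "
                 "| poration onset (% eps_axon) |",
                 "|---|---|---|---|"]
        for r in self.rows:
            def fmt(v):
                return f"{100 * v:.1f}" if isinstance(v, (int, float)) else v
            lines.append(
                f"| {r['rate']} | {'yes' if r['protein'] else 'no'} | "
                f"{fmt(r['interdigitation_onset'])} | {fmt(r['poration_onset'])} |")
        return "\n".join(lines)


def build_report(ensembles: dict[float, EnsembleCurve],
                 state_map: StateMap | None = None,
                 protein_flags: tuple = (False, True),
                 provenance: dict | None = None) -> InjuryReport:
    """Full state-map table over rates and protein flags.

    Each row carries the onset strains plus a permeability-change
    schedule dPm(eps_axon) evaluated on the ensemble grid.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    sm = state_map or StateMap()
    rows = []
    for rate in sorted(ensembles):
        ens = ensembles[rate]
        mono = np.maximum.accumulate(ens.mean_eps_x)
        for protein in protein_flags:
            interdig, pore = threshold_crossings(ens, sm, protein)
            dpm = [classify_local_strain(max(float(e), 0.0), protein, sm)[1]
                   for e in mono]
            rows.append({
                "rate": float(rate),
                "protein": bool(protein),
                "interdigitation_onset": interdig if interdig is not None
                else NOT_REACHED,
                "poration_onset": pore if pore is not None else NOT_REACHED,
                "eps_axon_grid": [float(x) for x in ens.eps_axon],
                "dpm_percent": [float(x) for x in dpm],
                "n_members": ens.n_members,
            })
    return InjuryReport(state_map=sm, rows=rows, provenance=provenance or {})
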