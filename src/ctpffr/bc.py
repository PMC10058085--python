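"""Inlet and outlet boundary conditions for the coronary network.

The inlet condition is the mean aortic pressure estimated from brachial
cuff pressures, MAP = 0.4*(SBP - DBP) + DBP.  Each coronary outlet gets a
lumped microvascular resistance derived from the hyperemic flow its
Voronoi perfusion territory receives:

    Q_out,i = sum_n Vol_n * MBF_n          (mL/min, Vol in mL)
    R_i     = (MAP - Pv) / Q_out,i         (mmHg * min / mL)

with venous pressure Pv = 5 mmHg.  By construction R_i * Q_i = MAP - Pv
exactly.  Internal units at this layer are clinical (mmHg, mL/min);
conversion to SI happens once at the solver boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .perfusion import MBFMap, PerfusionTerritories

#: effective-dose conversion coefficient for cardiac CT, mSv per mGy*cm
DOSE_COEFFICIENT = 0.014

MMHG_TO_PA = 133.322  # 1 mmHg in Pa
MLMIN_TO_M3S = 1.0e-6 / 60.0  # 1 mL/min in m^3/s


def mean_aortic_pressure(sbp: float, dbp: float) -> float:
    """MAP (mmHg) from brachial systolic/diastolic cuff pressures.

    Uses the 40%-pulse-pressure rule MAP = 0.4*(SBP - DBP) + DBP, a convex
    combination of the two cuff readings.
    """
    if not dbp > 0:
        raise ValueError("DBP must be > 0")
    if not sbp > dbp:
        raise ValueError("SBP must exceed DBP")
    return 0.4 * (sbp - dbp) + dbp


@dataclass
class HemodynamicState:
    """Patient-level pressures and blood constants.

    SBP/DBP/MAP/Pv in mmHg; viscosity in Pa*s; density in kg/m^3.
    """

    sbp: float
    dbp: float
    pv: float = 5.0
    blood_viscosity: float = 0.0035
    blood_density: float = 1050.0
    map_pressure: float = field(init=False)

    def __post_init__(self) -> None:
        self.map_pressure = mean_aortic_pressure(self.sbp, self.dbp)
        if self.pv < 0 or self.pv >= self.map_pressure:
            raise ValueError("Pv must satisfy 0 <= Pv < MAP")
        if self.blood_viscosity <= 0 or self.blood_density <= 0:
            raise ValueError("blood constants must be positive")


@dataclass
class OutletBC:
    outlet_id: int
    q_hyp: float  # hyperemic territory flow, mL/min
    r_hyp: float  # lumped outlet resistance, mmHg*min/mL
    voxel_count: int
    flagged_zero_flow: bool = False


def outlet_flow(territories: PerfusionTerritories, mbf_map: MBFMap,
                outlet_id: int) -> float:
    """Hyperemic flow (mL/min) perfusing one outlet's territory.

    Sum over territory voxels of voxel volume (mL) times per-voxel MBF
    (mL/min/mL).
    """
    sel = territories.territory_mask(outlet_id)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"outlet {outlet_id} has an empty territory")
    vol_ml = mbf_map.voxel_volume_mm3 * 1.0e-3
    return float(mbf_map.values[sel].sum() * vol_ml)


def outlet_resistance(map_pressure: float, pv: float, q: float) -> float:
    """Lumped outlet resistance (mmHg*min/mL) from the perfusion pressure drop."""
    if q <= 0:
        raise ValueError("territory flow must be > 0")
    if map_pressure <= pv:
        raise ValueError("MAP must exceed venous pressure")
    return (map_pressure - pv) / q


def compute_outlet_bcs(territories: PerfusionTerritories, mbf_map: MBFMap,
                       hemo: HemodynamicState,
                       zero_flow_resistance: float = 1.0e6) -> dict[int, OutletBC]:
    """Eq.-2/Eq.-3 boundary conditions for every outlet in the territory map.

    A territory whose integrated flow is zero (fully infarcted synthetic
    tissue) is flagged and assigned ``zero_flow_resistance`` instead of an
    infinite resistance so the network stays solvable.
    """
    bcs: dict[int, OutletBC] = {}
    for oid in territories.outlet_ids:
        n_vox = territories.voxel_count(oid)
        if n_vox == 0:
            raise ValueError(f"outlet {oid} has an empty territory")
        q = float(mbf_map.values[territories.territory_mask(oid)].sum()
                  * mbf_map.voxel_volume_mm3 * 1.0e-3)
        if q <= 0:
            warnings.warn(f"outlet {oid}: zero territory flow, applying resistance ceiling")
            bcs[oid] = OutletBC(oid, 0.0, zero_flow_resistance, n_vox, True)
        else:
            bcs[oid] = OutletBC(oid, q,
                                outlet_resistance(hemo.map_pressure, hemo.pv, q),
                                n_vox)
    return bcs


def effective_dose(dlp: float) -> float:
    """Effective radiation dose (mSv) from a dose-length product (mGy*cm)."""
    if dlp < 0:
        raise ValueError("DLP must be >= 0")
    return DOSE_COEFFICIENT * dlp
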