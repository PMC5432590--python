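"""Theoretical xylem conductivity from vessel anatomy.

Hagen–Poiseuille conductivity of a conduit population,

    k_t = (pi * rho / (128 * eta)) * sum(d_i^4),

with water density rho = 1000 kg m-3 and viscosity eta = 1e-9 MPa s and
vessel diameters d_i in meters. The mass-flow result (kg m s-1 MPa-1) is
converted to molar units through the molar mass of water and reported in
mmol m s-1 MPa-1; dividing by the subtended leaf area gives the
leaf-area-specific conductivity k_ts (mmol m-1 s-1 MPa-1).

Vessel lumens are measured as areas on cross-sections; Poiseuille's law
consumes diameters, so areas are mapped through the equivalent-circle
diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WATER_DENSITY",
    "WATER_VISCOSITY_MPA_S",
    "WATER_MOLAR_MASS",
    "DEFAULT_BIN_EDGES",
    "equivalent_diameter",
    "theoretical_conductivity",
    "specific_conductivity",
    "vessel_class_distribution",
    "ConductivityResult",
    "analyze_section",
    "summarize_sections",
]

WATER_DENSITY = 1000.0          # kg m-3
WATER_VISCOSITY_MPA_S = 1e-9    # MPa s (= 1e-3 Pa s)
WATER_MOLAR_MASS = 0.018015     # kg mol-1
DEFAULT_BIN_EDGES = (10.0, 15.0, 20.0, 25.0, 30.0)  # um; open-ended classes added


def equivalent_diameter(lumen_area):
    """Equivalent-circle diameter (um) of a vessel lumen area (um^2).

    ``d = 2 * sqrt(A / pi)`` — the diameter of the circle with the measured
    area; no ellipse correction is applied.
    """
    lumen_area = np.asarray(lumen_area, dtype=float)
    if np.any(lumen_area <= 0):
        raise ValueError("lumen areas must be positive")
    d = 2.0 * np.sqrt(lumen_area / np.pi)
    return float(d) if d.ndim == 0 else d


def theoretical_conductivity(diameters_um, extrapolate_half: bool = False) -> float:
    """Hagen–Poiseuille conductivity k_t (mmol m s-1 MPa-1) of a vessel set.

    Parameters
    ----------
    diameters_um : array_like
        Vessel lumen diameters in micrometers.
    extrapolate_half : bool
        If the vessel set covers only half of a (near-symmetric) petiole
        cross-section, double the d^4 sum to extrapolate to the whole organ.

    Notes
    -----
    Unit chain: (pi*rho/(128*eta)) * sum(d^4) with d in m gives mass flow per
    pressure gradient in kg m s-1 MPa-1; dividing by 0.018015 kg mol-1 and
    multiplying by 1000 yields mmol m s-1 MPa-1.
    """
    d = np.asarray(diameters_um, dtype=float)
    if d.size == 0:
        warnings.warn("empty vessel set: k_t = 0", stacklevel=2)
        return 0.0
    if np.any(d <= 0):
        raise ValueError("vessel diameters must be positive")
    sum_d4 = float(np.sum((d * 1e-6) ** 4))  # m^4
    if extrapolate_half:
        sum_d4 *= 2.0
    kt_mass = np.pi * WATER_DENSITY / (128.0 * WATER_VISCOSITY_MPA_S) * sum_d4
    return kt_mass / WATER_MOLAR_MASS * 1000.0


def specific_conductivity(k_t: float, leaf_area_cm2: float) -> float:
    """Leaf-area-specific conductivity k_ts = k_t / LA (mmol m-1 s-1 MPa-1).

    ``leaf_area_cm2`` is the leaf area subtended by the petiole, in cm^2
    (converted internally to m^2).
    """
    if leaf_area_cm2 <= 0:
        raise ValueError("leaf area must be positive")
    return k_t / (leaf_area_cm2 * 1e-4)


def vessel_class_distribution(diameters_um, bin_edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Vessel-number frequency and k_t contribution by diameter class.

    Classes are the half-open intervals between ``bin_edges`` plus an
    underflow (< first edge) and an overflow (>= last edge) class. Both the
    relative frequency and the relative d^4 (conductivity) contribution are
    in percent and each sums to 100 over the classes.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    d = np.asarray(diameters_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("vessel diameters must be positive")
    full_edges = np.concatenate([[0.0], edges, [np.inf]])
    counts, _ = np.histogram(d, bins=full_edges)
    d4_sums = np.array(
        [
            float(np.sum(d[(d >= lo) & (d < hi)] ** 4))
            for lo, hi in zip(full_edges[:-1], full_edges[1:])
        ]
    )
    labels = (
        [f"<{edges[0]:g}"]
        + [f"{lo:g}-{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]
        + [f">={edges[-1]:g}"]
    )
    total = counts.sum()
    total_d4 = d4_sums.sum()
    return pd.DataFrame(
        {
            "class_um": labels,
            "n": counts,
            "frequency_pct": 100.0 * counts / total if total else 0.0 * counts,
            "kt_contribution_pct": (
                100.0 * d4_sums / total_d4 if total_d4 else 0.0 * d4_sums
            ),
        }
    )


@dataclass
class ConductivityResult:
    """Per-section anatomy summary (the per-petiole table row)."""

    k_t: float                 # mmol m s-1 MPa-1
    k_ts: float                # mmol m-1 s-1 MPa-1 (per m^2 leaf area)
    mean_diameter: float       # um
    total_vessel_area: float   # mm^2
    n_vessels: int             # extrapolated count if half_section

    def to_dict(self) -> dict:
        return {
            "k_t": self.k_t,
            "k_ts": self.k_ts,
            "mean_diameter_um": self.mean_diameter,
            "total_vessel_area_mm2": self.total_vessel_area,
            "n_vessels": self.n_vessels,
        }


def analyze_section(
    vessels: pd.DataFrame,
    leaf_area_cm2: float,
    half_section: bool = False,
) -> ConductivityResult:
    """Conductivity summary of one petiole cross-section.

    ``vessels`` needs ``diameter_um`` or ``lumen_area_um2`` (diameters are
    derived by equivalent circle when only areas are present). With
    ``half_section``, counts, areas and the d^4 sum are doubled to
    extrapolate the digitized half to the whole petiole.
    """
    if len(vessels) == 0:
        raise ValueError("vessel set must be non-empty")
    if "diameter_um" in vessels.columns and vessels["diameter_um"].notna().all():
        d = vessels["diameter_um"].to_numpy(dtype=float)
    elif "lumen_area_um2" in vessels.columns:
        d = equivalent_diameter(vessels["lumen_area_um2"].to_numpy(dtype=float))
    else:
        raise ValueError("vessels need diameter_um or lumen_area_um2")
    factor = 2 if half_section else 1
    k_t = theoretical_conductivity(d, extrapolate_half=half_section)
    total_area_mm2 = float(np.sum(np.pi * (d / 2.0) ** 2)) * 1e-6 * factor
    return ConductivityResult(
        k_t=k_t,
        k_ts=specific_conductivity(k_t, leaf_area_cm2),
        mean_diameter=float(np.mean(d)),
        total_vessel_area=total_area_mm2,
        n_vessels=int(len(d)) * factor,
    )


def summarize_sections(
    vessels: pd.DataFrame, sections: pd.DataFrame
) -> pd.DataFrame:
    """Per-section conductivity table from long-format vessel records.

    ``vessels`` holds one row per vessel keyed by ``section_id``;
    ``sections`` holds per-section metadata (``section_id``,
    ``leaf_area_cm2``, optional ``petiole_area_mm2``, ``n_bundles``,
    ``half_section``, ``treatment``).
    """
    rows = []
    for _, meta in sections.iterrows():
        sid = meta["section_id"]
        sub = vessels[vessels["section_id"] == sid]
        res = analyze_section(
            sub,
            leaf_area_cm2=float(meta["leaf_area_cm2"]),
            half_section=bool(meta.get("half_section", False)),
        )
        row = {"section_id": sid, **res.to_dict()}
        for extra in ("treatment", "petiole_area_mm2", "n_bundles", "leaf_area_cm2"):
            if extra in meta.index:
                row[extra] = meta[extra]
        rows.append(row)
    return pd.DataFrame(rows).set_index("section_id")
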