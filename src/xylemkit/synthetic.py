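"""Synthetic data with known ground truth for every analysis stage.

Each generator draws a dataset of one of the four input kinds (vulnerability
curve observations, pressure–volume dehydration series, gas-exchange daily
courses, vessel populations) from an explicit forward model, seeds all
randomness, and attaches the generating parameters, so each analysis stage
can be scored by parameter recovery without any external data.

Presets named "WW", "TD" and "SD" carry literature-typical parameter values
for well-watered, transient-deficit and sustained-deficit acclimated
grapevines; they are convenience parameter sets, not data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .pressure_volume import PressureVolumeCurve
from .vulnerability import plc_sigmoid

__all__ = [
    "SimulatedData",
    "VCGenerator",
    "PVGenerator",
    "CourseGenerator",
    "VesselGenerator",
    "simulate_vc",
    "simulate_pv",
    "simulate_daily_course",
    "simulate_decline_course",
    "simulate_vessels",
    "PRESETS",
    "write_dataset",
]


class SimulatedData(NamedTuple):
    """A generated dataset plus the ground truth that produced it."""

    data: object  # DataFrame, or PressureVolumeCurve for PV
    truth: dict


# Preset parameter sets for the three acclimation regimes: sigmoid VC
# parameters (alpha = slope/25), PV osmotic/elastic parameters, and
# vessel-population summaries typical of each regime.
PRESETS: dict[str, dict] = {
    "WW": {
        "vc": {"alpha": 4.32, "plc50": -1.31},
        "pv": {"pi100": -1.02, "epsilon": 6.07},
        "course": {"k_leaf_true": 30.0, "k_plant_true": 10.0},
        "vessels": {"mean_diameter": 20.6, "n": 424},
    },
    "TD": {
        "vc": {"alpha": 4.12, "plc50": -1.18},
        "pv": {"pi100": -1.07, "epsilon": 8.16},
        "course": {"k_leaf_true": 28.0, "k_plant_true": 9.0},
        "vessels": {"mean_diameter": 18.3, "n": 468},
    },
    "SD": {
        "vc": {"alpha": 4.64, "plc50": -1.09},
        "pv": {"pi100": -1.10, "epsilon": 7.17},
        "course": {"k_leaf_true": 26.0, "k_plant_true": 8.0},
        "vessels": {"mean_diameter": 20.0, "n": 336},
    },
}


@dataclass
class VCGenerator:
    """Forward model for vulnerability-curve observations.

    Ψs is drawn uniformly over ``psi_range``; PLC is the logistic curve at
    Ψs plus additive Gaussian noise (``noise_sd`` PLC points), clamped to
    [0, 100].
    """

    alpha: float
    plc50: float
    psi_range: tuple = (-2.2, -0.2)
    n: int = 36
    noise_sd: float = 5.0
    seed: int | None = None
    treatment: str = "SYN"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.psi_range[0] < self.psi_range[1]:
            raise ValueError("psi_range must be ordered (low, high)")


def simulate_vc(gen: VCGenerator) -> SimulatedData:
    """Draw one vulnerability-curve dataset."""
    rng = np.random.default_rng(gen.seed)
    psi = rng.uniform(gen.psi_range[0], gen.psi_range[1], gen.n)
    plc = plc_sigmoid(psi, gen.alpha, gen.plc50)
    if gen.noise_sd > 0:
        plc = plc + rng.normal(0.0, gen.noise_sd, gen.n)
    plc = np.clip(plc, 0.0, 100.0)
    df = pd.DataFrame(
        {
            "psi_stem": psi,
            "plc": plc,
            "treatment": gen.treatment,
            "shoot_id": [f"s{i:03d}" for i in range(gen.n)],
        }
    )
    truth = {"alpha": gen.alpha, "plc50": gen.plc50, "noise_sd": gen.noise_sd}
    df.attrs["truth"] = truth
    return SimulatedData(df, truth)


@dataclass
class PVGenerator:
    """Forward pressure–volume model: Boyle–van't Hoff osmotic dilution plus
    a linear turgor decline with constant bulk modulus.

    On a descending RWC grid, with symplastic fraction
    ``R_s = (RWC/100 − af) / (1 − af)``:

    * osmotic potential  π = pi100 / R_s,
    * turgor pressure    P = max(0, −pi100 − epsilon · (1 − R_s)),
    * water potential    Ψ = P + π,
    * fresh weight       dry + (turgid − dry) · RWC/100.

    Multiplicative Gaussian noise (sd ``noise_rel``) applies to weights and
    Ψ. The model's analytic turgor loss point,
    Ψ_TLP = pi100·epsilon/(epsilon + pi100), is recorded as ground truth.
    """

    pi100: float
    epsilon: float
    apoplastic_fraction: float = 0.0
    turgid_weight: float = 2.0
    dry_weight: float = 0.5
    n: int = 15
    rwc_min: float = 72.0
    noise_rel: float = 0.0
    seed: int | None = None
    treatment: str = "SYN"
    leaf_id: str = "synthetic"

    def __post_init__(self):
        if self.pi100 >= 0:
            raise ValueError("pi100 must be negative (MPa)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive (MPa)")
        if not 0 <= self.apoplastic_fraction < 1:
            raise ValueError("apoplastic_fraction must lie in [0, 1)")

    @property
    def analytic_tlp(self) -> float:
        """Ψ at which the forward model's turgor reaches zero, MPa."""
        return self.pi100 * self.epsilon / (self.epsilon + self.pi100)

    @property
    def analytic_rwc_tlp(self) -> float:
        """Total RWC (percent) at the analytic turgor loss point."""
        rs_tlp = 1.0 + self.pi100 / self.epsilon
        af = self.apoplastic_fraction
        return 100.0 * (af + (1.0 - af) * rs_tlp)


def simulate_pv(gen: PVGenerator) -> SimulatedData:
    """Draw one pressure–volume dehydration series."""
    if gen.epsilon <= -gen.pi100:
        warnings.warn(
            "epsilon <= -pi100: turgor loss lies at or below zero symplastic "
            "water content; the curve has no turgor phase",
            stacklevel=2,
        )
    rng = np.random.default_rng(gen.seed)
    af = gen.apoplastic_fraction
    rwc = np.linspace(100.0, gen.rwc_min, gen.n)
    r_s = (rwc / 100.0 - af) / (1.0 - af)
    if np.any(r_s <= 0):
        raise ValueError("rwc_min too low: symplastic water content reaches 0")
    pi = gen.pi100 / r_s
    turgor = np.maximum(0.0, -gen.pi100 - gen.epsilon * (1.0 - r_s))
    psi = turgor + pi
    fresh = gen.dry_weight + (gen.turgid_weight - gen.dry_weight) * rwc / 100.0
    if gen.noise_rel > 0:
        fresh = fresh * (1.0 + rng.normal(0.0, gen.noise_rel, gen.n))
        psi = psi * (1.0 + rng.normal(0.0, gen.noise_rel, gen.n))
    psi = np.minimum(psi, 0.0)
    fresh = np.minimum(fresh, gen.turgid_weight)
    with warnings.catch_warnings():
        # weighing noise breaks strict monotonicity by construction
        warnings.simplefilter("ignore", UserWarning)
        curve = PressureVolumeCurve(
            fresh, psi, gen.turgid_weight, gen.dry_weight,
            leaf_id=gen.leaf_id, treatment=gen.treatment,
        )
    truth = {
        "pi100": gen.pi100,
        "epsilon": gen.epsilon,
        "apoplastic_fraction": af,
        "psi_tlp": gen.analytic_tlp,
        "rwc_tlp": gen.analytic_rwc_tlp,
        "noise_rel": gen.noise_rel,
    }
    return SimulatedData(curve, truth)


def _default_e_profile(n: int = 40, e_max: float = 4.0):
    """Half-sine transpiration course between 06:00 and 18:00."""
    t = np.linspace(6.0, 18.0, n)
    return t, e_max * np.sin(np.pi * (t - 6.0) / 12.0)


@dataclass
class CourseGenerator:
    """Forward model for a gas-exchange daily course.

    Water potentials follow from Ohm's law: Ψl = Ψpd − E/k_plant and
    Ψs = Ψl + E/k_leaf. ``noise_rel`` applies multiplicatively and
    independently to the recorded E and to each water-potential drop
    (pre-dawn is taken as exact), so the per-record conductance error is of
    order noise_rel. gs is E over a fixed nominal mole-fraction VPD.
    """

    k_leaf_true: float = 30.0
    k_plant_true: float = 10.0
    psi_predawn: float = -0.15
    E_profile: tuple | None = None  # (time_h, E) arrays; default half-sine
    noise_rel: float = 0.0
    seed: int | None = None
    vpd_mol_frac: float = 0.015
    theta: float = 43.0
    treatment: str = "SYN"

    def __post_init__(self):
        if self.k_leaf_true <= 0 or self.k_plant_true <= 0:
            raise ValueError("conductances must be positive")


def simulate_daily_course(gen: CourseGenerator) -> SimulatedData:
    """Draw one daily course of gas-exchange records."""
    rng = np.random.default_rng(gen.seed)
    if gen.E_profile is None:
        t, e_true = _default_e_profile()
    else:
        t = np.asarray(gen.E_profile[0], dtype=float)
        e_true = np.asarray(gen.E_profile[1], dtype=float)
    n = len(t)
    drop_plant = e_true / gen.k_plant_true
    drop_leaf = e_true / gen.k_leaf_true
    e_rec = e_true.copy()
    if gen.noise_rel > 0:
        drop_plant = drop_plant * (1.0 + rng.normal(0.0, gen.noise_rel, n))
        drop_leaf = drop_leaf * (1.0 + rng.normal(0.0, gen.noise_rel, n))
        e_rec = e_rec * (1.0 + rng.normal(0.0, gen.noise_rel, n))
    psi_leaf = gen.psi_predawn - drop_plant
    psi_stem = psi_leaf + drop_leaf
    gs = e_rec * 1e-3 / gen.vpd_mol_frac
    df = pd.DataFrame(
        {
            "time": t,
            "E": e_rec,
            "gs": gs,
            "psi_leaf": psi_leaf,
            "psi_stem": psi_stem,
            "psi_predawn": gen.psi_predawn,
            "treatment": gen.treatment,
            "theta": gen.theta,
        }
    )
    truth = {
        "k_leaf_true": gen.k_leaf_true,
        "k_plant_true": gen.k_plant_true,
        "psi_predawn": gen.psi_predawn,
        "noise_rel": gen.noise_rel,
    }
    df.attrs["truth"] = truth
    return SimulatedData(df, truth)


def simulate_decline_course(
    k_ref: float = 35.0,
    midpoint: float = -0.5,
    alpha: float = 6.0,
    psi_range: tuple = (-1.4, -0.1),
    n: int = 60,
    drop: float = 0.1,
    psi_predawn_offset: float = 0.05,
    noise_rel: float = 0.0,
    seed: int | None = None,
    treatment: str = "SYN",
) -> SimulatedData:
    """Gas-exchange records in which k_leaf declines sigmoidally with Ψs.

    A constructed scenario for the decline-versus-embolism comparison:
    k_leaf(Ψs) = k_ref · (1 − L(Ψs)/100) with the logistic percent loss
    L(Ψs) = 100/(1 + exp(alpha (Ψs − midpoint))). Each record fixes the
    stem-to-leaf drop to ``drop`` MPa, sets E = k_leaf(Ψs)·drop, and places
    pre-dawn ``psi_predawn_offset`` above Ψs, so inverting Ohm's law
    recovers the prescribed k_leaf exactly at zero noise.
    """
    rng = np.random.default_rng(seed)
    psi_s = rng.uniform(psi_range[0], psi_range[1], n)
    loss = plc_sigmoid(psi_s, alpha, midpoint)
    k_leaf = k_ref * (1.0 - loss / 100.0)
    e = k_leaf * drop
    if noise_rel > 0:
        e = e * (1.0 + rng.normal(0.0, noise_rel, n))
    psi_leaf = psi_s - drop
    df = pd.DataFrame(
        {
            "time": np.linspace(8.0, 16.0, n),
            "E": e,
            "gs": e * 1e-3 / 0.015,
            "psi_leaf": psi_leaf,
            "psi_stem": psi_s,
            "psi_predawn": np.minimum(psi_s + psi_predawn_offset, 0.0),
            "treatment": treatment,
            "theta": 30.0,
        }
    )
    truth = {
        "k_ref": k_ref,
        "kleaf_midpoint": midpoint,
        "alpha": alpha,
        "noise_rel": noise_rel,
    }
    df.attrs["truth"] = truth
    return SimulatedData(df, truth)


@dataclass
class VesselGenerator:
    """Log-normal vessel-diameter population.

    ``log_mean``/``log_sd`` parameterize ln(diameter in um); areas are
    back-computed as circle areas.
    """

    log_mean: float
    log_sd: float = 0.3
    n: int = 200
    seed: int | None = None
    n_bundles: int = 25

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")

    @classmethod
    def from_mean_diameter(cls, mean_diameter: float, log_sd: float = 0.3, **kw):
        """Parameterize so the population mean diameter is ``mean_diameter``
        (log-normal mean = exp(mu + sigma^2/2))."""
        mu = np.log(mean_diameter) - log_sd**2 / 2.0
        return cls(log_mean=mu, log_sd=log_sd, **kw)


def simulate_vessels(gen: VesselGenerator) -> SimulatedData:
    """Draw one vessel population."""
    rng = np.random.default_rng(gen.seed)
    d = rng.lognormal(gen.log_mean, gen.log_sd, gen.n)
    df = pd.DataFrame(
        {
            "diameter_um": d,
            "lumen_area_um2": np.pi * (d / 2.0) ** 2,
            "bundle_id": [f"b{i % gen.n_bundles:02d}" for i in range(gen.n)],
        }
    )
    truth = {
        "log_mean": gen.log_mean,
        "log_sd": gen.log_sd,
        "expected_mean_diameter": float(np.exp(gen.log_mean + gen.log_sd**2 / 2)),
        "n": gen.n,
    }
    df.attrs["truth"] = truth
    return SimulatedData(df, truth)


def write_dataset(sim: SimulatedData, path) -> None:
    """Write a simulated dataset as CSV with a sibling ``*.truth.json``."""
    import pathlib

    path = pathlib.Path(path)
    if isinstance(sim.data, PressureVolumeCurve):
        curve = sim.data
        df = pd.DataFrame(
            {
                "fresh_weight": curve.fresh_weight,
                "psi_leaf": curve.psi_leaf,
                "turgid_weight": curve.turgid_weight,
                "dry_weight": curve.dry_weight,
                "leaf_id": curve.leaf_id,
                "treatment": curve.treatment,
            }
        )
    else:
        df = sim.data
    df.to_csv(path, index=False)
    truth_path = path.with_suffix(".truth.json")
    truth_path.write_text(json.dumps(sim.truth, indent=2) + "\n")
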