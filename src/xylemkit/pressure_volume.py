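"""Pressure–volume (PV) curve analysis.

A PV curve tracks leaf water potential against leaf weight during bench
dehydration. In transformed coordinates (x = 100 − RWC, y = −1/Ψ) the
post-turgor-loss phase is a straight "osmotic line" whose extrapolation
yields the osmotic potential at full turgor (π100, at x = 0) and the
apoplastic water fraction (at y = 0); the departure from that line marks
the turgor loss point (Ψ_TLP, RWC_TLP), and the turgor phase gives the
bulk modulus of elasticity ε as the slope of turgor pressure against
symplastic relative water content.

Because the wet end of the curve is operator-judged in classical
practice, this module uses an explicit, reproducible linear-region rule
(documented in :meth:`PressureVolumeCurve.fit`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PVFitError",
    "relative_water_content",
    "PressureVolumeCurve",
    "PressureVolumeResults",
    "pv_parameter_table",
]


class PVFitError(RuntimeError):
    """PV-curve analysis failed (no acceptable osmotic line)."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


def relative_water_content(fresh_weight, turgid_weight, dry_weight):
    """RWC in percent: ``100 * (fresh - dry) / (turgid - dry)``.

    Values above 100 (fresh weight exceeding the nominal turgid weight,
    possible with over-rehydration or weighing noise) are clipped to 100
    with a warning.
    """
    if turgid_weight <= dry_weight:
        raise ValueError("turgid_weight must exceed dry_weight")
    fresh_weight = np.asarray(fresh_weight, dtype=float)
    rwc = 100.0 * (fresh_weight - dry_weight) / (turgid_weight - dry_weight)
    if np.any(rwc > 100.0):
        warnings.warn("RWC above 100% clipped (fresh weight > turgid weight)",
                      stacklevel=2)
        rwc = np.minimum(rwc, 100.0)
    return float(rwc) if rwc.ndim == 0 else rwc


def _ols_line(x, y):
    """Least-squares line y = m x + b; returns (m, b, r2, residuals)."""
    m, b = np.polyfit(x, y, 1)
    resid = y - (m * x + b)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return m, b, r2, resid


class PressureVolumeCurve:
    """One leaf's dehydration series plus its turgid and dry weights.

    Parameters
    ----------
    fresh_weight : array_like, g
        Leaf weights recorded during dehydration (non-increasing).
    psi_leaf : array_like, MPa
        Water potential measured immediately after each weighing (<= 0).
    turgid_weight, dry_weight : float, g
        Fully rehydrated and oven-dry weights; turgid > dry > 0.
    """

    def __init__(
        self,
        fresh_weight,
        psi_leaf,
        turgid_weight: float,
        dry_weight: float,
        leaf_id=None,
        treatment=None,
    ):
        self.fresh_weight = np.asarray(fresh_weight, dtype=float)
        self.psi_leaf = np.asarray(psi_leaf, dtype=float)
        if self.fresh_weight.shape != self.psi_leaf.shape:
            raise ValueError("fresh_weight and psi_leaf must match in length")
        if dry_weight <= 0 or turgid_weight <= dry_weight:
            raise ValueError("need turgid_weight > dry_weight > 0")
        if np.any(self.fresh_weight <= 0):
            raise ValueError("fresh weights must be positive")
        if np.any(self.psi_leaf > 0):
            raise ValueError("psi_leaf must be <= 0 (MPa, tension)")
        if np.any(np.diff(self.fresh_weight) > 0):
            warnings.warn(
                "fresh weight not monotonically non-increasing; "
                "treating as weighing noise",
                stacklevel=2,
            )
        self.turgid_weight = float(turgid_weight)
        self.dry_weight = float(dry_weight)
        self.leaf_id = leaf_id
        self.treatment = treatment

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, turgid_weight=None, dry_weight=None,
                       leaf_id=None, treatment=None):
        """Build from a table with ``fresh_weight`` and ``psi_leaf`` columns;
        turgid/dry weights are taken from columns if not given explicitly."""
        tw = turgid_weight if turgid_weight is not None else data["turgid_weight"].iloc[0]
        dw = dry_weight if dry_weight is not None else data["dry_weight"].iloc[0]
        if treatment is None and "treatment" in data.columns:
            treatment = data["treatment"].iloc[0]
        if leaf_id is None and "leaf_id" in data.columns:
            leaf_id = data["leaf_id"].iloc[0]
        return cls(data["fresh_weight"], data["psi_leaf"], tw, dw,
                   leaf_id=leaf_id, treatment=treatment)

    def rwc(self):
        """Relative water content (percent) of every observation."""
        return relative_water_content(
            self.fresh_weight, self.turgid_weight, self.dry_weight
        )

    def fit(
        self,
        min_line_points: int = 4,
        resid_factor: float = 2.0,
        r2_min: float | None = None,
        symplastic_epsilon: bool = True,
    ) -> "PressureVolumeResults":
        """Extract π100, ε, Ψ_TLP, RWC_TLP and the apoplastic fraction.

        Osmotic-line rule: starting from the ``min_line_points`` driest
        transformable points, extend the candidate line one point toward
        the wet end at a time. A candidate is accepted while its prediction
        residual against the line fitted on the points accepted so far
        stays within ``resid_factor`` times that line's residual SD (the
        turgor kink lifts −1/Ψ far above the osmotic line, so this is a
        scale-free break detector); the accepted line is then refitted with
        the new point. The turgor loss point is the wettest accepted point,
        evaluated *on* the line. An optional hard R^2 floor (``r2_min``)
        can additionally stop the extension; it is off by default because
        R^2 is scale-dependent — a shallow but genuine osmotic line under
        realistic weighing noise never reaches high R^2.

        ε is the single slope of turgor pressure P = Ψ − π against
        (by default symplastic) relative water content over the turgor
        phase; with fewer than 3 turgor-phase points it is reported absent
        (NaN).
        """
        n = len(self.psi_leaf)
        if n < 8:
            raise PVFitError(
                f"need >= 8 observations spanning turgor loss, got {n}"
            )
        rwc = self.rwc()
        x_all = 100.0 - rwc
        psi = self.psi_leaf
        # transformable points: psi strictly negative (y = -1/psi finite)
        finite = psi < 0
        order = np.argsort(x_all)[::-1]  # driest (largest x) first
        order = order[finite[order]]
        if len(order) < min_line_points:
            raise PVFitError(
                "too few transformable points for the osmotic line",
                diagnostics={"n_transformable": int(len(order))},
            )
        x = x_all[order]
        y = -1.0 / psi[order]

        k = min_line_points
        m, b, r2, resid = _ols_line(x[:k], y[:k])
        y_scale = float(np.max(np.abs(y)))
        while k < len(x):
            sd = float(np.sqrt(np.sum(resid**2) / (k - 2))) if k > 2 else 0.0
            pred_resid = abs(y[k] - (m * x[k] + b))
            # standard error of a new observation predicted at x[k]:
            # the residual/SE ratio is t-distributed, so the threshold is
            # leverage-corrected rather than a bare residual-SD multiple
            xk_bar = x[:k].mean()
            sxx = float(np.sum((x[:k] - xk_bar) ** 2))
            spe = np.sqrt(1.0 + 1.0 / k + (x[k] - xk_bar) ** 2 / sxx)
            if sd <= 1e-12 * y_scale:
                ok = pred_resid <= 1e-8 * y_scale  # exact-line limit
            else:
                ok = pred_resid <= resid_factor * sd * spe
            if ok:
                m1, b1, r21, resid1 = _ols_line(x[: k + 1], y[: k + 1])
                if r2_min is not None and r21 < r2_min:
                    break
                m, b, r2, resid = m1, b1, r21, resid1
                k += 1
            else:
                break

        if b <= 0:
            raise PVFitError(
                "osmotic line intercept non-positive; no physical pi100",
                diagnostics={"slope": m, "intercept": b, "n_line": k},
            )
        pi100 = -1.0 / b

        # turgor loss point: wettest point accepted into the line, on the line
        x_tlp = x[k - 1]
        y_tlp = m * x_tlp + b
        if y_tlp <= 0:
            raise PVFitError("osmotic line non-positive at the TLP point")
        psi_tlp = -1.0 / y_tlp
        rwc_tlp = 100.0 - x_tlp

        # apoplastic fraction from the x-intercept (y = 0 at RWC = 100*af)
        af = np.nan
        if m < 0:
            x_int = -b / m
            af = max(0.0, 1.0 - x_int / 100.0)
        else:
            warnings.warn("osmotic line not declining; apoplastic fraction "
                          "undefined", stacklevel=2)
            af = 0.0

        # turgor phase: all points wetter than the TLP (including psi == 0)
        turgor_mask = x_all < x_tlp
        eps = np.nan
        n_turgor = int(turgor_mask.sum())
        if n_turgor >= 3:
            pi_line = -1.0 / (m * x_all[turgor_mask] + b)
            p_turgor = psi[turgor_mask] - pi_line
            if symplastic_epsilon and af < 1.0:
                r_s = (rwc[turgor_mask] / 100.0 - af) / (1.0 - af)
            else:
                r_s = rwc[turgor_mask] / 100.0
            if np.ptp(r_s) > 0:
                eps = float(np.polyfit(r_s, p_turgor, 1)[0])

        return PressureVolumeResults(
            curve=self,
            pi100=float(pi100),
            epsilon=eps,
            psi_tlp=float(psi_tlp),
            rwc_tlp=float(rwc_tlp),
            apoplastic_fraction=float(af),
            n_points_osmotic_line=int(k),
            r_squared_osmotic_line=float(r2),
            n_points_turgor=n_turgor,
            osmotic_line=(float(m), float(b)),
        )


@dataclass
class PressureVolumeResults:
    """Parameters extracted from one pressure–volume curve."""

    curve: PressureVolumeCurve
    pi100: float           # osmotic potential at full turgor, MPa (< 0)
    epsilon: float         # bulk modulus of elasticity, MPa (NaN if absent)
    psi_tlp: float         # water potential at turgor loss, MPa
    rwc_tlp: float         # relative water content at turgor loss, percent
    apoplastic_fraction: float
    n_points_osmotic_line: int
    r_squared_osmotic_line: float
    n_points_turgor: int
    osmotic_line: tuple    # (slope, intercept) in (x = 100-RWC, y = -1/psi)

    def summary(self) -> str:
        eps = f"{self.epsilon:8.2f}" if np.isfinite(self.epsilon) else "   (n/a)"
        return "\n".join(
            [
                "Pressure-volume curve fit",
                f"  leaf / treatment    : {self.curve.leaf_id} / {self.curve.treatment}",
                f"  pi100   [MPa]       : {self.pi100:8.3f}",
                f"  epsilon [MPa]       : {eps}",
                f"  psi_TLP [MPa]       : {self.psi_tlp:8.3f}",
                f"  RWC_TLP [%]         : {self.rwc_tlp:8.2f}",
                f"  apoplastic fraction : {self.apoplastic_fraction:8.3f}",
                f"  osmotic line        : {self.n_points_osmotic_line} points, "
                f"R^2 = {self.r_squared_osmotic_line:.4f}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "leaf_id": self.curve.leaf_id,
            "treatment": self.curve.treatment,
            "pi100": self.pi100,
            "epsilon": self.epsilon,
            "psi_tlp": self.psi_tlp,
            "rwc_tlp": self.rwc_tlp,
            "apoplastic_fraction": self.apoplastic_fraction,
            "n_points_osmotic_line": self.n_points_osmotic_line,
            "r_squared_osmotic_line": self.r_squared_osmotic_line,
        }


def pv_parameter_table(per_leaf: pd.DataFrame) -> pd.DataFrame:
    """Treatment means ± SE of PV parameters from a per-leaf table.

    ``per_leaf`` should have one row per leaf with a ``treatment`` column
    and the parameter columns produced by
    :meth:`PressureVolumeResults.to_dict`.
    """
    params = ["pi100", "epsilon", "psi_tlp", "rwc_tlp"]
    rows = []
    for trt, grp in per_leaf.groupby("treatment"):
        row = {"treatment": trt, "n": len(grp)}
        for p in params:
            vals = grp[p].dropna()
            row[p] = vals.mean() if len(vals) else np.nan
            row[p + "_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("treatment")
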