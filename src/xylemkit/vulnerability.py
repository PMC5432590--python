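"""Xylem vulnerability curves.

A vulnerability curve (VC) relates the percent loss of hydraulic
conductivity (PLC) of a xylem segment to the stem water potential Ψs at
which it was measured. The package fits the two-parameter logistic

    PLC(Ψs) = 100 / (1 + exp(α (Ψs − PLC50)))

by nonlinear least squares (an optional free upper asymptote is
available), derives Ψ12 / Ψ88 and the midpoint slope (25·α, %/MPa), and
compares treatments through the linearized form

    ln(100/PLC − 1) = α (Ψs − PLC50)

fitted by ordinary least squares with treatment and Ψs×treatment
interaction effects.

The model/results split follows statsmodels: build a
:class:`VulnerabilityCurve` from data, call :meth:`~VulnerabilityCurve.fit`,
inspect the returned :class:`VulnerabilityCurveResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize as opt
import statsmodels.formula.api as smf

__all__ = [
    "VCFitError",
    "plc_sigmoid",
    "psi_at_plc",
    "linearize",
    "VulnerabilityCurve",
    "VulnerabilityCurveResults",
    "TreatmentComparisonResults",
    "compare_treatments",
]


class VCFitError(RuntimeError):
    """Nonlinear VC fit failed to converge.

    Carries the starting values and a data summary to make the failure
    diagnosable without re-running.
    """

    def __init__(self, message, start_params=None, data_summary=None):
        super().__init__(message)
        self.start_params = start_params
        self.data_summary = data_summary


def plc_sigmoid(psi_stem, alpha, plc50, plc_max=100.0):
    """Logistic vulnerability curve, PLC as a function of stem water potential.

    ``plc_max / (1 + exp(alpha * (psi_stem - plc50)))`` — strictly increasing
    as psi_stem becomes more negative, bounded in (0, plc_max), equal to
    ``plc_max / 2`` at ``psi_stem == plc50``.

    Parameters
    ----------
    psi_stem : float or array_like
        Stem water potential, MPa (negative under tension).
    alpha : float
        Steepness, MPa^-1; the absolute slope at the midpoint is
        ``plc_max * alpha / 4`` (25·alpha for the standard 100% asymptote).
    plc50 : float
        Water potential at 50% loss of conductivity, MPa.
    plc_max : float
        Upper asymptote, percent; 100 for the standard two-parameter form.
    """
    psi_stem = np.asarray(psi_stem, dtype=float)
    # clip the exponent to avoid overflow far out on the asymptotes
    z = np.clip(alpha * (psi_stem - plc50), -700.0, 700.0)
    out = plc_max / (1.0 + np.exp(z))
    return float(out) if out.ndim == 0 else out


def psi_at_plc(level, alpha, plc50):
    """Invert the sigmoid: Ψs at which PLC reaches ``level`` percent.

    Closed form ``plc50 + ln((100 - level)/level) / alpha``; levels 12 and 88
    are symmetric about plc50.
    """
    level = np.asarray(level, dtype=float)
    if np.any((level <= 0) | (level >= 100)):
        raise ValueError("level must lie strictly inside (0, 100)")
    out = plc50 + np.log((100.0 - level) / level) / alpha
    return float(out) if out.ndim == 0 else out


def linearize(observations: pd.DataFrame, plc_col: str = "plc"):
    """Transform PLC observations to the linearized response y = ln(100/PLC − 1).

    Observations with PLC exactly 0 or 100 have no finite transform and are
    excluded (counted, not raised); everything else passes through.

    Returns
    -------
    (DataFrame, int)
        The transformable rows with an added ``y`` column, and the number of
        excluded rows.
    """
    plc = observations[plc_col].to_numpy(dtype=float)
    ok = (plc > 0) & (plc < 100)
    out = observations.loc[ok].copy()
    out["y"] = np.log(100.0 / plc[ok] - 1.0)
    return out, int((~ok).sum())


def _start_params(psi, plc):
    """Deterministic, data-driven starting values for the sigmoid fit."""
    plc50_0 = float(psi[np.argmin(np.abs(plc - 50.0))])
    span = float(np.ptp(psi))
    alpha_0 = 4.0 / span if span > 0 else 1.0
    return alpha_0, plc50_0


class VulnerabilityCurve:
    """Sigmoidal vulnerability-curve model for (Ψs, PLC) observations.

    Parameters
    ----------
    psi_stem : array_like
        Stem water potentials, MPa (negative).
    plc : array_like
        Percent loss of conductivity in [0, 100].
    free_max : bool
        If True, fit a free upper asymptote (three parameters) instead of
        fixing it at 100. The two-parameter form is the default because the
        linearized treatment statistics are defined on it.

    Examples
    --------
    >>> vc = VulnerabilityCurve(psi, plc)
    >>> res = vc.fit(n_bootstrap=1000, seed=42)
    >>> res.plc50, res.slope_at_p50
    """

    def __init__(self, psi_stem, plc, free_max: bool = False):
        self.psi_stem = np.asarray(psi_stem, dtype=float)
        self.plc = np.asarray(plc, dtype=float)
        if self.psi_stem.shape != self.plc.shape or self.psi_stem.ndim != 1:
            raise ValueError("psi_stem and plc must be matching 1-d arrays")
        if len(self.psi_stem) < 4:
            raise ValueError("need at least 4 observations to fit a VC")
        if np.any((self.plc < 0) | (self.plc > 100)):
            raise ValueError("plc must lie in [0, 100]")
        self.free_max = free_max

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, psi_col="psi_stem", plc_col="plc", free_max=False
    ):
        return cls(data[psi_col], data[plc_col], free_max=free_max)

    @property
    def start_params(self):
        """(alpha0, plc50_0[, plc_max0]): PLC50 from the observation nearest
        50% loss, alpha from 4 / (Ψs range)."""
        a0, p0 = _start_params(self.psi_stem, self.plc)
        if self.free_max:
            return (a0, p0, max(float(self.plc.max()), 50.0))
        return (a0, p0)

    def _model(self, psi, *params):
        if self.free_max:
            return plc_sigmoid(psi, params[0], params[1], plc_max=params[2])
        return plc_sigmoid(psi, params[0], params[1])

    def fit(self, n_bootstrap: int = 0, seed=None) -> "VulnerabilityCurveResults":
        """Nonlinear least-squares fit; optional case-resampling bootstrap.

        Parameters
        ----------
        n_bootstrap : int
            Number of bootstrap resamples (observations resampled with
            replacement) for percentile confidence intervals; 0 disables.
        seed : int or numpy Generator, optional
            Seeds the bootstrap resampling.
        """
        p0 = self.start_params
        popt, pcov = self._fit_once(self.psi_stem, self.plc, p0)
        degenerate = bool(
            np.all(self.plc <= 50.0) or np.all(self.plc >= 50.0) or abs(popt[0]) < 1e-3
        )
        if degenerate:
            warnings.warn(
                "degenerate VC data (PLC does not span 50%% or curve is flat); "
                "confidence intervals will be wide",
                stacklevel=2,
            )
        boot = None
        if n_bootstrap:
            rng = np.random.default_rng(seed)
            n = len(self.psi_stem)
            draws = []
            for _ in range(n_bootstrap):
                idx = rng.integers(0, n, size=n)
                try:
                    b, _ = self._fit_once(self.psi_stem[idx], self.plc[idx], popt)
                except VCFitError:
                    continue
                draws.append(b)
            boot = np.asarray(draws)
        return VulnerabilityCurveResults(
            model=self,
            params=np.asarray(popt),
            cov_params=pcov,
            bootstrap_params=boot,
            degenerate=degenerate,
        )

    def _fit_once(self, psi, plc, p0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", opt.OptimizeWarning)
                popt, pcov = opt.curve_fit(
                    self._model, psi, plc, p0=p0, maxfev=10000
                )
        except (RuntimeError, opt.OptimizeWarning) as exc:
            raise VCFitError(
                f"vulnerability-curve fit did not converge: {exc}",
                start_params=p0,
                data_summary={
                    "n": len(psi),
                    "psi_range": (float(psi.min()), float(psi.max())),
                    "plc_range": (float(plc.min()), float(plc.max())),
                },
            ) from exc
        return popt, pcov


@dataclass
class VulnerabilityCurveResults:
    """Fitted vulnerability curve: estimates, uncertainty, derived points."""

    model: VulnerabilityCurve
    params: np.ndarray
    cov_params: np.ndarray
    bootstrap_params: np.ndarray | None = None
    degenerate: bool = False
    ci_level: float = field(default=0.95)

    @property
    def alpha(self) -> float:
        """Sigmoid steepness, MPa^-1."""
        return float(self.params[0])

    @property
    def plc50(self) -> float:
        """Water potential at 50% loss of conductivity, MPa."""
        return float(self.params[1])

    @property
    def plc_max(self) -> float:
        return float(self.params[2]) if self.model.free_max else 100.0

    @property
    def slope_at_p50(self) -> float:
        """Absolute slope of the curve at its midpoint, %/MPa (25·alpha for
        the fixed-asymptote form)."""
        return self.plc_max * self.alpha / 4.0

    @property
    def psi12(self) -> float:
        """Ψs at 12% loss of conductivity (air-entry-like point), MPa."""
        return self.psi_at(12.0)

    @property
    def psi88(self) -> float:
        """Ψs at 88% loss of conductivity, MPa."""
        return self.psi_at(88.0)

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors from the NLS covariance."""
        return np.sqrt(np.diag(self.cov_params))

    def predict(self, psi_stem):
        """PLC predicted by the fitted curve at the given Ψs."""
        return plc_sigmoid(psi_stem, self.alpha, self.plc50, plc_max=self.plc_max)

    def psi_at(self, level):
        """Ψs at which the fitted curve crosses ``level`` percent loss."""
        return psi_at_plc(level, self.alpha, self.plc50)

    def conf_int(self, level: float | None = None) -> pd.DataFrame:
        """Confidence intervals for (alpha, plc50).

        Bootstrap percentile intervals when a bootstrap was run, otherwise
        the normal approximation from the NLS covariance.
        """
        level = self.ci_level if level is None else level
        q = np.array([(1 - level) / 2, 1 - (1 - level) / 2])
        names = ["alpha", "plc50"] + (["plc_max"] if self.model.free_max else [])
        if self.bootstrap_params is not None and len(self.bootstrap_params):
            lo, hi = np.quantile(self.bootstrap_params, q, axis=0)
        else:
            z = -_norm_ppf((1 - level) / 2)
            lo = self.params - z * self.bse
            hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi}, index=names)

    @property
    def residuals(self) -> np.ndarray:
        return self.model.plc - self.predict(self.model.psi_stem)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Vulnerability curve fit (logistic, "
            + ("free asymptote)" if self.model.free_max else "asymptote fixed at 100%)"),
            f"  n observations      : {len(self.model.plc)}",
            f"  alpha  [MPa^-1]     : {self.alpha:8.3f}  "
            f"({ci.loc['alpha', 'lower']:.3f}, {ci.loc['alpha', 'upper']:.3f})",
            f"  PLC50  [MPa]        : {self.plc50:8.3f}  "
            f"({ci.loc['plc50', 'lower']:.3f}, {ci.loc['plc50', 'upper']:.3f})",
            f"  slope at P50 [%/MPa]: {self.slope_at_p50:8.1f}",
            f"  psi12  [MPa]        : {self.psi12:8.3f}",
            f"  psi88  [MPa]        : {self.psi88:8.3f}",
            f"  RMSE   [PLC]        : {np.sqrt(np.mean(self.residuals**2)):8.3f}",
        ]
        if self.degenerate:
            lines.append("  WARNING: degenerate data; estimates unreliable")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ci = self.conf_int()
        d = {
            "alpha": self.alpha,
            "plc50": self.plc50,
            "plc_max": self.plc_max,
            "slope_at_p50": self.slope_at_p50,
            "psi12": self.psi12,
            "psi88": self.psi88,
            "n": int(len(self.model.plc)),
            "degenerate": self.degenerate,
            "conf_int": {
                name: [float(ci.loc[name, "lower"]), float(ci.loc[name, "upper"])]
                for name in ci.index
            },
        }
        return d


def _norm_ppf(p):
    from scipy.stats import norm

    return norm.ppf(p)


@dataclass
class TreatmentComparisonResults:
    """Linearized VC regression across treatments.

    ``ols_results`` is the underlying statsmodels fit of
    ``y ~ psi_stem * C(treatment)`` on the linearized response; per-treatment
    (alpha, plc50) are back-solved from each treatment's line
    ``y = a·Ψs + b`` as alpha = a, plc50 = −b/a.
    """

    ols_results: object
    per_treatment: pd.DataFrame
    joint_fstat: float
    joint_pvalue: float
    interaction_pvalue: float
    n_excluded: int
    n_used: int

    def summary(self) -> str:
        lines = [
            "Treatment comparison on the linearized vulnerability curve",
            f"  observations used / excluded (PLC at 0 or 100): "
            f"{self.n_used} / {self.n_excluded}",
            f"  joint test, all treatment terms = 0: "
            f"F = {self.joint_fstat:.3f}, p = {self.joint_pvalue:.4g}",
            f"  interaction (slope) test p = {self.interaction_pvalue:.4g}",
            "",
            self.per_treatment.to_string(),
        ]
        return "\n".join(lines)


def compare_treatments(
    observations: pd.DataFrame,
    psi_col: str = "psi_stem",
    plc_col: str = "plc",
    group_col: str = "treatment",
    cov_type: str = "HC3",
) -> TreatmentComparisonResults:
    """Compare vulnerability curves between treatments on the linearized scale.

    Fits OLS ``ln(100/PLC − 1) ~ Ψs + treatment + Ψs:treatment`` and reports
    the joint Wald test that every treatment-involving coefficient is zero
    (i.e. that one common line fits all groups), plus the interaction-only
    test. Requires at least two treatments, each with at least three
    transformable observations (PLC strictly inside (0, 100)).

    The logit-like transform makes the error variance depend strongly on
    PLC (it diverges toward 0 and 100), so the Wald tests default to the
    HC3 heteroscedasticity-robust covariance; pass ``cov_type="nonrobust"``
    for the classical F-test.
    """
    data, n_excluded = linearize(observations, plc_col=plc_col)
    counts = data.groupby(group_col).size()
    if len(counts) < 2:
        raise ValueError("compare_treatments needs at least two treatments")
    thin = counts[counts < 3]
    if len(thin):
        raise ValueError(
            f"treatments with < 3 transformable observations: {list(thin.index)}"
        )
    data = data.rename(columns={psi_col: "_psi", group_col: "_trt"})
    ols = smf.ols("y ~ _psi * C(_trt)", data=data).fit(cov_type=cov_type)
    rank = np.linalg.matrix_rank(ols.model.exog)
    if rank < ols.model.exog.shape[1]:
        names = ols.model.exog_names
        raise ValueError(
            "rank-deficient design in treatment comparison; "
            f"collinear terms among: {names}"
        )
    trt_terms = [n for n in ols.params.index if "C(_trt)" in n]
    joint = ols.f_test([f"{t} = 0" for t in trt_terms])
    inter_terms = [t for t in trt_terms if "_psi:" in t or ":_psi" in t]
    inter = ols.f_test([f"{t} = 0" for t in inter_terms])

    rows = []
    levels = sorted(data["_trt"].unique())
    base = levels[0]
    for lev in levels:
        a = ols.params["_psi"]
        b = ols.params["Intercept"]
        if lev != base:
            a += ols.params.get(f"_psi:C(_trt)[T.{lev}]", 0.0)
            b += ols.params.get(f"C(_trt)[T.{lev}]", 0.0)
        rows.append(
            {
                "treatment": lev,
                "alpha": a,
                "plc50": -b / a if a != 0 else np.nan,
                "n": int(counts[lev]),
            }
        )
    per_treatment = pd.DataFrame(rows).set_index("treatment")
    return TreatmentComparisonResults(
        ols_results=ols,
        per_treatment=per_treatment,
        joint_fstat=float(joint.fvalue),
        joint_pvalue=float(joint.pvalue),
        interaction_pvalue=float(inter.pvalue),
        n_excluded=n_excluded,
        n_used=int(len(data)),
    )
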