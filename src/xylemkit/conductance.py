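"""Hydraulic conductances from raw measurements.

Percent loss of conductivity (PLC) of a xylem segment, Ohm's-law leaf and
whole-plant hydraulic conductances from gas exchange and water potentials,
and binning of daily-course records into stem-water-potential classes.

Conventions
-----------
Water potentials are stored as (negative) MPa throughout; transpiration E
is in mmol H2O m-2 s-1, so conductances come out in mmol m-2 s-1 MPa-1.
No unit inference is performed on input tables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "InvalidMeasurementError",
    "UndefinedConductanceError",
    "percent_loss_conductance",
    "leaf_conductance",
    "plant_conductance",
    "derive_conductances",
    "bin_by_psi",
    "read_gas_exchange",
]

GAS_EXCHANGE_COLUMNS = ("time", "E", "gs", "psi_leaf", "psi_stem", "treatment", "theta")


class InvalidMeasurementError(ValueError):
    """A hydraulic measurement violates its physical preconditions."""


class UndefinedConductanceError(ZeroDivisionError):
    """Ohm's-law conductance requested across a zero water-potential gradient."""


def percent_loss_conductance(k_initial, k_max):
    """Percent loss of hydraulic conductivity, ``100 * (1 - k_i / k_max)``.

    ``k_initial`` is the native (possibly embolized) conductance of the
    segment and ``k_max`` its conductance after flushing. Values are clamped
    to [0, 100]; ``k_initial > k_max`` (possible with measurement noise)
    clamps to 0 with a warning rather than rejecting the observation.

    Parameters
    ----------
    k_initial, k_max : float or array_like
        Conductances in any common flow unit; only their ratio matters.

    Returns
    -------
    float or ndarray
        PLC in percent, in [0, 100].
    """
    k_initial = np.asarray(k_initial, dtype=float)
    k_max = np.asarray(k_max, dtype=float)
    if np.any(k_max <= 0):
        raise InvalidMeasurementError("k_max must be > 0 for PLC")
    if np.any(k_initial < 0):
        raise InvalidMeasurementError("k_initial must be >= 0")
    raw = 100.0 * (1.0 - k_initial / k_max)
    if np.any(raw < 0):
        warnings.warn(
            "k_initial > k_max for some observations; PLC clamped to 0",
            stacklevel=2,
        )
    out = np.clip(raw, 0.0, 100.0)
    return float(out) if out.ndim == 0 else out


def _ohm_conductance(E, psi_up, psi_down, what):
    E = np.asarray(E, dtype=float)
    gradient = np.asarray(psi_up, dtype=float) - np.asarray(psi_down, dtype=float)
    if np.any(gradient == 0):
        raise UndefinedConductanceError(
            f"zero water-potential gradient: {what} undefined"
        )
    k = E / gradient
    if np.any(k < 0):
        warnings.warn(
            f"reversed water-potential gradient: negative {what} returned "
            "(filter downstream if undesired)",
            stacklevel=3,
        )
    return float(k) if k.ndim == 0 else k


def leaf_conductance(E, psi_stem, psi_leaf):
    """Leaf hydraulic conductance ``k_leaf = E / (psi_stem - psi_leaf)``.

    Ohm's-law analogy over the stem-to-leaf segment; E in mmol m-2 s-1 and
    potentials in MPa give k_leaf in mmol m-2 s-1 MPa-1 (leaf-area specific).
    A reversed gradient (psi_leaf > psi_stem) yields a negative value with a
    warning; exclusion is a pipeline-level decision, never silent.
    """
    return _ohm_conductance(E, psi_stem, psi_leaf, "k_leaf")


def plant_conductance(E, psi_predawn, psi_leaf):
    """Whole-plant hydraulic conductance ``k_plant = E / (psi_predawn - psi_leaf)``.

    As :func:`leaf_conductance` with pre-dawn water potential (the soil-side
    boundary) replacing stem water potential.
    """
    return _ohm_conductance(E, psi_predawn, psi_leaf, "k_plant")


def derive_conductances(records: pd.DataFrame) -> pd.DataFrame:
    """Add k_leaf / k_plant columns to a gas-exchange table.

    Expects columns ``E, psi_stem, psi_leaf`` and optionally ``psi_predawn``;
    rows with a zero gradient get NaN conductance and ``flag_zero_gradient``.
    Reversed gradients are kept (signed) and flagged in
    ``flag_reversed_gradient``.
    """
    out = records.copy()
    grad_leaf = out["psi_stem"] - out["psi_leaf"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["k_leaf"] = np.where(grad_leaf != 0, out["E"] / grad_leaf, np.nan)
    out["flag_zero_gradient"] = grad_leaf == 0
    out["flag_reversed_gradient"] = grad_leaf < 0
    if "psi_predawn" in out.columns and out["psi_predawn"].notna().any():
        grad_plant = out["psi_predawn"] - out["psi_leaf"]
        with np.errstate(divide="ignore", invalid="ignore"):
            out["k_plant"] = np.where(
                grad_plant != 0, out["E"] / grad_plant, np.nan
            )
        out.loc[grad_plant == 0, "flag_zero_gradient"] = True
        out.loc[grad_plant < 0, "flag_reversed_gradient"] = True
    return out


def bin_by_psi(records: pd.DataFrame, bin_width: float = 0.2) -> pd.DataFrame:
    """Average daily-course records within stem-water-potential classes.

    Classes are contiguous half-open intervals anchored at 0 MPa,
    ``(-(i+1)*w, -i*w]``, so a record at exactly ``-i*w`` falls in the wetter
    class. Per-class means and standard errors of k_leaf, k_plant and gs are
    reported; empty classes are omitted.

    Parameters
    ----------
    records : DataFrame
        Must contain ``psi_stem``; conductance columns (``k_leaf``,
        ``k_plant``) are computed on the fly via :func:`derive_conductances`
        if absent.
    bin_width : float
        Class width in MPa, > 0. The field convention leaves the width a
        user choice; 0.2 MPa is the default.

    Returns
    -------
    DataFrame
        One row per non-empty class with ``psi_class_center``, ``n`` and
        mean/SE columns for each available quantity.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if len(records) == 0:
        raise ValueError("no records to bin")
    df = records.copy()
    if "k_leaf" not in df.columns and {"E", "psi_stem", "psi_leaf"} <= set(df.columns):
        df = derive_conductances(df)
    df = df[np.isfinite(df["psi_stem"])]
    # index i such that psi in (-(i+1)w, -i w]; psi <= 0 expected
    idx = np.ceil(-df["psi_stem"].to_numpy() / bin_width).astype(int) - 1
    idx = np.maximum(idx, 0)  # psi == 0 joins the first class
    df = df.assign(_class=idx)
    rows = []
    for i, grp in df.groupby("_class", sort=True):
        row = {
            "psi_class_center": -(i + 0.5) * bin_width,
            "n": len(grp),
        }
        for col, out in (("k_leaf", "k_leaf"), ("k_plant", "k_plant"), ("gs", "gs_mean")):
            if col in grp.columns:
                vals = grp[col].dropna()
                row[out] = vals.mean() if len(vals) else np.nan
                row[out + "_se"] = (
                    vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
                )
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("psi_class_center", ascending=False)
    return out.reset_index(drop=True)


def read_gas_exchange(path) -> pd.DataFrame:
    """Read a gas-exchange daily-course CSV.

    Requires columns ``time, E, gs, psi_leaf, psi_stem, treatment, theta``;
    ``psi_predawn`` is optional (k_plant is simply unavailable without it).
    Basic physical invariants (E, gs >= 0; potentials <= 0; theta in
    [0, 100]) are validated.
    """
    df = pd.read_csv(path)
    missing = [c for c in GAS_EXCHANGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gas-exchange table missing columns: {missing}")
    if (df["E"] < 0).any() or (df["gs"] < 0).any():
        raise InvalidMeasurementError("E and gs must be non-negative")
    psi_cols = ["psi_leaf", "psi_stem"] + (
        ["psi_predawn"] if "psi_predawn" in df.columns else []
    )
    for c in psi_cols:
        if (df[c].dropna() > 0).any():
            raise InvalidMeasurementError(f"{c} must be <= 0 (MPa, tension)")
    if ((df["theta"] < 0) | (df["theta"] > 100)).any():
        raise InvalidMeasurementError("theta must lie in [0, 100] percent")
    return df
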