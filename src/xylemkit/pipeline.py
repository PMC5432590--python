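"""End-to-end study pipeline.

Ties the stages together the way the full analysis of a drought-acclimation
experiment is run: per-treatment vulnerability-curve fits plus the
linearized treatment comparison, pressure–volume parameter tables, anatomy
tables, binned conductance-versus-Ψs curves, and a "decoupling" summary
comparing where k_leaf has lost half of its wet-reference value against
where the petiole has lost half of its conductivity (PLC50). A positive
gap (k_leaf midpoint wetter than PLC50) indicates that leaf conductance
declines before substantial xylem embolism.

Every stochastic step receives its seed by deterministic fan-out from one
top-level seed, so a rerun with the same config reproduces every number.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import summarize_sections, vessel_class_distribution, equivalent_diameter
from .conductance import bin_by_psi, derive_conductances, read_gas_exchange
from .pressure_volume import PressureVolumeCurve, pv_parameter_table
from .vulnerability import VulnerabilityCurve, compare_treatments

__all__ = ["StudyConfig", "StudyReport", "run_study", "kleaf_decline_fit"]

logger = logging.getLogger("xylemkit.pipeline")


@dataclass
class StudyConfig:
    """Configuration of a full study run.

    File paths may be omitted (None): the corresponding stages are skipped
    with a logged notice. The top-level ``seed`` is fanned out to every
    stochastic stage and recorded in all outputs.
    """

    vc_file: str | None = None
    pv_file: str | None = None
    vessels_file: str | None = None
    sections_file: str | None = None
    gas_exchange_file: str | None = None
    output_dir: str = "study_out"
    group_col: str = "treatment"
    bin_width: float = 0.2
    n_bootstrap: int = 1000
    seed: int = 0
    free_max: bool = False
    make_plots: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        paths = [
            self.vc_file, self.pv_file, self.vessels_file,
            self.sections_file, self.gas_exchange_file,
        ]
        if not any(paths):
            raise ValueError("at least one input data kind must be configured")
        for p in paths:
            if p is not None and not pathlib.Path(p).exists():
                raise FileNotFoundError(p)
        if self.vessels_file and not self.sections_file:
            raise ValueError("vessels_file requires sections_file metadata")


@dataclass
class StudyReport:
    """Bundle of per-stage outputs produced by :func:`run_study`."""

    config: StudyConfig
    vc_models: dict = field(default_factory=dict)
    vc_comparison: object = None
    pv_per_leaf: pd.DataFrame | None = None
    pv_treatment_means: pd.DataFrame | None = None
    anatomy_sections: pd.DataFrame | None = None
    vessel_classes: pd.DataFrame | None = None
    binned_conductance: pd.DataFrame | None = None
    kleaf_fits: dict = field(default_factory=dict)
    decoupling: pd.DataFrame | None = None
    output_files: list = field(default_factory=list)


def kleaf_decline_fit(points: pd.DataFrame, n_bootstrap: int = 0, seed=None,
                      reference: float | None = None):
    """Fit the sigmoid decline of binned k_leaf against Ψs class center.

    k_leaf is converted to percent loss relative to ``reference``
    (defaulting to the mean of the wettest class, i.e. the least-negative
    ``psi_class_center``), then fitted with the vulnerability-curve
    machinery; the fitted ``plc50`` is the Ψs of 50% k_leaf loss. Flat or
    non-monotone series come back with the fit's ``degenerate`` flag set.

    Parameters
    ----------
    points : DataFrame
        Binned conductance table with ``psi_class_center`` and ``k_leaf``.
    reference : float, optional
        Maximal-k_leaf baseline against which percent loss is computed.
    """
    pts = points.dropna(subset=["k_leaf"]).sort_values(
        "psi_class_center", ascending=False
    )
    if len(pts) < 4:
        raise ValueError("need >= 4 binned points for a k_leaf decline fit")
    if reference is None:
        reference = float(pts["k_leaf"].iloc[0])
    if reference <= 0:
        raise ValueError("the k_leaf reference (wettest-class mean) must be positive")
    loss = 100.0 * (1.0 - pts["k_leaf"].to_numpy() / reference)
    loss = np.clip(loss, 0.0, 100.0)
    model = VulnerabilityCurve(pts["psi_class_center"].to_numpy(), loss)
    res = model.fit(n_bootstrap=n_bootstrap, seed=seed)
    return res


def _stage_seeds(seed: int, n: int = 8):
    """Deterministic per-stage 31-bit seeds from the top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_study(config: StudyConfig) -> StudyReport:
    """Run every stage for which input data is configured.

    Writes plain CSV/JSON outputs into ``config.output_dir`` and returns the
    in-memory :class:`StudyReport`. Missing inputs skip their stage with a
    logged notice, never silently.
    """
    config.validate()
    outdir = pathlib.Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = StudyReport(config=config)
    seeds = _stage_seeds(config.seed)

    def _write_json(name: str, payload: dict):
        path = outdir / name
        payload = {"seed": config.seed, **payload}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        report.output_files.append(str(path))

    def _write_csv(name: str, df: pd.DataFrame, index=False):
        path = outdir / name
        df.to_csv(path, index=index, float_format="%.10g")
        report.output_files.append(str(path))

    # --- vulnerability curves -------------------------------------------
    if config.vc_file:
        vc_data = pd.read_csv(config.vc_file)
        models = {}
        for i, (trt, grp) in enumerate(vc_data.groupby(config.group_col)):
            res = VulnerabilityCurve.from_dataframe(
                grp, free_max=config.free_max
            ).fit(n_bootstrap=config.n_bootstrap, seed=seeds[0] + i)
            models[trt] = res
        report.vc_models = models
        _write_json(
            "vc_models.json", {trt: res.to_dict() for trt, res in models.items()}
        )
        if vc_data[config.group_col].nunique() >= 2:
            report.vc_comparison = compare_treatments(
                vc_data, group_col=config.group_col
            )
            (outdir / "vc_comparison.txt").write_text(
                report.vc_comparison.summary() + "\n"
            )
            report.output_files.append(str(outdir / "vc_comparison.txt"))
    else:
        logger.info("no vulnerability-curve input configured; stage skipped")

    # --- pressure-volume curves -----------------------------------------
    if config.pv_file:
        pv_data = pd.read_csv(config.pv_file)
        rows = []
        for leaf, grp in pv_data.groupby("leaf_id"):
            curve = PressureVolumeCurve.from_dataframe(grp, leaf_id=leaf)
            rows.append(curve.fit().to_dict())
        report.pv_per_leaf = pd.DataFrame(rows)
        report.pv_treatment_means = pv_parameter_table(report.pv_per_leaf)
        _write_csv("pv_parameters.csv", report.pv_per_leaf)
        _write_csv("pv_treatment_means.csv", report.pv_treatment_means, index=True)
    else:
        logger.info("no pressure-volume input configured; stage skipped")

    # --- anatomy ---------------------------------------------------------
    if config.vessels_file:
        vessels = pd.read_csv(config.vessels_file)
        sections = pd.read_csv(config.sections_file)
        report.anatomy_sections = summarize_sections(vessels, sections)
        if "diameter_um" in vessels.columns:
            d = vessels["diameter_um"].to_numpy(dtype=float)
        else:
            d = equivalent_diameter(vessels["lumen_area_um2"].to_numpy(dtype=float))
        report.vessel_classes = vessel_class_distribution(d)
        _write_csv("anatomy_sections.csv", report.anatomy_sections, index=True)
        _write_csv("vessel_classes.csv", report.vessel_classes)
    else:
        logger.info("no anatomy input configured; stage skipped")

    # --- conductance daily courses --------------------------------------
    if config.gas_exchange_file:
        gx = read_gas_exchange(config.gas_exchange_file)
        gx = derive_conductances(gx)
        binned_all = []
        kleaf_fits = {}
        for j, (trt, grp) in enumerate(gx.groupby(config.group_col)):
            binned = bin_by_psi(grp, bin_width=config.bin_width)
            binned.insert(0, config.group_col, trt)
            binned_all.append(binned)
            try:
                kleaf_fits[trt] = kleaf_decline_fit(
                    binned, n_bootstrap=config.n_bootstrap, seed=seeds[1] + j
                )
            except ValueError as exc:
                logger.warning("k_leaf decline fit skipped for %s: %s", trt, exc)
        report.binned_conductance = pd.concat(binned_all, ignore_index=True)
        report.kleaf_fits = kleaf_fits
        _write_csv("conductance_binned.csv", report.binned_conductance)
    else:
        logger.info("no gas-exchange input configured; stage skipped")

    # --- decoupling summary (k_leaf decline vs PLC50) --------------------
    if report.vc_models and report.kleaf_fits:
        rows = []
        for trt in sorted(report.vc_models):
            if trt not in report.kleaf_fits:
                continue
            psi50_plc = report.vc_models[trt].plc50
            kf = report.kleaf_fits[trt]
            psi50_kleaf = kf.plc50
            rows.append(
                {
                    "treatment": trt,
                    "psi50_kleaf": psi50_kleaf,
                    "psi50_plc": psi50_plc,
                    "gap_mpa": psi50_kleaf - psi50_plc,
                    "kleaf_fit_degenerate": kf.degenerate,
                }
            )
        if rows:
            report.decoupling = pd.DataFrame(rows).set_index("treatment")
            _write_csv("decoupling.csv", report.decoupling, index=True)

    if config.make_plots:
        try:
            _overlay_plot(report, outdir)
        except Exception as exc:  # plotting is best-effort, never fatal
            logger.warning("plotting failed: %s", exc)

    _write_json("run_info.json", {"outputs": sorted(report.output_files)})
    return report


def _overlay_plot(report: StudyReport, outdir: pathlib.Path):
    """Optional overlay of the fitted PLC sigmoids and binned k_leaf."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(6, 4))
    psi = np.linspace(-2.5, 0.0, 200)
    for trt, res in report.vc_models.items():
        ax1.plot(psi, res.predict(psi), label=f"PLC {trt}")
    ax1.set_xlabel("stem water potential (MPa)")
    ax1.set_ylabel("PLC (%)")
    if report.binned_conductance is not None:
        ax2 = ax1.twinx()
        for trt, grp in report.binned_conductance.groupby(
            report.config.group_col
        ):
            ax2.plot(
                grp["psi_class_center"], grp["k_leaf"], "o--", label=f"k_leaf {trt}"
            )
        ax2.set_ylabel("k_leaf (mmol m$^{-2}$ s$^{-1}$ MPa$^{-1}$)")
    ax1.legend(loc="center left", fontsize=8)
    fig.tight_layout()
    fig.savefig(outdir / "overlay.png", dpi=120)
    plt.close(fig)
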