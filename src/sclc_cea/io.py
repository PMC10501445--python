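"""Configuration schema, file readers/writers and the end-to-end pipeline.

A single JSON configuration drives ``run_pipeline``: it either points at
digitized curve / risk-table CSVs per arm and endpoint, or at a synthetic
generation block; a ``params`` block overrides base-case model inputs; an
``analysis`` block sets WTP, PSA draws/seed, scenario discounts and the
CEAC grid.  The pipeline chains simulate -> reconstruct -> fit -> cohort
run -> analyses and writes ``results.json``, per-arm trace CSVs and a log
of seeds and settings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .km import DigitizedCurve, RiskTable, preprocess_curve, reconstruct_ipd
from .model import ENDPOINTS, CostEffectivenessModel
from .params import ARM_ACTIVE, ARM_CONTROL, ModelParams
from .survival import criterion_table, fit_all, select_model
from .synthetic import (
    DEFAULT_MEDIANS,
    DEFAULT_SHAPES,
    TrialDesign,
    calibrate_to_median,
    gen_digitized_fixture,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "run_pipeline",
    "read_ipd_csv",
    "write_ipd_csv",
    "read_curve_csv",
    "read_risk_csv",
]

IPD_COLUMNS = ["time_months", "event", "arm", "endpoint"]


class ConfigError(ValueError):
    """Configuration failed validation; the message itemises every problem."""


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

def read_ipd_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(IPD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"IPD CSV {path} lacks columns: {sorted(missing)}")
    return df[IPD_COLUMNS]


def write_ipd_csv(ipd: pd.DataFrame, path) -> None:
    ipd[IPD_COLUMNS].to_csv(path, index=False)


def read_curve_csv(path) -> DigitizedCurve:
    df = pd.read_csv(path)
    return preprocess_curve(df[["time_months", "survival"]].to_numpy())


def read_risk_csv(path) -> RiskTable:
    df = pd.read_csv(path)
    return RiskTable(df["time_months"].to_numpy(), df["n_risk"].to_numpy())


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBlock:
    n_total: int = 585
    allocation_ratio: tuple[int, int] = (2, 1)
    censor_time_months: float = 30.0
    seed: int = 20230831
    medians: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MEDIANS.items()})
    shapes: dict = field(default_factory=lambda: dict(DEFAULT_SHAPES))
    read_step_months: float = 0.5
    risk_step_months: float = 3.0
    max_time_months: float = 30.0
    noise_sd: float = 0.0


@dataclass
class AnalysisBlock:
    wtp: float = 37423.0
    psa_draws: int = 1000
    psa_seed: int = 20230831
    tornado: bool = True
    scenario_discounts: tuple[float, ...] = (0.2, 0.5, 0.8165)
    ceac_max: float = 200_000.0
    ceac_step: float = 2000.0


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    synthetic: SyntheticBlock | None = None
    curves: dict | None = None  # {arm: {endpoint: {"curve": path, "risk": path}}}
    params: ModelParams = field(default_factory=ModelParams)
    analysis: AnalysisBlock = field(default_factory=AnalysisBlock)
    output_dir: str = "results"

    def validate(self) -> "RunConfig":
        errs: list[str] = []
        if (self.synthetic is None) == (self.curves is None):
            errs.append("exactly one of 'synthetic' and 'curves' must be present")
        if self.curves is not None:
            for arm in (ARM_ACTIVE, ARM_CONTROL):
                for ep in ENDPOINTS:
                    blk = self.curves.get(arm, {}).get(ep)
                    if not blk:
                        errs.append(f"curves.{arm}.{ep} missing")
                        continue
                    for kind in ("curve", "risk"):
                        p = blk.get(kind)
                        if not p or not Path(p).exists():
                            errs.append(f"curves.{arm}.{ep}.{kind}: file not found: {p}")
        errs.extend(self.params.validation_errors())
        if self.analysis.wtp < 0:
            errs.append("analysis.wtp must be >= 0")
        if self.analysis.psa_draws < 1:
            errs.append("analysis.psa_draws must be >= 1")
        for d in self.analysis.scenario_discounts:
            if not 0.0 <= d <= 1.0:
                errs.append(f"analysis.scenario_discounts entry {d} outside [0, 1]")
        if errs:
            raise ConfigError("invalid configuration:\n  " + "\n  ".join(errs))
        return self


def _check_keys(d: dict, allowed: set[str], where: str, errs: list[str]) -> None:
    unknown = set(d) - allowed
    if unknown:
        errs.append(f"unknown keys in {where}: {sorted(unknown)}")


def config_from_dict(raw: dict) -> RunConfig:
    errs: list[str] = []
    _check_keys(raw, {"inputs", "params", "analysis", "output_dir"}, "top level", errs)

    synthetic = curves = None
    inputs = raw.get("inputs", {})
    _check_keys(inputs, {"synthetic", "curves"}, "inputs", errs)
    if "synthetic" in inputs:
        blk = dict(inputs["synthetic"])
        allowed = {f.name for f in dataclasses.fields(SyntheticBlock)}
        _check_keys(blk, allowed, "inputs.synthetic", errs)
        try:
            blk = {k: v for k, v in blk.items() if k in allowed}
            if "allocation_ratio" in blk:
                blk["allocation_ratio"] = tuple(blk["allocation_ratio"])
            synthetic = SyntheticBlock(**blk)
        except TypeError as e:
            errs.append(f"inputs.synthetic: {e}")
    if "curves" in inputs:
        curves = inputs["curves"]

    params = ModelParams()
    if "params" in raw:
        try:
            merged = params.to_dict()
            merged.update(raw["params"])
            params = ModelParams.from_dict(merged)
        except ValueError as e:
            errs.append(str(e))

    analysis = AnalysisBlock()
    if "analysis" in raw:
        blk = dict(raw["analysis"])
        allowed = {f.name for f in dataclasses.fields(AnalysisBlock)}
        _check_keys(blk, allowed, "analysis", errs)
        blk = {k: v for k, v in blk.items() if k in allowed}
        if "scenario_discounts" in blk:
            blk["scenario_discounts"] = tuple(blk["scenario_discounts"])
        analysis = AnalysisBlock(**blk)

    if errs:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errs))
    cfg = RunConfig(
        synthetic=synthetic,
        curves=curves,
        params=params,
        analysis=analysis,
        output_dir=raw.get("output_dir", "results"),
    )
    return cfg.validate()


def load_config(path) -> RunConfig:
    """Parse and validate a JSON run configuration."""
    with open(path) as fh:
        raw = json.load(fh)
    return config_from_dict(raw)


def dump_config(cfg: RunConfig, path) -> None:
    """Serialise a config so that load(dump(cfg)) round-trips."""
    raw: dict = {"output_dir": cfg.output_dir, "params": cfg.params.to_dict()}
    if cfg.synthetic is not None:
        raw["inputs"] = {"synthetic": dataclasses.asdict(cfg.synthetic)}
    else:
        raw["inputs"] = {"curves": cfg.curves}
    raw["analysis"] = dataclasses.asdict(cfg.analysis)
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=2, default=list)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _synthetic_inputs(blk: SyntheticBlock, outdir: Path) -> dict:
    """Generate digitized fixtures per arm/endpoint and write them to CSV."""
    design = TrialDesign(
        n_total=blk.n_total,
        allocation_ratio=tuple(blk.allocation_ratio),
        accrual_horizon_months=blk.censor_time_months,
        seed=blk.seed,
    )
    read_times = np.arange(0.0, blk.max_time_months + 1e-9, blk.read_step_months)
    risk_times = np.arange(0.0, blk.max_time_months + 1e-9, blk.risk_step_months)
    rng = np.random.default_rng(blk.seed)
    out: dict = {}
    for arm in (ARM_ACTIVE, ARM_CONTROL):
        out[arm] = {}
        for ep in ENDPOINTS:
            wb = calibrate_to_median(blk.medians[ep][arm], blk.shapes[ep])
            curve, risk = gen_digitized_fixture(
                wb, read_times, design, arm=arm, risk_times=risk_times,
                noise_sd=blk.noise_sd, rng=rng,
            )
            curve.to_frame().to_csv(outdir / f"curve_{arm}_{ep}.csv", index=False)
            risk.to_frame().to_csv(outdir / f"risk_{arm}_{ep}.csv", index=False)
            out[arm][ep] = (curve, risk)
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the report bundle; returns results dict."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"sclc_cea {__version__}"]

    # stage 1: inputs -------------------------------------------------------
    if cfg.synthetic is not None:
        inputs = _synthetic_inputs(cfg.synthetic, outdir)
        log_lines.append(f"synthetic inputs, seed={cfg.synthetic.seed}")
    else:
        inputs = {
            arm: {
                ep: (
                    read_curve_csv(cfg.curves[arm][ep]["curve"]),
                    read_risk_csv(cfg.curves[arm][ep]["risk"]),
                )
                for ep in ENDPOINTS
            }
            for arm in (ARM_ACTIVE, ARM_CONTROL)
        }
        log_lines.append("digitized curve inputs from files")

    # stage 2: reconstruction ----------------------------------------------
    ipd_frames = []
    for arm, by_ep in inputs.items():
        for ep, (curve, risk) in by_ep.items():
            try:
                ipd_frames.append(reconstruct_ipd(curve, risk, arm=arm, endpoint=ep))
            except Exception as e:
                raise RuntimeError(f"reconstruction failed for {arm}/{ep}: {e}") from e
    ipd = pd.concat(ipd_frames, ignore_index=True)
    write_ipd_csv(ipd, outdir / "ipd.csv")

    # stage 3: parametric fitting ------------------------------------------
    fits_report: dict = {}
    fits: dict[str, dict] = {}
    for arm in (ARM_ACTIVE, ARM_CONTROL):
        fits[arm] = {}
        for ep in ENDPOINTS:
            sub = ipd[(ipd["arm"] == arm) & (ipd["endpoint"] == ep)]
            try:
                candidates = fit_all(sub, endpoint=ep, arm=arm)
            except Exception as e:
                raise RuntimeError(f"survival fitting failed for {arm}/{ep}: {e}") from e
            chosen = select_model(candidates)
            fits[arm][ep] = chosen
            fits_report[f"{arm}_{ep}"] = {
                "selected": chosen.to_dict(),
                "criteria": criterion_table(candidates).to_dict(orient="records"),
            }
    (outdir / "fits.json").write_text(json.dumps(fits_report, indent=2))

    # stage 4: cohort model -------------------------------------------------
    params = cfg.params.replace(wtp=cfg.analysis.wtp)
    model = CostEffectivenessModel(fits, params)
    results = model.fit()
    for arm, trace in results.traces.items():
        trace.to_frame().to_csv(outdir / f"trace_{arm}.csv", index=False)

    base_block = results.to_dict()

    # stage 5: analyses -----------------------------------------------------
    out: dict = {"base_case": base_block}
    if cfg.analysis.tornado:
        tor = model.tornado()
        tor.to_csv(outdir / "tornado.csv", index=False)
        out["tornado"] = tor.to_dict(orient="records")

    psa = model.psa(n_draws=cfg.analysis.psa_draws, seed=cfg.analysis.psa_seed,
                    wtp=cfg.analysis.wtp)
    psa.draws.to_csv(outdir / "psa.csv", index=False)
    out["psa"] = psa.summary()
    grid = np.arange(0.0, cfg.analysis.ceac_max + 1e-9, cfg.analysis.ceac_step)
    curve = psa.ceac(grid)
    curve.to_csv(outdir / "ceac.csv", index=False)
    out["ceac"] = curve.to_dict(orient="records")
    log_lines.append(
        f"psa: n={cfg.analysis.psa_draws} seed={cfg.analysis.psa_seed} wtp={cfg.analysis.wtp}"
    )

    out["scenarios"] = []
    for d in cfg.analysis.scenario_discounts:
        sc = model.price_scenario(d)
        out["scenarios"].append(
            {
                "discount": d,
                "active": sc.active.to_dict(),
                "control": sc.control.to_dict(),
                "incremental": sc.report.to_dict(),
            }
        )
    thr = model.threshold_price(cfg.analysis.wtp)
    out["threshold_price"] = {
        "status": thr.status,
        "discount": thr.discount,
        "discount_closed_form": thr.discount_closed_form,
        "icer_at_discount": thr.icer_at_discount,
    }

    (outdir / "results.json").write_text(json.dumps(out, indent=2))
    log_lines.append("stages completed: inputs, reconstruct, fit, run, analyses")
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return out
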