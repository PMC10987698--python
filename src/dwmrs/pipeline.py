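"""End-to-end orchestration: simulate → preprocess → quantify → fit → stats.

One seeded configuration drives the whole chain deterministically. Each
stage communicates through the documented tidy tables, and a run directory
receives the resolved configuration, every stage's output and a log of
rejected shots, filtered metabolites and convergence flags.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as dio
from .diffusion import DecayCurve, GroupFit, build_decay, fit_group
from .preprocess import DEFAULT_REF_WINDOW, preprocess_shots
from .protocol import DEFAULT_PROTOCOL, AcquisitionProtocol
from .quantify import DEFAULT_FIT_WINDOW, filter_metabolites, fit_spectrum
from .simulate import CohortDataset, GroundTruth, WEEKS, default_truth, simulate_cohort
from .stats import StatsReport, rm_anova

log = logging.getLogger("dwmrs.pipeline")


class PreprocessSettings(BaseModel):
    model_config = ConfigDict(frozen=True)
    drop_threshold: float = 0.5
    ref_window: tuple[float, float] = DEFAULT_REF_WINDOW


class QuantifySettings(BaseModel):
    model_config = ConfigDict(frozen=True)
    window: tuple[float, float] = DEFAULT_FIT_WINDOW
    baseline_order: int = 2
    mode: str = "dmrs"  # CRLB filtering rule


class FitSettings(BaseModel):
    model_config = ConfigDict(frozen=True)
    d_assumed: float = 0.3  # μm²/ms, sets the cumulant-fit b-range


class StatsSettings(BaseModel):
    model_config = ConfigDict(frozen=True)
    n_comparisons: int | None = None  # default: number of retained metabolites
    posthoc: str = "pooled"


class PipelineConfig(BaseModel):
    """Validated, self-describing configuration of one pipeline run."""

    model_config = ConfigDict(frozen=True)

    seed: int
    n_animals: int = 5
    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL
    truth: GroundTruth | None = None  # None → study default with this seed
    preprocess: PreprocessSettings = Field(default_factory=PreprocessSettings)
    quantify: QuantifySettings = Field(default_factory=QuantifySettings)
    fit: FitSettings = Field(default_factory=FitSettings)
    stats: StatsSettings = Field(default_factory=StatsSettings)

    def resolved_truth(self) -> GroundTruth:
        return self.truth if self.truth is not None else default_truth(seed=self.seed)


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: CohortDataset
    quant: pd.DataFrame
    retained: list[str]
    curves: pd.DataFrame
    fits: dict[str, dict[str, dict[str, GroupFit]]]  # week -> metab -> model -> fit
    cohort_table: pd.DataFrame
    reports: dict[str, StatsReport]
    rejections: list[dict] = dc_field(default_factory=list)
    out_dir: Path | None = None


def quantify_cohort(config: PipelineConfig, ds: CohortDataset):
    """Preprocess and quantify every (animal, week, b); returns the tidy
    quantification table and the shot-rejection records."""
    reference = ds.basis.reference_spectrum()
    pp, qs = config.preprocess, config.quantify
    rows, rejections = [], []
    for animal in ds.animals:
        for week in WEEKS:
            shots = ds.shots(animal, week)
            for b in config.protocol.b_values:
                mean, n_eff, drifts, report = preprocess_shots(
                    shots.spectra[b], config.protocol,
                    drop_threshold=pp.drop_threshold,
                    ref_window=pp.ref_window,
                    reference=reference,
                )
                if report.removed:
                    rejections.append(
                        {"animal": animal, "week": week, "b_value": b,
                         "removed": list(report.removed)}
                    )
                    log.info(
                        "rejected %d/%d shots (animal=%s %s b=%g)",
                        len(report.removed), len(report.amplitudes), animal, week, b,
                    )
                res = fit_spectrum(
                    mean, ds.basis,
                    window=qs.window, baseline_order=qs.baseline_order,
                )
                for m in ds.basis.names:
                    rows.append(
                        (animal, week, b, m, res.amplitudes[m], res.crlb_pct[m],
                         res.residual_rms, res.snr, n_eff)
                    )
    quant = pd.DataFrame(
        rows,
        columns=["animal", "week", "b_value", "metabolite", "amplitude",
                 "crlb_pct", "residual_rms", "snr", "n_shots_eff"],
    )
    return quant, rejections


def _fit_cohort(config: PipelineConfig, quant: pd.DataFrame, retained: list[str]):
    """Per-animal decay curves and both model fits, per week and metabolite."""
    curves_rows = []
    fits: dict[str, dict[str, dict[str, GroupFit]]] = {}
    animals = sorted(quant["animal"].unique())
    for week in WEEKS:
        fits[week] = {}
        for m in retained:
            per_animal: dict[str, DecayCurve] = {}
            for animal in animals:
                sub = quant[(quant["animal"] == animal) & (quant["week"] == week)]
                curve = build_decay(sub, m, b_values=config.protocol.b_values)
                per_animal[animal] = curve
                for b, s in zip(curve.b, curve.s_norm):
                    curves_rows.append((animal, week, m, b, s))
            fits[week][m] = {
                "sticks": fit_group(per_animal, m, model="sticks"),
                "cumulant": fit_group(
                    per_animal, m, model="cumulant", d_assumed=config.fit.d_assumed
                ),
            }
            for model, gf in fits[week][m].items():
                for animal, f in gf.per_animal.items():
                    if not f.converged:
                        log.warning(
                            "non-converged %s fit: %s %s %s", model, animal, week, m
                        )
    curves = pd.DataFrame(
        curves_rows, columns=["animal", "week", "metabolite", "b_value", "s_norm"]
    )
    return curves, fits


def build_cohort_table(
    quant: pd.DataFrame,
    fits: dict,
    retained: list[str],
    b_min: float,
) -> pd.DataFrame:
    """Long parameter table (animal, timepoint, metabolite, parameter, value).

    Concentration is the quantified amplitude at the lowest b-value;
    d_intra comes from the per-animal sticks fit, adc and kurtosis from the
    per-animal cumulant fit.
    """
    rows = []
    base = quant[np.isclose(quant["b_value"], b_min)]
    for week in WEEKS:
        for m in retained:
            sub = base[(base["week"] == week) & (base["metabolite"] == m)]
            for _, r in sub.iterrows():
                rows.append((r["animal"], week, m, "conc", r["amplitude"]))
            for animal, f in fits[week][m]["sticks"].per_animal.items():
                rows.append((animal, week, m, "d_intra", f.d_intra))
            for animal, f in fits[week][m]["cumulant"].per_animal.items():
                rows.append((animal, week, m, "adc", f.adc))
                rows.append((animal, week, m, "kurtosis", f.kurtosis))
    return pd.DataFrame(
        rows, columns=["animal", "timepoint", "metabolite", "parameter", "value"]
    )


def cohort_table_from_artifacts(quant: pd.DataFrame, fits_doc: dict) -> pd.DataFrame:
    """Rebuild the long parameter table from the on-disk stage artifacts
    (quantification CSV frame + fits JSON document)."""
    b_min = quant["b_value"].min()
    base = quant[np.isclose(quant["b_value"], b_min)]
    metabolites = sorted(
        set.intersection(*(set(w) for w in fits_doc["weeks"].values()))
    )
    rows = []
    for week, per_met in fits_doc["weeks"].items():
        for m in metabolites:
            sub = base[(base["week"] == week) & (base["metabolite"] == m)]
            for _, r in sub.iterrows():
                rows.append((r["animal"], week, m, "conc", r["amplitude"]))
            models = per_met[m]
            for a, f in models.get("sticks", {}).get("per_animal", {}).items():
                rows.append((a, week, m, "d_intra", f["d_intra"]))
            for a, f in models.get("cumulant", {}).get("per_animal", {}).items():
                rows.append((a, week, m, "adc", f["adc"]))
                rows.append((a, week, m, "kurtosis", f["kurtosis"]))
    return pd.DataFrame(
        rows, columns=["animal", "timepoint", "metabolite", "parameter", "value"]
    )


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> PipelineResult:
    """Execute the whole chain deterministically from one seed.

    When ``out_dir`` is given, the resolved configuration and every stage's
    output are written there (quant.csv, curves.csv, fits.json, stats.json,
    truth_table.csv, run.log).
    """
    handler = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logging.getLogger("dwmrs").addHandler(handler)
        logging.getLogger("dwmrs").setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        if handler is not None:
            logging.getLogger("dwmrs").removeHandler(handler)
            handler.close()


def _run(config: PipelineConfig, out_dir: Path | None) -> PipelineResult:
    truth = config.resolved_truth()
    ds = simulate_cohort(config.protocol, truth, config.n_animals, seed=config.seed)
    log.info("simulated cohort: %d animals, noise_sd=%.4g", config.n_animals, ds.noise_sd)

    quant, rejections = quantify_cohort(config, ds)
    retained = filter_metabolites(quant, mode=config.quantify.mode)
    dropped = sorted(set(ds.basis.names) - set(retained))
    log.info("CRLB filter (%s): retained %s; excluded %s",
             config.quantify.mode, retained, dropped)
    if not retained:
        raise RuntimeError("quantify stage: no metabolite passed the CRLB filter")

    curves, fits = _fit_cohort(config, quant, retained)
    cohort_table = build_cohort_table(quant, fits, retained, config.protocol.b_min)

    n_cmp = config.stats.n_comparisons or len(retained)
    reports = {
        p: rm_anova(cohort_table, p, n_comparisons=n_cmp, posthoc=config.stats.posthoc)
        for p in ("conc", "d_intra", "adc", "kurtosis")
    }

    result = PipelineResult(
        config=config, dataset=ds, quant=quant, retained=retained, curves=curves,
        fits=fits, cohort_table=cohort_table, reports=reports,
        rejections=rejections, out_dir=out_dir,
    )
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def fits_to_dict(fits: dict, d_assumed: float) -> dict:
    out: dict = {"d_assumed": d_assumed, "weeks": {}}
    for week, per_met in fits.items():
        out["weeks"][week] = {}
        for m, models in per_met.items():
            out["weeks"][week][m] = {
                model: {
                    "per_animal": {
                        a: dataclasses.asdict(f) for a, f in gf.per_animal.items()
                    },
                    "mean": gf.mean_params,
                    "sd": gf.sd_params,
                    "group_average_curve": dataclasses.asdict(gf.average_curve_fit),
                }
                for model, gf in models.items()
            }
    return out


def stats_to_dict(reports: dict[str, StatsReport]) -> dict:
    return {
        "parameters": {
            p: {
                "anova": {k: dataclasses.asdict(v) for k, v in r.anova.items()},
                "posthoc": [dataclasses.asdict(l) for l in r.posthoc],
                "n_comparisons": r.n_comparisons,
            }
            for p, r in reports.items()
        }
    }


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    cfg = result.config
    resolved = cfg.model_copy(update={"truth": cfg.resolved_truth()})
    dio.write_json({"config": resolved.model_dump(mode="json")},
                   out_dir / "config.json", "config")
    dio.write_csv(result.quant, out_dir / "quant.csv", "quant")
    dio.write_csv(result.curves, out_dir / "curves.csv", "curves")
    result.dataset.truth_table.to_csv(out_dir / "truth_table.csv", index=False)
    dio.write_json(
        fits_to_dict(result.fits, cfg.fit.d_assumed), out_dir / "fits.json", "fits"
    )
    dio.write_json(stats_to_dict(result.reports), out_dir / "stats.json", "stats")
    dio.write_json(
        {"retained": result.retained, "rejections": result.rejections},
        out_dir / "report.json", "report",
    )
    log.info("outputs written to %s", out_dir)
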