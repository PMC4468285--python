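"""End-to-end run orchestration.

Stages, in order: simulate (or ingest) a cohort -> validate tables -> fit
the Cole model per subject -> exclude artefact-contaminated fits by the
|Td| <= 0.5 ns rule -> apply the six TBW predictors -> agreement report
(pooled and by sex) and the correlation-vs-frequency sweep.  All stage
outputs are written as CSV plus a JSON run summary with the exclusion
bookkeeping; a rerun with the same config and seed is byte-identical
(timestamps live only in the log).

The headline agreement report uses only the Td-kept subset for every
method, mirroring a single artefact-free comparison set; the
``include_all_subjects`` flag additionally emits the unfiltered
single-frequency prediction table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from .cohort import SimConfig, Subject, simulate_cohort, cohort_table, spectra_table
from .cole import (
    FREQ_MAX_HZ,
    FREQ_MIN_HZ,
    ColeParams,
    ImpedanceSpectrum,
    artifact_filter,
    fit_cole,
)
from .predictors import METHODS, predict_all
from .agreement import frequency_sweep, stratified_report

__all__ = ["RunConfig", "RunResult", "validate_inputs", "run"]

logger = logging.getLogger("biswater")

COHORT_REQUIRED = ("id", "sex", "age", "height_cm", "weight_kg", "tbw_dilution_l")
SPECTRA_REQUIRED = ("id", "frequency_hz", "r_ohm", "xc_ohm")


@dataclass(frozen=True)
class RunConfig:
    mode: str = "simulate"  # "simulate" | "ingest"
    cohort_csv: str | None = None
    spectra_csv: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    td_threshold_ns: float = 0.5
    methods: tuple[str, ...] = METHODS
    n_boot: int = 2000
    seed: int = 0
    out_dir: str = "biswater_run"
    include_all_subjects: bool = False
    force: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError(f"mode must be 'simulate' or 'ingest', got {self.mode!r}")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.mode == "ingest":
            for name in ("cohort_csv", "spectra_csv"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{name} required in ingest mode: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key-value config; generator fields carry a ``sim_`` prefix."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config must be a flat mapping: {path}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim_kwargs = {
            k[4:]: v for k, v in raw.items() if k.startswith("sim_")
        }
        run_kwargs = {k: v for k, v in raw.items() if not k.startswith("sim_")}
        if "methods" in run_kwargs and isinstance(run_kwargs["methods"], str):
            run_kwargs["methods"] = tuple(
                m.strip() for m in run_kwargs["methods"].split(",") if m.strip()
            )
        elif "methods" in run_kwargs:
            run_kwargs["methods"] = tuple(run_kwargs["methods"])
        sim = SimConfig(**sim_kwargs)
        return cls(sim=sim, **run_kwargs)


@dataclass
class RunResult:
    cohort: pd.DataFrame
    spectra: pd.DataFrame
    fits: pd.DataFrame
    predictions: pd.DataFrame
    report: pd.DataFrame
    sweep: pd.DataFrame | None
    summary: dict


def validate_inputs(
    cohort: pd.DataFrame, spectra: pd.DataFrame
) -> list[str]:
    """Schema/unit/grid checks; a non-empty result should block a run."""
    issues: list[str] = []
    for col in COHORT_REQUIRED:
        if col not in cohort.columns:
            issues.append(f"cohort table missing column {col!r}")
    for col in SPECTRA_REQUIRED:
        if col not in spectra.columns:
            issues.append(f"spectra table missing column {col!r}")
    if issues:
        return issues

    dup = cohort["id"][cohort["id"].duplicated()].tolist()
    if dup:
        issues.append(f"duplicate subject ids in cohort table: {dup[:5]}")
    bad_sex = set(cohort["sex"]) - {"male", "female"}
    if bad_sex:
        issues.append(f"unrecognised sex values: {sorted(bad_sex)}")
    if (cohort["height_cm"] < 3).any():
        issues.append(
            "height_cm values < 3: heights look like metres, expected centimetres"
        )
    for col in ("height_cm", "weight_kg", "tbw_dilution_l"):
        if (cohort[col] <= 0).any():
            issues.append(f"non-positive values in {col}")

    cohort_ids = set(cohort["id"])
    spec_ids = set(spectra["id"])
    if cohort_ids - spec_ids:
        issues.append(f"subjects without spectra: {sorted(cohort_ids - spec_ids)[:5]}")
    if spec_ids - cohort_ids:
        issues.append(f"spectra without cohort rows: {sorted(spec_ids - cohort_ids)[:5]}")

    for sid, grp in spectra.groupby("id", sort=False):
        f = grp["frequency_hz"].to_numpy(dtype=float)
        if np.any(np.diff(f) <= 0):
            issues.append(f"{sid}: frequencies not strictly increasing")
            continue
        if f[0] < FREQ_MIN_HZ or f[-1] > FREQ_MAX_HZ:
            issues.append(f"{sid}: frequencies outside the 5 kHz - 1 MHz band")
        for target, lo, hi in ((50e3, 40e3, 60e3), (100e3, 80e3, 125e3)):
            if not np.any((f >= lo) & (f <= hi)):
                issues.append(
                    f"{sid}: no grid point near {target/1e3:.0f} kHz — "
                    "interpolation of the single-frequency readout is unreliable"
                )
        if (grp["r_ohm"] <= 0).any():
            issues.append(f"{sid}: non-positive resistance values")
    return issues


def _subjects_from_table(cohort: pd.DataFrame) -> dict[str, Subject]:
    return {
        row.id: Subject(
            id=str(row.id),
            sex=str(row.sex),
            age=float(row.age),
            height_cm=float(row.height_cm),
            weight_kg=float(row.weight_kg),
        )
        for row in cohort.itertuples(index=False)
    }


def _spectra_from_table(spectra: pd.DataFrame) -> dict[str, ImpedanceSpectrum]:
    out = {}
    for sid, grp in spectra.groupby("id", sort=False):
        out[str(sid)] = ImpedanceSpectrum(
            frequencies=grp["frequency_hz"].to_numpy(dtype=float),
            r_ohm=grp["r_ohm"].to_numpy(dtype=float),
            xc_ohm=grp["xc_ohm"].to_numpy(dtype=float),
        )
    return out


def _fit_stage(
    subjects: dict[str, Subject],
    spectra: dict[str, ImpedanceSpectrum],
    td_threshold_ns: float,
) -> tuple[pd.DataFrame, dict[str, ColeParams]]:
    rows = []
    fitted: dict[str, ColeParams] = {}
    for sid in subjects:
        params, diag = fit_cole(spectra[sid])
        kept = diag.converged and artifact_filter(params, td_threshold_ns)
        if diag.converged:
            fitted[sid] = params
        rows.append(
            {
                "id": sid,
                "r0_ohm": params.r0_ohm,
                "rinf_ohm": params.rinf_ohm,
                "fc_hz": params.fc_hz,
                "alpha": params.alpha,
                "td_ns": params.td_ns,
                "residual_rms": diag.residual_rms,
                "converged": diag.converged,
                "kept_by_td_filter": kept,
            }
        )
    return pd.DataFrame(rows), fitted


def _predict_stage(
    subjects: dict[str, Subject],
    spectra: dict[str, ImpedanceSpectrum],
    fits: dict[str, ColeParams],
    cohort: pd.DataFrame,
    methods: tuple[str, ...],
    ids: list[str],
) -> pd.DataFrame:
    ref = cohort.set_index("id")
    rows = []
    for sid in ids:
        preds = predict_all(subjects[sid], spectra[sid], fits.get(sid), methods)
        for p in preds:
            rows.append(
                {
                    "id": sid,
                    "sex": subjects[sid].sex,
                    "method": p.method,
                    "ecw_l": p.ecw_l,
                    "icw_l": p.icw_l,
                    "tbw_pred_l": p.tbw_l,
                    "tbw_reference_l": float(ref.loc[sid, "tbw_dilution_l"]),
                    "qc_flags": ";".join(p.qc_flags),
                }
            )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> RunResult:
    """Execute all stages and write artifacts to ``config.out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path) -> RunResult:
    if config.mode == "simulate":
        sim = replace(config.sim, seed=config.sim.seed or config.seed)
        logger.info("simulating cohort: n=%d seed=%d", sim.n_subjects, sim.seed)
        records = simulate_cohort(sim)
        cohort = cohort_table(records)
        spectra = spectra_table(records)
    else:
        logger.info("ingesting %s / %s", config.cohort_csv, config.spectra_csv)
        cohort = pd.read_csv(config.cohort_csv, float_precision="round_trip")
        spectra = pd.read_csv(config.spectra_csv, float_precision="round_trip")

    issues = validate_inputs(cohort, spectra)
    for issue in issues:
        logger.warning("input issue: %s", issue)
    if issues and not config.force:
        raise ValueError(
            f"input validation failed with {len(issues)} issue(s); "
            f"first: {issues[0]} (use force to override)"
        )

    subjects = _subjects_from_table(cohort)
    spec_map = _spectra_from_table(spectra)
    fits, fitted = _fit_stage(subjects, spec_map, config.td_threshold_ns)

    n_input = len(fits)
    n_excluded_fit = int((~fits["converged"]).sum())
    kept_ids = fits.loc[fits["kept_by_td_filter"], "id"].tolist()
    n_kept = len(kept_ids)
    n_excluded_td = n_input - n_kept - n_excluded_fit
    logger.info(
        "exclusion accounting: n_input=%d n_kept=%d n_excluded_td=%d n_excluded_fit=%d",
        n_input, n_kept, n_excluded_td, n_excluded_fit,
    )

    if n_kept == 0:
        raise ValueError("no subjects pass the Td artefact filter; nothing to report")

    predictions = _predict_stage(
        subjects, spec_map, fitted, cohort, config.methods, kept_ids
    )
    report = stratified_report(predictions, n_boot=config.n_boot, seed=config.seed)

    sweep_df = None
    sweep_ids = [sid for sid in kept_ids if "ecw_dilution_l" in cohort.columns]
    if len(sweep_ids) >= 3 and "ecw_dilution_l" in cohort.columns:
        ref = cohort.set_index("id")
        sweep = frequency_sweep(
            [subjects[s].height_cm for s in sweep_ids],
            [spec_map[s] for s in sweep_ids],
            [fitted[s] for s in sweep_ids],
            [float(ref.loc[s, "tbw_dilution_l"]) for s in sweep_ids],
            [float(ref.loc[s, "ecw_dilution_l"]) for s in sweep_ids],
        )
        sweep_df = sweep.to_frame()

    summary = {
        "mode": config.mode,
        "seed": config.seed,
        "td_threshold_ns": config.td_threshold_ns,
        "methods": list(config.methods),
        "n_input": n_input,
        "n_kept": n_kept,
        "n_excluded_td": n_excluded_td,
        "n_excluded_fit": n_excluded_fit,
        "n_boot": config.n_boot,
    }

    cohort.to_csv(out_dir / "cohort.csv", index=False)
    spectra.to_csv(out_dir / "spectra.csv", index=False)
    fits.to_csv(out_dir / "cole_fits.csv", index=False)
    predictions.to_csv(out_dir / "predictions.csv", index=False)
    report.to_csv(out_dir / "agreement_report.csv", index=False)
    if sweep_df is not None:
        sweep_df.to_csv(out_dir / "frequency_sweep.csv", index=False)
    if config.include_all_subjects:
        all_preds = _predict_stage(
            subjects, spec_map, fitted, cohort, config.methods, fits["id"].tolist()
        )
        all_preds.to_csv(out_dir / "predictions_all_subjects.csv", index=False)
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    logger.info("run complete: outputs in %s", out_dir)

    return RunResult(
        cohort=cohort,
        spectra=spectra,
        fits=fits,
        predictions=predictions,
        report=report,
        sweep=sweep_df,
        summary=summary,
    )
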