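"""Stage runner behind the command line: synth → simulate → fit → predict →
validate → report, each stage writing its artifact into one output
directory and logging a JSON manifest line.

Stages read their upstream artifacts from the same directory; a missing
upstream fails with the stage name, and a stage that raises removes its
partial outputs so reruns stay clean. Reruns with the same config and seed
are byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

from . import fixtures, io
from .estimate import fit_membrane, predict_rejection_grid, validate
from .reporting import summarize_rejections
from .simulate import simulate_batch
from .synth import NoiseModel, generate_experiment
from .transport import Conditions
from .units import bar_to_pa, rpm_to_rad_s

logger = logging.getLogger("sdmcell")

STAGES = ("synth", "simulate", "fit", "predict", "validate", "report")

# default held-out conditions exercised by the validate stage:
# (membrane-agnostic pressure/rpm pairs off the 10 bar / 300-450 rpm grid)
DEFAULT_VALIDATION_CONDITIONS = ((8.0, 250.0), (6.0, 500.0), (9.0, 200.0), (12.0, 500.0))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _configure_logging(verbose: bool) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def _manifest(out_dir: Path, entry: dict) -> None:
    entry = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), **entry}
    with open(out_dir / "manifest.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def _guarded(stage: str, out_dir: Path, outputs: list[Path], fn):
    try:
        result = fn()
    except FileNotFoundError as exc:
        for p in outputs:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, f"missing upstream artifact: {exc}") from exc
    except Exception as exc:
        for p in outputs:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc
    _manifest(out_dir, {"stage": stage, "outputs": [str(p) for p in outputs]})
    return result


def run_pipeline(
    config: io.RunConfig,
    out_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
    seed: int = 0,
    verbose: bool = False,
) -> dict[str, Path]:
    """Execute the requested stages in canonical order; return artifact paths."""
    _configure_logging(verbose)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _manifest(out_dir, {"event": "run", "stages": stages, "seed": seed})
    solutes = config.solutes()
    truth = config.membrane()
    artifacts: dict[str, Path] = {}

    if "synth" in stages:
        rec_dir = out_dir / "records"

        def do_synth():
            for i, rpm in enumerate(fixtures.STIRRING_SPEEDS_RPM):
                cond = Conditions(
                    delta_p=config.conditions.delta_p,
                    stirring_speed=rpm_to_rad_s(rpm),
                    temperature=config.conditions.temperature,
                )
                rec = generate_experiment(
                    truth, cond, config.geometry, config.feed, solutes,
                    NoiseModel(config.noise_cv, config.noise_cv,
                               seed=(seed * 1000 + i) % (2**31)),
                    label=f"{config.membrane_class} {rpm:g} rpm",
                    stop_vcf=config.stop_vcf,
                    sample_interval=config.sample_interval,
                )
                io.write_record(rec, rec_dir)
                logger.info("synth: wrote record %s", rec.label)

        _guarded("synth", out_dir, [rec_dir], do_synth)
        artifacts["synth"] = rec_dir

    if "simulate" in stages:
        path = out_dir / "trajectory.csv"

        def do_simulate():
            traj = simulate_batch(
                config.feed, truth, config.conditions, config.geometry, solutes,
                permeate_step=config.permeate_step,
                stop_vcf=config.stop_vcf,
                sample_interval=config.sample_interval,
            )
            traj.to_frame().to_csv(path, index=False)
            logger.info("simulate: %d samples, termination=%s",
                        len(traj.samples), traj.termination)

        _guarded("simulate", out_dir, [path], do_simulate)
        artifacts["simulate"] = path

    fitted_path = out_dir / "fitted_membrane.json"
    if "fit" in stages:

        def do_fit():
            rec_dir = out_dir / "records"
            csvs = sorted(rec_dir.glob("*.csv")) if rec_dir.is_dir() else []
            if not csvs:
                raise FileNotFoundError(f"no experiment records in {rec_dir}")
            records = [io.read_record(p) for p in csvs]
            fitted = fit_membrane(
                records, solutes,
                name=f"{config.membrane_class}-fitted",
                membrane_class=config.membrane_class,
            )
            io.write_membrane(fitted, fitted_path)
            logger.info("fit: Lv=%.4e, %d Ls values", fitted.Lv,
                        len(fitted.Ls_by_solute))

        _guarded("fit", out_dir, [fitted_path], do_fit)
        artifacts["fit"] = fitted_path

    if "predict" in stages:
        path = out_dir / "predictions.csv"

        def do_predict():
            if not fitted_path.exists():
                raise FileNotFoundError(fitted_path)
            fitted = io.read_membrane(fitted_path)
            grid = predict_rejection_grid(
                fitted, solutes,
                pressures_bar=[6.0, 8.0, 10.0, 12.0],
                rpms=[200.0, 300.0, 450.0, 500.0],
                feed=config.feed,
                geometry=config.geometry,
                temperature=config.conditions.temperature,
                stop_vcf=config.stop_vcf,
            )
            grid.to_csv(path, index=False)
            logger.info("predict: %d grid cells", len(grid))

        _guarded("predict", out_dir, [path], do_predict)
        artifacts["predict"] = path

    if "validate" in stages:
        path = out_dir / "validation.json"

        def do_validate():
            if not fitted_path.exists():
                raise FileNotFoundError(fitted_path)
            fitted = io.read_membrane(fitted_path)
            val_records = []
            for i, (p_bar, rpm) in enumerate(DEFAULT_VALIDATION_CONDITIONS):
                cond = Conditions(
                    delta_p=bar_to_pa(p_bar),
                    stirring_speed=rpm_to_rad_s(rpm),
                    temperature=config.conditions.temperature,
                )
                val_records.append(
                    generate_experiment(
                        truth, cond, config.geometry, config.feed, solutes,
                        NoiseModel(config.noise_cv, config.noise_cv,
                                   seed=(seed * 1000 + 500 + i) % (2**31)),
                        label=f"validation {p_bar:g} bar {rpm:g} rpm",
                        stop_vcf=config.stop_vcf,
                        sample_interval=config.sample_interval,
                    )
                )
            report = validate(fitted, val_records, solutes)
            report.to_json(path)
            logger.info("validate: n=%d rmse=%.5f", report.n, report.rmse)

        _guarded("validate", out_dir, [path], do_validate)
        artifacts["validate"] = path

    if "report" in stages:
        path = out_dir / "summary.json"

        def do_report():
            table = (
                fixtures.load_nf_rejections()
                if config.membrane_class == "NF"
                else fixtures.load_ro_rejections()
            )
            summary = summarize_rejections(table)
            payload = summary.to_dict()
            payload["metadata"] = {"membrane_class": config.membrane_class,
                                   "seed": seed}
            path.write_text(json.dumps(payload, indent=2))
            logger.info("report: mean rejection %.2f%%",
                        summary.mean_rejection_pct_rounded)

        _guarded("report", out_dir, [path], do_report)
        artifacts["report"] = path

    return artifacts
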