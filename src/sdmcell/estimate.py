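"""Permeability estimation, grid prediction and RMSE validation.

This module inverts the forward model: given stirred-cell experiment
records (flux series by VCF plus run-averaged observed rejections), it
derives the membrane water permeability Lv and the per-solute permeability
Ls, predicts observed rejection over arbitrary pressure/stirring grids,
and scores predictions against held-out experiments with the root mean
square error

    RMSE = sqrt( (1/n) Σ (y_pred − y_true)² ).

Fitting conventions
-------------------
Lv comes from the flux series: each sampled (Jv, Cb, Cp) for the salt fixes
the surface concentration Cm through film theory, hence the effective
driving pressure ΔP − (π(Cm) − π(Cp)), and Lv follows by least squares over
the points.

Ls for a trace solute is fit in rejection space: the model rejection for a
record is the run average of the trace closed form Jv_i/(Jv_i + Ls·e^(Jv_i/k))
over the record's own flux samples, and Ls minimizes the sum of squared
rejection residuals across records (a single single-sample record reduces to
the analytic inversion Ls = Jv(1−R)/(R·e^(Jv/k))). The osmotically active
salt feeds back on the flux, so its Ls is fit by re-simulating the batch run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .simulate import simulate_batch
from .transport import (
    CellGeometry,
    Conditions,
    FeedState,
    Membrane,
    Solute,
    mass_transfer_coefficient,
    osmotic_pressure,
)
from .units import lmh_to_m_s

LS_BOUNDS = (0.0, 1e-3)  # m/s; spans well beyond observed NF/RO values


class InfeasibleObservationError(ValueError):
    """Observed flux/rejection imply a driving pressure <= 0."""


@dataclass
class ExperimentRecord:
    """One stirred-cell run: conditions, flux series and averaged rejections.

    ``flux_series`` columns: ``vcf``, ``water_flux_LMH`` and, for solutes
    with measured concentrations, ``<name>_feed_mg_L`` / ``<name>_permeate_mg_L``.
    ``rejections`` are run-averaged observed rejections as fractions.
    """

    label: str
    conditions: Conditions
    geometry: CellGeometry
    feed: FeedState
    flux_series: pd.DataFrame
    rejections: dict[str, float]

    def __post_init__(self) -> None:
        for name, r in self.rejections.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{self.label}: rejection for {name!r} outside [0,1]")
        if (self.flux_series["water_flux_LMH"] <= 0).any():
            raise ValueError(f"{self.label}: non-positive flux in series")


@dataclass
class LsFit:
    """Fitted solute permeability with an identifiability flag.

    When every observed rejection sits at 0 or 1 the data only bound Ls;
    ``value`` then carries the bound and ``identifiable`` is False.
    """

    value: float  # m/s
    identifiable: bool = True
    note: str = ""


@dataclass
class ValidationReport:
    n: int
    rmse: float
    records: list[dict] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {"n": self.n, "rmse": self.rmse, "records": self.records}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean square error between two equal-length vectors."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have the same length")
    if p.size == 0:
        raise ValueError("rmse undefined for n = 0")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def _series_points(record: ExperimentRecord, solute_name: str):
    """(Jv, Cb, Cp) in SI from a record's flux series for one solute."""
    df = record.flux_series
    Jv = lmh_to_m_s(df["water_flux_LMH"].to_numpy(dtype=float))
    cb = df[f"{solute_name}_feed_mg_L"].to_numpy(dtype=float) * 1e-3
    cp = df[f"{solute_name}_permeate_mg_L"].to_numpy(dtype=float) * 1e-3
    return Jv, cb, cp


def fit_Lv(
    record: ExperimentRecord,
    solutes: dict[str, Solute],
    salt_name: str = "NaCl",
) -> float:
    """Water permeability from a flux series with measured salt passage.

    For each sample, film theory lifts the observed (Jv, Cb, Cp) to the
    surface concentration Cm = Cp + (Cb − Cp)·e^(Jv/k); the effective
    driving pressure is then d = ΔP − (π(Cm) − π(Cp)) and the least-squares
    slope of Jv on d over the points gives Lv.
    """
    salt = solutes[salt_name]
    k = mass_transfer_coefficient(salt, record.conditions, record.geometry)
    Jv, cb, cp = _series_points(record, salt_name)
    cm = cp + (cb - cp) * np.exp(Jv / k)
    T = record.conditions.temperature
    dpi = np.array(
        [
            osmotic_pressure(m, salt, T) - osmotic_pressure(p, salt, T)
            for m, p in zip(cm, cp)
        ]
    )
    driving = record.conditions.delta_p - dpi
    if np.any(driving <= 0):
        raise InfeasibleObservationError(
            f"{record.label}: inferred osmotic pressure exceeds ΔP at some samples"
        )
    return float(np.dot(Jv, driving) / np.dot(driving, driving))


def invert_Ls(observed_rejection: float, Jv: float, k: float) -> float:
    """Analytic Ls from one observed rejection at known flux and k.

    Inverts R = Jv/(Jv + Ls·e^(Jv/k)): Ls = Jv (1 − R) / (R e^(Jv/k)).
    """
    if not 0.0 < observed_rejection <= 1.0:
        if observed_rejection == 0.0:
            raise ValueError("R = 0 implies infinite solute permeability")
        raise ValueError("observed rejection must lie in (0, 1]")
    if Jv <= 0 or k <= 0:
        raise ValueError("Jv and k must be > 0")
    return Jv * (1.0 - observed_rejection) / (observed_rejection * np.exp(Jv / k))


def _trace_model_rejection(record: ExperimentRecord, solute: Solute, Ls: float) -> float:
    """Run-averaged trace-solute rejection predicted on the record's flux series."""
    k = mass_transfer_coefficient(solute, record.conditions, record.geometry)
    Jv = lmh_to_m_s(record.flux_series["water_flux_LMH"].to_numpy(dtype=float))
    return float(np.mean(Jv / (Jv + Ls * np.exp(Jv / k))))


def _salt_model_rejection(
    record: ExperimentRecord,
    membrane: Membrane,
    solutes: dict[str, Solute],
    salt_name: str,
    Ls: float,
) -> float:
    """Run-averaged salt rejection from a full batch re-simulation."""
    feed = FeedState(
        record.feed.volume,
        {salt_name: record.feed.concentration_by_solute[salt_name]},
    )
    stop_vp = float(record.flux_series["permeate_volume_mL"].iloc[-1]) * 1e-6
    traj = simulate_batch(
        feed,
        membrane.with_Ls(salt_name, Ls),
        record.conditions,
        record.geometry,
        solutes,
        stop_volume=stop_vp,
        stop_vcf=None,
    )
    return traj.run_average_rejections()[salt_name]


def fit_Ls(
    records: Sequence[ExperimentRecord],
    solute: Solute,
    membrane: Membrane | None = None,
    solutes: dict[str, Solute] | None = None,
    salt_name: str = "NaCl",
    bounds: tuple[float, float] = LS_BOUNDS,
) -> LsFit:
    """Least-squares Ls over one or more records, in rejection space.

    Trace solutes use the closed-form forward model on each record's flux
    series; the osmotically active salt (which sets the flux itself) is
    re-simulated and needs ``membrane`` (with Lv) and the solute registry.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    obs = np.array([r.rejections[solute.name] for r in records])
    eps = 1e-12
    if np.all(obs >= 1.0 - eps):
        return LsFit(0.0, identifiable=False,
                     note="all rejections at 1: data only bound Ls near 0")
    if np.all(obs <= eps):
        return LsFit(bounds[1], identifiable=False,
                     note="all rejections at 0: Ls unbounded above")

    if solute.osmotically_active:
        if membrane is None or solutes is None:
            raise ValueError("salt fitting needs membrane (Lv) and solute registry")

        def model(ls: float) -> np.ndarray:
            return np.array(
                [_salt_model_rejection(r, membrane, solutes, salt_name, ls)
                 for r in records]
            )
    else:

        def model(ls: float) -> np.ndarray:
            return np.array([_trace_model_rejection(r, solute, ls) for r in records])

    lo = max(bounds[0], 1e-16)
    hi = bounds[1]
    if len(records) == 1:
        # mean model rejection is strictly decreasing in Ls: bracketed root
        target = obs[0]

        def f(ls: float) -> float:
            return model(ls)[0] - target

        if f(hi) > 0:
            return LsFit(hi, identifiable=False, note="rejection below model range")
        ls = brentq(f, lo, hi, xtol=1e-300, rtol=8.9e-16)
        return LsFit(float(ls))

    def residuals(x: np.ndarray) -> np.ndarray:
        return model(10.0 ** x[0]) - obs

    # log-scale parameterization keeps the search well-conditioned across
    # the ~3 decades separating NF and RO permeabilities
    x0 = np.log10(
        np.clip(
            invert_Ls(
                float(np.clip(np.mean(obs), 1e-6, 1 - 1e-9)),
                float(np.mean(lmh_to_m_s(records[0].flux_series["water_flux_LMH"]))),
                mass_transfer_coefficient(solute, records[0].conditions,
                                          records[0].geometry),
            ),
            lo,
            hi,
        )
    )
    sol = least_squares(
        residuals,
        x0=[x0],
        bounds=([np.log10(lo)], [np.log10(hi)]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    return LsFit(float(10.0 ** sol.x[0]))


def fit_membrane(
    records: Sequence[ExperimentRecord],
    solutes: dict[str, Solute],
    name: str,
    membrane_class: str,
    salt_name: str = "NaCl",
) -> Membrane:
    """Fit Lv (pooled over records) and every solute's Ls; return the membrane."""
    records = list(records)
    num = 0.0
    den = 0.0
    for rec in records:
        salt = solutes[salt_name]
        k = mass_transfer_coefficient(salt, rec.conditions, rec.geometry)
        Jv, cb, cp = _series_points(rec, salt_name)
        cm = cp + (cb - cp) * np.exp(Jv / k)
        T = rec.conditions.temperature
        dpi = np.array(
            [osmotic_pressure(m, salt, T) - osmotic_pressure(p, salt, T)
             for m, p in zip(cm, cp)]
        )
        driving = rec.conditions.delta_p - dpi
        if np.any(driving <= 0):
            raise InfeasibleObservationError(f"{rec.label}: ΔP <= inferred Δπ")
        num += float(np.dot(Jv, driving))
        den += float(np.dot(driving, driving))
    Lv = num / den
    membrane = Membrane(name, membrane_class, Lv, {})
    # the salt first (it alone shapes the flux), then the trace compounds
    salt_fit = fit_Ls(records, solutes[salt_name], membrane, solutes, salt_name)
    membrane = membrane.with_Ls(salt_name, salt_fit.value)
    for sname, solute in solutes.items():
        if sname == salt_name:
            continue
        if any(sname in rec.rejections for rec in records):
            usable = [rec for rec in records if sname in rec.rejections]
            membrane = membrane.with_Ls(sname, fit_Ls(usable, solute).value)
    return membrane


def predict_rejection_grid(
    membrane: Membrane,
    solutes: dict[str, Solute],
    pressures_bar: Sequence[float],
    rpms: Sequence[float],
    feed: FeedState,
    geometry: CellGeometry,
    temperature: float = 298.15,
    stop_vcf: float = 10.0,
) -> pd.DataFrame:
    """Run-averaged predicted rejection for every (solute, ΔP, rpm) cell.

    Grid points where the applied pressure cannot overcome the feed osmotic
    pressure are kept in the table, marked ``feasible=False`` with NaN
    predictions rather than silently dropped.
    """
    from .units import bar_to_pa, rpm_to_rad_s
    from .transport import NoPositiveFluxError

    if len(pressures_bar) == 0 or len(rpms) == 0:
        raise ValueError("pressure and rpm grids must be nonempty")
    rows = []
    for p_bar in pressures_bar:
        for rpm in rpms:
            cond = Conditions(
                delta_p=bar_to_pa(p_bar),
                stirring_speed=rpm_to_rad_s(rpm),
                temperature=temperature,
            )
            try:
                traj = simulate_batch(
                    feed, membrane, cond, geometry, solutes, stop_vcf=stop_vcf
                )
                avg = traj.run_average_rejections()
                feasible = True
            except NoPositiveFluxError:
                avg = {name: float("nan") for name in feed.concentration_by_solute}
                feasible = False
            for name in feed.concentration_by_solute:
                rows.append(
                    {
                        "solute": name,
                        "pressure_bar": p_bar,
                        "rpm": rpm,
                        "predicted_rejection_pct": avg[name] * 100.0,
                        "feasible": feasible,
                    }
                )
    return pd.DataFrame(rows)


def validate(
    membrane: Membrane,
    validation_records: Sequence[ExperimentRecord],
    solutes: dict[str, Solute],
) -> ValidationReport:
    """Predict each held-out record's rejections and score with RMSE.

    Predictions re-simulate the batch run under the record's own conditions
    with the fitted membrane; the RMSE pools every (record, solute) pair, in
    rejection-fraction units.
    """
    validation_records = list(validation_records)
    if not validation_records:
        raise ValueError("empty validation set")
    preds: list[float] = []
    obs: list[float] = []
    rec_entries = []
    for rec in validation_records:
        traj = simulate_batch(
            rec.feed, membrane, rec.conditions, rec.geometry, solutes,
            stop_volume=float(rec.flux_series["permeate_volume_mL"].iloc[-1]) * 1e-6,
            stop_vcf=None,
        )
        avg = traj.run_average_rejections()
        entry = {"label": rec.label, "solutes": {}}
        for name, r_obs in rec.rejections.items():
            r_pred = avg[name]
            preds.append(r_pred)
            obs.append(r_obs)
            entry["solutes"][name] = {"predicted": r_pred, "observed": r_obs}
        rec_entries.append(entry)
    return ValidationReport(n=len(preds), rmse=rmse(preds, obs), records=rec_entries)
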