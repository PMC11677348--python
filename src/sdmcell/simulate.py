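"""Dead-end stirred-cell batch filtration, integrated over permeate volume.

The cell starts with a fixed feed charge; permeate withdrawal concentrates
the feed, raising its osmotic pressure and dragging the solvent flux down —
the characteristic flux-decline-versus-VCF shape of dead-end filtration.
Everything is indexed by the volume concentration factor

    VCF = Vf / (Vf − Vp),

the ratio of initial feed volume to remaining (concentrated) volume.

Integration is quasi-steady: at each permeate-volume increment the local
transport system is re-solved and the feed solute masses advanced with a
classical RK4 step on dM/dVp = −Cp(M, V), dV/dVp = −1. Elapsed time is
recovered as dt = dVp / (Jv·A). Cumulative permeate mass is accumulated
from the exact per-step decrements, so the solute mass balance

    feed mass + cumulative permeate mass = initial mass

holds to floating-point round-off at every sample point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .transport import (
    CellGeometry,
    Conditions,
    FeedState,
    Membrane,
    NoPositiveFluxError,
    Solute,
    solve_local_transport,
)
from .units import ML_TO_M3, m_s_to_lmh


def vcf(initial_feed_volume: float, permeate_volume: float) -> float:
    """Volume concentration factor Vf / (Vf − Vp)."""
    if permeate_volume < 0:
        raise ValueError("permeate volume must be >= 0")
    if permeate_volume >= initial_feed_volume:
        raise ValueError("permeate volume must be below the initial feed volume")
    return initial_feed_volume / (initial_feed_volume - permeate_volume)


@dataclass(frozen=True)
class SamplePoint:
    """One permeate sample along a batch run."""

    cumulative_permeate_volume: float  # Vp, m³
    vcf: float
    water_flux_lmh: float
    elapsed_time_s: float
    feed_concentrations: dict[str, float]  # kg/m³
    permeate_sample_concentrations: dict[str, float]  # instantaneous Cp, kg/m³
    cumulative_permeate_concentrations: dict[str, float]  # kg/m³
    rejections: dict[str, float]  # instantaneous observed, fraction


@dataclass
class Trajectory:
    """Ordered samples plus the provenance needed to reproduce them."""

    samples: list[SamplePoint]
    geometry: CellGeometry
    membrane: Membrane
    conditions: Conditions
    permeate_step: float  # m³
    termination: str = "stop_volume"
    initial_masses: dict[str, float] = field(default_factory=dict)  # kg

    def mass_balance_error(self) -> float:
        """Largest relative solute-mass imbalance over all samples."""
        worst = 0.0
        for pt in self.samples:
            v_feed = self.geometry.initial_feed_volume - pt.cumulative_permeate_volume
            for name, m0 in self.initial_masses.items():
                if m0 == 0.0:
                    continue
                m_feed = pt.feed_concentrations[name] * v_feed
                m_perm = (
                    pt.cumulative_permeate_concentrations[name]
                    * pt.cumulative_permeate_volume
                )
                worst = max(worst, abs(m_feed + m_perm - m0) / m0)
        return worst

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as CSV-ready columns (mL, LMH, mg/L at the boundary)."""
        names = list(self.initial_masses)
        rows = []
        for pt in self.samples:
            row = {
                "vcf": pt.vcf,
                "permeate_volume_mL": pt.cumulative_permeate_volume / ML_TO_M3,
                "water_flux_LMH": pt.water_flux_lmh,
                "elapsed_time_s": pt.elapsed_time_s,
            }
            for n in names:
                row[f"{n}_feed_mg_L"] = pt.feed_concentrations[n] / 1e-3
                row[f"{n}_permeate_mg_L"] = pt.permeate_sample_concentrations[n] / 1e-3
            rows.append(row)
        return pd.DataFrame(rows)

    def run_average_rejections(self) -> dict[str, float]:
        """Per-solute mean of instantaneous observed rejections over samples."""
        names = list(self.samples[0].rejections)
        return {
            n: float(np.mean([pt.rejections[n] for pt in self.samples]))
            for n in names
        }


def simulate_batch(
    feed: FeedState,
    membrane: Membrane,
    conditions: Conditions,
    geometry: CellGeometry,
    solutes: dict[str, Solute],
    permeate_step: float = 1.0 * ML_TO_M3,
    stop_volume: float | None = None,
    stop_vcf: float | None = 10.0,
    sample_interval: float = 30.0 * ML_TO_M3,
    surface_osmotic: bool = True,
) -> Trajectory:
    """Integrate a dead-end stirred-cell run and sample every ``sample_interval``.

    The run stops at ``stop_volume`` (or the volume implied by ``stop_vcf``,
    default VCF 10) or earlier if the driving pressure is exhausted, in which
    case the trajectory is truncated and flagged ``termination='zero_flux'``.
    Samples are taken at exact multiples of ``sample_interval`` (plus the
    initial state at VCF 1); ``permeate_step`` must not exceed it.
    """
    Vf = feed.volume
    if stop_volume is None:
        if stop_vcf is None or stop_vcf < 1:
            raise ValueError("need stop_volume or stop_vcf >= 1")
        stop_volume = Vf * (1.0 - 1.0 / stop_vcf)
    if not 0 < stop_volume < Vf:
        raise ValueError("stop volume must lie in (0, initial feed volume)")
    if permeate_step <= 0 or permeate_step > sample_interval:
        raise ValueError("need 0 < permeate_step <= sample_interval")

    names = list(feed.concentration_by_solute)
    masses = {n: feed.concentration_by_solute[n] * Vf for n in names}
    initial_masses = dict(masses)
    cum_perm = {n: 0.0 for n in names}
    Vp = 0.0
    elapsed = 0.0
    samples: list[SamplePoint] = []
    termination = "stop_volume"
    last_Jv: float | None = None

    def local_state(vp: float, m: dict[str, float]):
        v = Vf - vp
        fs = FeedState(v, {n: m[n] / v for n in names})
        return solve_local_transport(
            fs, membrane, conditions, geometry, solutes,
            surface_osmotic=surface_osmotic, initial_Jv=last_Jv,
        )

    def record(state) -> None:
        v = Vf - Vp
        cb = {n: masses[n] / v for n in names}
        cp = {n: state.solutes[n].Cp for n in names}
        cum = {n: (cum_perm[n] / Vp if Vp > 0 else cp[n]) for n in names}
        rej = {n: (1.0 - cp[n] / cb[n]) if cb[n] > 0 else float("nan") for n in names}
        samples.append(
            SamplePoint(
                cumulative_permeate_volume=Vp,
                vcf=vcf(Vf, Vp),
                water_flux_lmh=m_s_to_lmh(state.Jv),
                elapsed_time_s=elapsed,
                feed_concentrations=cb,
                permeate_sample_concentrations=cp,
                cumulative_permeate_concentrations=cum,
                rejections=rej,
            )
        )

    try:
        state = local_state(Vp, masses)
    except NoPositiveFluxError:
        raise NoPositiveFluxError("no positive flux at the initial feed state")
    last_Jv = state.Jv
    record(state)

    # march sample boundary by sample boundary so samples land exactly
    boundaries = np.arange(sample_interval, stop_volume + 0.5 * permeate_step,
                           sample_interval)
    # guard against float noise duplicating the final boundary
    if boundaries.size == 0 or boundaries[-1] < stop_volume - 1e-9 * sample_interval:
        boundaries = np.append(boundaries, stop_volume)

    stopped = False
    for boundary in boundaries:
        span = boundary - Vp
        n_sub = max(1, int(np.ceil(span / permeate_step - 1e-9)))
        h = span / n_sub
        for _ in range(n_sub):
            try:
                # RK4 on dM/dVp = −Cp(M, Vp)
                s1 = local_state(Vp, masses)
                k1 = {n: -s1.solutes[n].Cp for n in names}
                m2 = {n: masses[n] + 0.5 * h * k1[n] for n in names}
                s2 = local_state(Vp + 0.5 * h, m2)
                k2 = {n: -s2.solutes[n].Cp for n in names}
                m3 = {n: masses[n] + 0.5 * h * k2[n] for n in names}
                s3 = local_state(Vp + 0.5 * h, m3)
                k3 = {n: -s3.solutes[n].Cp for n in names}
                m4 = {n: masses[n] + h * k3[n] for n in names}
                s4 = local_state(Vp + h, m4)
                k4 = {n: -s4.solutes[n].Cp for n in names}
            except NoPositiveFluxError:
                termination = "zero_flux"
                stopped = True
                break
            for n in names:
                dm = (h / 6.0) * (k1[n] + 2 * k2[n] + 2 * k3[n] + k4[n])
                masses[n] += dm
                cum_perm[n] -= dm  # exact mirror of the feed decrement
            elapsed += h / (s1.Jv * geometry.membrane_area)
            last_Jv = s1.Jv
            Vp += h
        if stopped:
            break
        state = local_state(Vp, masses)
        last_Jv = state.Jv
        record(state)

    traj = Trajectory(
        samples=samples,
        geometry=geometry,
        membrane=membrane,
        conditions=conditions,
        permeate_step=permeate_step,
        termination=termination,
        initial_masses=initial_masses,
    )
    return traj
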