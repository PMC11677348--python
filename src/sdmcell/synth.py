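"""Synthetic experiment generation.

Wraps the forward simulator with a measurement model so the whole
fit → predict → validate chain can be exercised against known ground truth.
The measurement model is multiplicative lognormal noise on the sampled
water flux and on the sampled permeate concentrations — both quantities are
strictly positive and their errors scale with magnitude — with independent
coefficients of variation and a fixed seed for reproducibility.

``study_emulation_suite`` reproduces the emulated study's design: 300 mL of
500 mg/L NaCl + 13 pharmaceuticals at 50 ng/L, a 14.6 cm² membrane, 10 bar,
25 °C, runs at 300 and 450 rpm sampled every 30 mL, with the packaged
fitted Ls table as the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fixtures
from .estimate import ExperimentRecord
from .simulate import simulate_batch
from .transport import CellGeometry, Conditions, FeedState, Membrane, Solute


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise.

    ``flux_cv`` / ``rejection_cv`` are fractional coefficients of variation
    applied to sampled water flux and permeate concentrations respectively.
    """

    flux_cv: float = 0.01
    rejection_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flux_cv < 0 or self.rejection_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if self.flux_cv >= 1 or self.rejection_cv >= 1:
            raise ValueError("noise CV >= 1 is unphysical for this model")

    def _factors(self, rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
        if cv == 0:
            return np.ones(n)
        sigma = np.sqrt(np.log1p(cv * cv))  # lognormal with unit mean, CV=cv
        return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def generate_experiment(
    true_membrane: Membrane,
    conditions: Conditions,
    geometry: CellGeometry,
    feed: FeedState,
    solutes: dict[str, Solute],
    noise: NoiseModel,
    label: str = "synthetic",
    stop_vcf: float = 10.0,
    sample_interval: float = fixtures.SAMPLE_INTERVAL_M3,
) -> ExperimentRecord:
    """Simulate one batch run and corrupt its observables with noise.

    Feed-side concentrations are kept exact (in practice they follow from
    the mass balance); sampled flux and permeate concentrations get
    independent multiplicative noise, and the record's run-averaged
    rejections are recomputed from the noisy permeate samples.
    """
    traj = simulate_batch(
        feed, true_membrane, conditions, geometry, solutes,
        stop_vcf=stop_vcf, sample_interval=sample_interval,
    )
    df = traj.to_frame()
    rng = np.random.default_rng(noise.seed)
    n = len(df)
    df["water_flux_LMH"] *= noise._factors(rng, noise.flux_cv, n)

    names = list(feed.concentration_by_solute)
    rejections: dict[str, float] = {}
    for name in names:
        noisy_cp = df[f"{name}_permeate_mg_L"].to_numpy() * noise._factors(
            rng, noise.rejection_cv, n
        )
        df[f"{name}_permeate_mg_L"] = noisy_cp
        cb = df[f"{name}_feed_mg_L"].to_numpy()
        rejections[name] = float(np.mean(1.0 - noisy_cp / cb))

    return ExperimentRecord(
        label=label,
        conditions=conditions,
        geometry=geometry,
        feed=feed,
        flux_series=df,
        rejections=rejections,
    )


def study_emulation_suite(
    seed: int = 0,
    membrane_class: str = "NF",
    noise_cv: float = 0.01,
) -> tuple[Membrane, list[ExperimentRecord]]:
    """Two-record suite (300 and 450 rpm) emulating the reference study.

    Returns the generating (ground-truth) membrane alongside the records so
    recovery can be scored. ``noise_cv=0`` gives noise-free records.
    """
    membrane = fixtures.reference_membrane(membrane_class)
    solutes = fixtures.load_solutes()
    geometry = fixtures.study_geometry()
    feed = fixtures.study_feed()
    records = []
    for i, rpm in enumerate(fixtures.STIRRING_SPEEDS_RPM):
        noise = NoiseModel(flux_cv=noise_cv, rejection_cv=noise_cv,
                           seed=(seed * 1000 + i) % (2**31))
        records.append(
            generate_experiment(
                membrane,
                fixtures.study_conditions(rpm),
                geometry,
                feed,
                solutes,
                noise,
                label=f"{membrane_class} {rpm:g} rpm",
            )
        )
    return membrane, records
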