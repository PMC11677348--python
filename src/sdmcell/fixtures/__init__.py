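"""Packaged reference tables and study constants.

The CSVs under ``sdmcell/fixtures/`` transcribe the published stirred-cell
study this package emulates: solute properties, run-averaged NF/RO
rejections at 300/450 rpm, fitted solute permeabilities Ls, and the
held-out validation conditions. Loaders return plain pandas frames or the
package's domain objects; values are never rescaled on load.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..transport import CellGeometry, Conditions, FeedState, Membrane, Solute
from ..units import bar_to_pa, rpm_to_rad_s

# Experiment constants of the emulated stirred-cell study
MEMBRANE_AREA_M2 = 14.6e-4  # 14.6 cm²
INITIAL_FEED_VOLUME_M3 = 300e-6  # 300 mL
OPERATING_PRESSURE_BAR = 10.0
STIRRING_SPEEDS_RPM = (300.0, 450.0)
NACL_FEED_MG_L = 500.0
PHAC_FEED_NG_L = 50.0
FEED_PH = 6.7
TEMPERATURE_K = 298.15  # 25 °C
SAMPLE_INTERVAL_M3 = 30e-6  # permeate sampled every 30 mL

# Not reported for the cell used; package assumption (HP4750-class stir bar)
STIRRING_RADIUS_M = 0.02

# Synthetic solvent permeabilities (never published): chosen to give
# typical initial fluxes of ~50 LMH (NF) and ~14 LMH (RO) at 10 bar.
SYNTHETIC_LV = {"NF": 1.45e-11, "RO": 4.2e-12}  # m s⁻¹ Pa⁻¹


def _read(name: str) -> pd.DataFrame:
    with resources.files("sdmcell.fixtures").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_solute_table() -> pd.DataFrame:
    return _read("solute_properties.csv")


def load_solutes() -> dict[str, Solute]:
    """Solute registry (NaCl + 13 pharmaceuticals) keyed by name."""
    df = load_solute_table()
    out: dict[str, Solute] = {}
    for row in df.itertuples(index=False):
        out[row.name] = Solute(
            name=row.name,
            molecular_weight=row.molecular_weight_g_mol,
            diffusion_coefficient=row.diffusion_coefficient_m2_s,
            log_kow=row.log_kow,
            pka=row.pka,
            osmotically_active=bool(row.osmotically_active),
            vant_hoff_factor=row.vant_hoff_factor,
        )
    return out


def load_nf_rejections() -> pd.DataFrame:
    return _read("nf_rejections.csv")


def load_ro_rejections() -> pd.DataFrame:
    return _read("ro_rejections.csv")


def load_ls_values() -> dict[str, dict[str, float]]:
    """Fitted Ls (m/s) keyed membrane class → solute name."""
    df = _read("ls_values.csv")
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.membrane, {})[row.solute] = row.Ls_m_s
    return out


def load_validation_reference() -> pd.DataFrame:
    return _read("validation_reference.csv")


def reference_membrane(membrane_class: str) -> Membrane:
    """NF or RO membrane with fitted Ls values and the synthetic Lv."""
    ls = load_ls_values()[membrane_class]
    return Membrane(
        name=f"{membrane_class}-reference",
        membrane_class=membrane_class,
        Lv=SYNTHETIC_LV[membrane_class],
        Ls_by_solute=dict(ls),
    )


def study_geometry() -> CellGeometry:
    return CellGeometry(
        membrane_area=MEMBRANE_AREA_M2,
        initial_feed_volume=INITIAL_FEED_VOLUME_M3,
        stirring_radius=STIRRING_RADIUS_M,
    )


def study_conditions(rpm: float, pressure_bar: float = OPERATING_PRESSURE_BAR) -> Conditions:
    return Conditions(
        delta_p=bar_to_pa(pressure_bar),
        stirring_speed=rpm_to_rad_s(rpm),
        temperature=TEMPERATURE_K,
    )


def study_feed() -> FeedState:
    """300 mL of 500 mg/L NaCl with the 13 pharmaceuticals at 50 ng/L each."""
    conc = {"NaCl": NACL_FEED_MG_L * 1e-3}
    for name in load_solutes():
        if name != "NaCl":
            conc[name] = PHAC_FEED_NG_L * 1e-9
    return FeedState(INITIAL_FEED_VOLUME_M3, conc)
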