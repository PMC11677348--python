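"""CSV/JSON/YAML interfaces.

All files speak practitioner units (bar, rpm, °C, mL, cm², LMH, mg/L,
ng/L); conversion to SI happens here and nowhere deeper. Tabular artifacts
are RFC-4180 CSV with ``.`` decimal separator; reports are JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures
from .estimate import ExperimentRecord
from .transport import CellGeometry, Conditions, FeedState, Membrane, Solute
from .units import bar_to_pa, celsius_to_kelvin, pa_to_bar, rad_s_to_rpm, rpm_to_rad_s

SOLUTE_COLUMNS = [
    "name", "molecular_weight_g_mol", "log_kow", "pka",
    "diffusion_coefficient_m2_s", "osmotically_active", "vant_hoff_factor",
]


def read_solutes(path: str | Path) -> dict[str, Solute]:
    """Solute property table → registry; header must match SOLUTE_COLUMNS."""
    df = pd.read_csv(path, comment="#")
    missing = set(SOLUTE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"solute table missing columns: {sorted(missing)}")
    out = {}
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


def read_ls_table(path: str | Path, membrane_class: str) -> dict[str, float]:
    """`membrane,solute,Ls_m_s` table → Ls mapping for one membrane class."""
    df = pd.read_csv(path, comment="#")
    need = {"membrane", "solute", "Ls_m_s"}
    if not need <= set(df.columns):
        raise ValueError(f"Ls table must have columns {sorted(need)}")
    sub = df[df["membrane"] == membrane_class]
    if sub.empty:
        raise ValueError(f"no rows for membrane {membrane_class!r}")
    return dict(zip(sub["solute"], sub["Ls_m_s"].astype(float)))


def write_membrane(membrane: Membrane, path: str | Path) -> None:
    payload = {
        "name": membrane.name,
        "membrane_class": membrane.membrane_class,
        "Lv_m_s_Pa": membrane.Lv,
        "Ls_m_s": membrane.Ls_by_solute,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_membrane(path: str | Path) -> Membrane:
    payload = json.loads(Path(path).read_text())
    return Membrane(
        name=payload["name"],
        membrane_class=payload["membrane_class"],
        Lv=payload["Lv_m_s_Pa"],
        Ls_by_solute=payload["Ls_m_s"],
    )


def write_record(record: ExperimentRecord, directory: str | Path) -> Path:
    """Persist one experiment record as <label>.csv + <label>.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = record.label.replace(" ", "_").replace("/", "-")
    # 17 significant digits: float64 round-trips exactly through the CSV
    record.flux_series.to_csv(directory / f"{stem}.csv", index=False,
                              float_format="%.17g")
    meta = {
        "label": record.label,
        "pressure_bar": pa_to_bar(record.conditions.delta_p),
        "rpm": rad_s_to_rpm(record.conditions.stirring_speed),
        "temperature_K": record.conditions.temperature,
        "fluid_density_kg_m3": record.conditions.fluid_density,
        "fluid_viscosity_Pa_s": record.conditions.fluid_viscosity,
        "membrane_area_m2": record.geometry.membrane_area,
        "initial_feed_volume_m3": record.geometry.initial_feed_volume,
        "stirring_radius_m": record.geometry.stirring_radius,
        "feed_kg_m3": record.feed.concentration_by_solute,
        "rejections": record.rejections,
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return directory / f"{stem}.csv"


def read_record(csv_path: str | Path) -> ExperimentRecord:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return ExperimentRecord(
        label=meta["label"],
        conditions=Conditions(
            delta_p=bar_to_pa(meta["pressure_bar"]),
            stirring_speed=rpm_to_rad_s(meta["rpm"]),
            temperature=meta["temperature_K"],
            fluid_density=meta["fluid_density_kg_m3"],
            fluid_viscosity=meta["fluid_viscosity_Pa_s"],
        ),
        geometry=CellGeometry(
            membrane_area=meta["membrane_area_m2"],
            initial_feed_volume=meta["initial_feed_volume_m3"],
            stirring_radius=meta["stirring_radius_m"],
        ),
        feed=FeedState(meta["initial_feed_volume_m3"], meta["feed_kg_m3"]),
        flux_series=pd.read_csv(csv_path, float_precision="round_trip"),
        rejections=meta["rejections"],
    )


@dataclass
class RunConfig:
    """Parsed YAML configuration for the pipeline and CLI."""

    geometry: CellGeometry
    conditions: Conditions
    feed: FeedState
    membrane_class: str
    Lv: float
    ls_source: str  # path to an Ls CSV, or "fixtures"
    solutes_source: str  # path to a solute CSV, or "fixtures"
    permeate_step: float  # m³
    stop_vcf: float
    sample_interval: float  # m³
    noise_cv: float

    def solutes(self) -> dict[str, Solute]:
        if self.solutes_source == "fixtures":
            return fixtures.load_solutes()
        return read_solutes(self.solutes_source)

    def membrane(self) -> Membrane:
        if self.ls_source == "fixtures":
            ls = fixtures.load_ls_values()[self.membrane_class]
        else:
            ls = read_ls_table(self.ls_source, self.membrane_class)
        return Membrane(
            name=f"{self.membrane_class}-config",
            membrane_class=self.membrane_class,
            Lv=self.Lv,
            Ls_by_solute=ls,
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; omitted keys fall back to the
    emulated study's constants (10 bar, 300 rpm, 25 °C, packaged tables)."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    geo = raw.get("geometry", {})
    cond = raw.get("conditions", {})
    feed = raw.get("feed", {})
    mem = raw.get("membrane", {})
    sim = raw.get("simulate", {})

    geometry = CellGeometry(
        membrane_area=geo.get("membrane_area_cm2", 14.6) * 1e-4,
        initial_feed_volume=geo.get("initial_feed_volume_mL", 300.0) * 1e-6,
        stirring_radius=geo.get("stirring_radius_m", fixtures.STIRRING_RADIUS_M),
    )
    conditions = Conditions(
        delta_p=bar_to_pa(cond.get("pressure_bar", 10.0)),
        stirring_speed=rpm_to_rad_s(cond.get("rpm", 300.0)),
        temperature=celsius_to_kelvin(cond.get("temperature_C", 25.0)),
        fluid_density=cond.get("fluid_density_kg_m3", 997.0),
        fluid_viscosity=cond.get("fluid_viscosity_Pa_s", 8.9e-4),
    )
    membrane_class = mem.get("class", "NF")
    solutes_source = raw.get("solutes_csv", "fixtures")
    solute_names = (
        list(fixtures.load_solutes())
        if solutes_source == "fixtures"
        else list(read_solutes(solutes_source))
    )
    conc = {"NaCl": feed.get("nacl_mg_L", 500.0) * 1e-3}
    for name in solute_names:
        if name != "NaCl":
            conc[name] = feed.get("phac_ng_L", 50.0) * 1e-9
    return RunConfig(
        geometry=geometry,
        conditions=conditions,
        feed=FeedState(geometry.initial_feed_volume, conc),
        membrane_class=membrane_class,
        Lv=mem.get("Lv_m_s_Pa", fixtures.SYNTHETIC_LV.get(membrane_class, 1e-11)),
        ls_source=mem.get("ls_csv", "fixtures"),
        solutes_source=solutes_source,
        permeate_step=sim.get("permeate_step_mL", 1.0) * 1e-6,
        stop_vcf=sim.get("stop_vcf", 10.0),
        sample_interval=sim.get("sample_interval_mL", 30.0) * 1e-6,
        noise_cv=raw.get("noise_cv", 0.01),
    )
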