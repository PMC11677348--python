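"""Local solution–diffusion transport with film-theory concentration polarization.

The model couples, at a single instant of a stirred-cell filtration:

* solvent flux through the membrane,  Jv = Lv (ΔP − Δπ),
* solute flux through the membrane,   Js = Ls (Cm − Cp),  with Cp = Js / Jv,
* film theory at the membrane surface, (Cm − Cp) / (Cb − Cp) = exp(Jv / k),

where Cb, Cm, Cp are the bulk, membrane-surface and permeate concentrations,
k is the back-diffusion mass-transfer coefficient of the stirred boundary
layer, and Δπ is the osmotic pressure difference evaluated (by default) at
the membrane surface, π(Cm) − π(Cp), summed over osmotically active solutes.

For a single solute at fixed Jv the three relations collapse to closed forms:

    Cp    = Ls·E·Cb / (Jv + Ls·E)         with E = exp(Jv / k)
    R_obs = 1 − Cp/Cb = Jv / (Jv + Ls·E)
    R_true (no polarization, k → ∞)       = Jv / (Jv + Ls)

so the only genuine unknown is Jv itself, which appears in Δπ through Cm.
The solver exploits this: Jv is found by a damped fixed-point iteration with
a bracketed Brent fallback, and all concentrations follow analytically.

Trace solutes (osmotically inactive, e.g. pharmaceuticals at ng/L) cannot
feed back on Jv and are solved independently once Jv is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .units import GAS_CONSTANT


class TransportError(Exception):
    """Base class for physical/numerical failures of the transport solve."""


class NoPositiveFluxError(TransportError):
    """Applied pressure does not exceed the bulk osmotic pressure difference."""


class UnstirredCellError(TransportError):
    """k = 0: the film-theory polarization factor exp(Jv/k) diverges."""


class ConvergenceError(TransportError):
    def __init__(self, message: str, residuals: dict[str, float] | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


@dataclass(frozen=True)
class Solute:
    """A dissolved species with its transport-relevant properties.

    ``log_kow`` and ``pka`` are carried as physicochemical metadata only;
    the transport model uses ``molecular_weight``, ``diffusion_coefficient``
    and the osmotic fields.
    """

    name: str
    molecular_weight: float  # g/mol
    diffusion_coefficient: float  # Dsw, m²/s
    log_kow: float = float("nan")
    pka: float = float("nan")
    osmotically_active: bool = False
    vant_hoff_factor: float = 1.0  # i, count of dissociated species

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular_weight must be > 0")
        if self.diffusion_coefficient <= 0:
            raise ValueError(f"{self.name}: diffusion_coefficient must be > 0")
        if self.vant_hoff_factor < 1:
            raise ValueError(f"{self.name}: vant_hoff_factor must be >= 1")


@dataclass(frozen=True)
class Membrane:
    """Solvent permeability Lv plus per-solute solute permeabilities Ls."""

    name: str
    membrane_class: str  # "NF" | "RO"
    Lv: float  # m s⁻¹ Pa⁻¹
    Ls_by_solute: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.membrane_class not in ("NF", "RO"):
            raise ValueError("membrane_class must be 'NF' or 'RO'")
        if self.Lv <= 0:
            raise ValueError("Lv must be > 0")
        for solute, ls in self.Ls_by_solute.items():
            if ls < 0:
                raise ValueError(f"Ls for {solute!r} must be >= 0")

    def Ls(self, solute_name: str) -> float:
        try:
            return self.Ls_by_solute[solute_name]
        except KeyError:
            raise KeyError(
                f"membrane {self.name!r} has no Ls for solute {solute_name!r}"
            ) from None

    def with_Ls(self, solute_name: str, Ls: float) -> "Membrane":
        new = dict(self.Ls_by_solute)
        new[solute_name] = Ls
        return Membrane(self.name, self.membrane_class, self.Lv, new)


@dataclass(frozen=True)
class CellGeometry:
    """Dead-end stirred cell geometry."""

    membrane_area: float  # m²
    initial_feed_volume: float  # m³
    stirring_radius: float  # r, m

    def __post_init__(self) -> None:
        for fname in ("membrane_area", "initial_feed_volume", "stirring_radius"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be > 0")


@dataclass(frozen=True)
class Conditions:
    """Operating conditions; stirring speed stored as angular velocity."""

    delta_p: float  # transmembrane pressure ΔP, Pa
    stirring_speed: float  # w, rad/s
    temperature: float = 298.15  # K
    fluid_density: float = 997.0  # ρ, kg/m³ (water, 25 °C)
    fluid_viscosity: float = 8.9e-4  # μ, Pa·s (water, 25 °C)

    def __post_init__(self) -> None:
        if self.delta_p < 0:
            raise ValueError("delta_p must be >= 0")
        if self.stirring_speed < 0:
            raise ValueError("stirring_speed must be >= 0")
        if self.fluid_density <= 0 or self.fluid_viscosity <= 0:
            raise ValueError("fluid density and viscosity must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0 (kelvin)")


@dataclass
class FeedState:
    """Bulk feed at one instant: volume and per-solute concentrations Cb."""

    volume: float  # m³
    concentration_by_solute: dict[str, float]  # Cb, kg/m³

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("feed volume must be > 0")
        for name, c in self.concentration_by_solute.items():
            if c < 0:
                raise ValueError(f"negative feed concentration for {name!r}")


@dataclass(frozen=True)
class SoluteTransport:
    """Per-solute piece of a converged transport state."""

    Js: float  # kg m⁻² s⁻¹
    Cp: float  # kg/m³
    Cm: float  # kg/m³
    k: float  # m/s


@dataclass(frozen=True)
class TransportState:
    """Converged local solution of the coupled flux/polarization system."""

    Jv: float  # m/s
    solutes: dict[str, SoluteTransport]
    delta_pi: float  # effective osmotic pressure difference, Pa
    residuals: dict[str, float]
    iterations: int

    def rejection(self, solute_name: str, Cb: float) -> float:
        return rejection(Cb, self.solutes[solute_name].Cp)


def osmotic_pressure(concentration: float, solute: Solute, temperature: float) -> float:
    """Van 't Hoff osmotic pressure π = i·(c/M)·R·T in Pa.

    Osmotically inactive solutes (trace organics at ng/L) contribute zero.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if not solute.osmotically_active:
        return 0.0
    molar = concentration / (solute.molecular_weight * 1e-3)  # mol/m³
    return solute.vant_hoff_factor * molar * GAS_CONSTANT * temperature


def mass_transfer_coefficient(
    solute: Solute, conditions: Conditions, geometry: CellGeometry
) -> float:
    """Stirred-cell back-diffusion mass-transfer coefficient.

    k = 0.104 (Dsw/r) (w r² ρ / μ)^(2/3) (μ / (ρ Dsw))^(1/3)

    i.e. a Sherwood correlation Sh = 0.104 Re^(2/3) Sc^(1/3) on the stirring
    radius r, with w the angular velocity in rad/s. Returns 0.0 for an
    unstirred cell (w = 0), in which case film theory diverges and the
    transport solver refuses to proceed.
    """
    w = conditions.stirring_speed
    if w == 0:
        return 0.0
    D = solute.diffusion_coefficient
    r = geometry.stirring_radius
    rho = conditions.fluid_density
    mu = conditions.fluid_viscosity
    reynolds = w * r * r * rho / mu
    schmidt = mu / (rho * D)
    return 0.104 * (D / r) * reynolds ** (2.0 / 3.0) * schmidt ** (1.0 / 3.0)


def rejection(Cb: float, Cp: float) -> float:
    """Observed rejection R = 1 − Cp/Cb, as a fraction in [0, 1]."""
    if Cb <= 0:
        raise ValueError("rejection undefined for Cb <= 0")
    if Cp < 0:
        raise ValueError("Cp must be >= 0")
    r = 1.0 - Cp / Cb
    if r < -1e-12 or r > 1.0 + 1e-12:
        raise ValueError(f"rejection {r} outside [0, 1]; refusing to clip silently")
    return min(max(r, 0.0), 1.0)


def polarized_permeate_concentration(Cb: float, Ls: float, Jv: float, k: float) -> float:
    """Closed-form Cp for one solute at fixed solvent flux.

    Eliminating Cm between the solute-flux and film-theory relations gives
    Cp = Ls·E·Cb/(Jv + Ls·E) with E = exp(Jv/k).
    """
    if Jv <= 0:
        raise ValueError("requires Jv > 0")
    if k <= 0:
        raise UnstirredCellError("k = 0: film-theory polarization diverges")
    E = np.exp(Jv / k)
    return Ls * E * Cb / (Jv + Ls * E)


def observed_rejection_closed_form(Jv: float, Ls: float, k: float) -> float:
    """R_obs = Jv / (Jv + Ls·exp(Jv/k)) for a trace solute."""
    return Jv / (Jv + Ls * np.exp(Jv / k))


def true_rejection_closed_form(Jv: float, Ls: float) -> float:
    """No-polarization limit (k → ∞): R_true = Jv / (Jv + Ls)."""
    return Jv / (Jv + Ls)


def _delta_pi_at_flux(
    Jv: float,
    active: list[tuple[Solute, float, float, float]],
    temperature: float,
    surface: bool,
) -> float:
    """Osmotic pressure difference seen by the membrane at trial flux Jv.

    ``active`` holds (solute, Cb, Ls, k) for osmotically active solutes.
    """
    dpi = 0.0
    for solute, Cb, Ls, k in active:
        Cp = polarized_permeate_concentration(Cb, Ls, Jv, k)
        if surface:
            E = np.exp(Jv / k)
            Cm = Cp + (Cb - Cp) * E
            dpi += osmotic_pressure(Cm, solute, temperature) - osmotic_pressure(
                Cp, solute, temperature
            )
        else:
            dpi += osmotic_pressure(Cb, solute, temperature) - osmotic_pressure(
                Cp, solute, temperature
            )
    return dpi


def solve_local_transport(
    feed: FeedState,
    membrane: Membrane,
    conditions: Conditions,
    geometry: CellGeometry,
    solutes: dict[str, Solute],
    tolerance: float = 1e-10,
    max_iterations: int = 500,
    surface_osmotic: bool = True,
    initial_Jv: float | None = None,
) -> TransportState:
    """Solve the coupled flux / polarization system at one instant.

    Osmotically active solutes set Jv through Δπ; trace solutes are then
    resolved independently by the closed form. ``surface_osmotic`` selects
    Δπ = π(Cm) − π(Cp) (default) versus the bulk-based π(Cb) − π(Cp).

    Raises :class:`NoPositiveFluxError` if ΔP does not exceed the bulk
    osmotic pressure difference, :class:`UnstirredCellError` when a needed
    mass-transfer coefficient is zero, and :class:`ConvergenceError` (with
    per-equation residuals attached) on iteration failure.
    """
    dP = conditions.delta_p
    T = conditions.temperature
    Lv = membrane.Lv

    active: list[tuple[Solute, float, float, float]] = []
    trace: list[tuple[Solute, float, float, float]] = []
    keys: dict[int, str] = {}
    dpi_bulk = 0.0
    for name, Cb in feed.concentration_by_solute.items():
        solute = solutes[name]
        Ls = membrane.Ls(name)
        k = mass_transfer_coefficient(solute, conditions, geometry)
        entry = (solute, Cb, Ls, k)
        keys[id(entry)] = name
        if solute.osmotically_active and Cb > 0:
            dpi_bulk += osmotic_pressure(Cb, solute, T)  # Cp >= 0 lowers this
            active.append(entry)
        else:
            trace.append(entry)

    if dP <= dpi_bulk:
        raise NoPositiveFluxError(
            f"no positive flux: ΔP = {dP:.6g} Pa does not exceed the bulk "
            f"osmotic pressure {dpi_bulk:.6g} Pa"
        )
    if any(k == 0.0 for _, _, _, k in active + trace):
        raise UnstirredCellError(
            "unstirred cell (w = 0): film theory diverges; stirring required"
        )

    Jv_max = Lv * dP  # pure-solvent bound: Δπ >= 0 tightens it

    if not active:
        Jv = Jv_max
        iterations = 0
    else:
        # Damped fixed-point on Jv = Lv (ΔP − Δπ(Jv)). The osmotic feedback
        # Lv·dΔπ/dJv is weak for realistic parameters, so the undamped map
        # contracts fast; damping kicks in only if steps start growing.
        Jv = initial_Jv if initial_Jv and 0 < initial_Jv <= Jv_max else Lv * (dP - dpi_bulk)
        damping = 1.0
        prev_step = float("inf")
        converged = False
        iterations = 0
        for iterations in range(1, max_iterations + 1):
            dpi = _delta_pi_at_flux(Jv, active, T, surface_osmotic)
            Jv_new = Lv * (dP - dpi)
            if Jv_new <= 0:
                break  # fixed point pushed out of the physical range
            step = Jv_new - Jv
            if abs(step) > prev_step:
                damping = max(0.5 * damping, 0.05)
            Jv_next = Jv + damping * step
            if Jv_next <= 0:
                Jv_next = 0.5 * Jv
            if abs(Jv_next - Jv) <= tolerance * max(abs(Jv_next), 1e-300):
                Jv = Jv_next
                converged = True
                break
            prev_step = abs(step)
            Jv = Jv_next
        if not converged:
            # Bracketed fallback: g(Jv) = Jv − Lv(ΔP − Δπ(Jv)) is strictly
            # increasing, g(0+) < 0, g(Jv_max) >= 0.
            def g(jv: float) -> float:
                return jv - Lv * (dP - _delta_pi_at_flux(jv, active, T, surface_osmotic))

            lo = Jv_max * 1e-12
            if g(lo) >= 0:
                raise NoPositiveFluxError("no positive flux root for Jv")
            Jv = brentq(g, lo, Jv_max, xtol=1e-300, rtol=8.9e-16, maxiter=max_iterations)
            iterations = max_iterations

    # Resolve every solute at the converged Jv.
    per_solute: dict[str, SoluteTransport] = {}
    residuals: dict[str, float] = {}
    for entry in active + trace:
        solute, Cb, Ls, k = entry
        key = keys[id(entry)]
        if Cb == 0.0:
            per_solute[key] = SoluteTransport(0.0, 0.0, 0.0, k)
            continue
        Cp = polarized_permeate_concentration(Cb, Ls, Jv, k)
        E = np.exp(Jv / k)
        Cm = Cp + (Cb - Cp) * E
        Js = Cp * Jv
        per_solute[key] = SoluteTransport(Js, Cp, Cm, k)
        # closure residuals of the two solute equations, relative
        r_flux = abs(Js - Ls * (Cm - Cp)) / max(abs(Js), 1e-300)
        r_film = abs((Cm - Cp) - (Cb - Cp) * E) / max(abs(Cm - Cp), 1e-300)
        residuals[f"{key}:solute_flux"] = r_flux
        residuals[f"{key}:film"] = r_film

    dpi = _delta_pi_at_flux(Jv, active, T, surface_osmotic) if active else 0.0
    residuals["solvent_flux"] = abs(Jv - Lv * (dP - dpi)) / max(Jv, 1e-300)

    worst = max(residuals.values())
    if worst > max(tolerance * 100, 1e-8):
        raise ConvergenceError(
            f"transport solve did not close (max residual {worst:.3e})", residuals
        )
    return TransportState(Jv=Jv, solutes=per_solute, delta_pi=dpi,
                          residuals=residuals, iterations=iterations)
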