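"""Boundary unit conversions.

Everything inside the package is SI (Pa, m, s, kg, m³, kg/m³, K).
Practitioner-facing interfaces speak bar, rpm, LMH, mL, mg/L and ng/L;
these helpers convert exactly at the boundary and nowhere else.
"""

from __future__ import annotations

GAS_CONSTANT = 8.314462618  # J mol⁻¹ K⁻¹ (CODATA 2018)

BAR_TO_PA = 1.0e5
ML_TO_M3 = 1.0e-6
CM2_TO_M2 = 1.0e-4

# 1 LMH = 1 L m⁻² h⁻¹ = 1e-3 m³ m⁻² / 3600 s
LMH_TO_M_S = 1.0e-3 / 3600.0

MG_L_TO_KG_M3 = 1.0e-3
NG_L_TO_KG_M3 = 1.0e-9

_RPM_TO_RAD_S = 2.0 * 3.141592653589793 / 60.0


def bar_to_pa(p_bar: float) -> float:
    return p_bar * BAR_TO_PA


def pa_to_bar(p_pa: float) -> float:
    return p_pa / BAR_TO_PA


def rpm_to_rad_s(rpm: float) -> float:
    """Stirring speed: revolutions per minute → angular velocity in rad/s."""
    return rpm * _RPM_TO_RAD_S


def rad_s_to_rpm(w: float) -> float:
    return w / _RPM_TO_RAD_S


def lmh_to_m_s(flux_lmh: float) -> float:
    return flux_lmh * LMH_TO_M_S


def m_s_to_lmh(flux_m_s: float) -> float:
    return flux_m_s / LMH_TO_M_S


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15
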