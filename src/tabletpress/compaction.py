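"""Powder-compaction physics: mixing rules, compressibility, recovery, strength.

All mixing follows the volume-additive principle: specific volumes (1/rho)
add with the mass fractions, so every mixed density is the mass-weighted
harmonic mean of the component densities. Units are g/cm3, mm for geometry
arguments (converted internally to cm), MPa for stress.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

from .blend import BlendComposition
from .materials import KawakitaCoefficients, RecoveryCalibration, StrengthMixCoefficients

__all__ = [
    "mix_bulk_density",
    "die_area_cm2",
    "tablet_weight",
    "in_die_density",
    "kawakita_mixture_density",
    "mixture_kawakita_floor",
    "mixture_kawakita_asymptote",
    "invert_compression_stress",
    "blend_recovery",
    "out_die_density",
    "mixture_solid_density",
    "out_die_porosity",
    "sigma0_of_x",
    "kb_of_x",
    "tensile_strength",
    "UnreachableDensityError",
    "LowStressWarning",
]

#: below this stress (MPa) the Kawakita model is outside its trust range
LOW_STRESS_LIMIT_MPA = 20.0


class UnreachableDensityError(ValueError):
    """Target density outside the attainable range of the blend."""


class LowStressWarning(UserWarning):
    """Kawakita model evaluated below its calibrated stress range."""


def _per_material(composition: BlendComposition, table: Mapping[str, object], what: str) -> dict:
    """Aggregate lot fractions per material and look up their parameters."""
    out = {}
    for mat, x in composition.by_material().items():
        try:
            out[mat] = (x, table[mat])
        except KeyError:
            raise KeyError(f"no {what} defined for material {mat!r}") from None
    return out


def mix_bulk_density(composition: BlendComposition, densities: Mapping[str, float]) -> float:
    """Mass-weighted harmonic mean density of a blend (g/cm3).

    ``1/rho_mix = sum_i x_i / rho_i``; the result is bounded by the smallest
    and largest component density.
    """
    inv = 0.0
    for mat, (x, rho) in _per_material(composition, densities, "density").items():
        if rho <= 0.0:
            raise ValueError(f"density of {mat!r} must be positive, got {rho!r}")
        inv += x / rho
    return 1.0 / inv


def die_area_cm2(die_diameter_mm: float) -> float:
    """Cross-section area of a round die (cm2)."""
    if die_diameter_mm <= 0.0:
        raise ValueError(f"die diameter must be positive, got {die_diameter_mm!r}")
    r_cm = die_diameter_mm / 20.0
    return math.pi * r_cm * r_cm


def tablet_weight(die_diameter_mm: float, dosing_height_mm: float, fill_density: float) -> float:
    """Tablet mass (g) from die geometry and apparent fill density."""
    if dosing_height_mm <= 0.0 or fill_density <= 0.0:
        raise ValueError(
            f"dosing height and fill density must be positive, got "
            f"{(dosing_height_mm, fill_density)}"
        )
    return die_area_cm2(die_diameter_mm) * (dosing_height_mm / 10.0) * fill_density


def in_die_density(tablet_mass_g: float, die_diameter_mm: float, punch_distance_mm: float) -> float:
    """In-die density (g/cm3) of a tablet of given mass at a punch gap."""
    if tablet_mass_g <= 0.0 or punch_distance_mm <= 0.0:
        raise ValueError(
            f"mass and punch distance must be positive, got {(tablet_mass_g, punch_distance_mm)}"
        )
    return tablet_mass_g / (die_area_cm2(die_diameter_mm) * punch_distance_mm / 10.0)


# ---------------------------------------------------------------------------
# Kawakita mixture model and its inversion
# ---------------------------------------------------------------------------

def kawakita_mixture_density(
    stress_mpa: float,
    composition: BlendComposition,
    coeffs: Mapping[str, KawakitaCoefficients],
    *,
    warn_low_stress: bool = True,
) -> float:
    """Volume-additive Kawakita density of a blend at a compression stress.

    ``1/rho(P) = sum_i x_i/rho0_i * (1 + (1-a_i) b_i P) / (1 + b_i P)``;
    strictly increasing in P, equal to the harmonic mix of the rho0 at P=0.
    """
    if stress_mpa < 0.0:
        raise ValueError(f"stress must be non-negative, got {stress_mpa!r}")
    if warn_low_stress and 0.0 < stress_mpa < LOW_STRESS_LIMIT_MPA:
        warnings.warn(
            f"Kawakita density evaluated at {stress_mpa:g} MPa, below the "
            f"{LOW_STRESS_LIMIT_MPA:g} MPa trust limit of the model",
            LowStressWarning,
            stacklevel=2,
        )
    inv = 0.0
    for _, (x, kc) in _per_material(composition, coeffs, "Kawakita coefficients").items():
        bp = kc.b * stress_mpa
        inv += x / kc.rho0 * (1.0 + (1.0 - kc.a) * bp) / (1.0 + bp)
    return 1.0 / inv


def mixture_kawakita_floor(
    composition: BlendComposition, coeffs: Mapping[str, KawakitaCoefficients]
) -> float:
    """Blend density at zero stress (harmonic mix of the rho0)."""
    return kawakita_mixture_density(0.0, composition, coeffs, warn_low_stress=False)


def mixture_kawakita_asymptote(
    composition: BlendComposition, coeffs: Mapping[str, KawakitaCoefficients]
) -> float:
    """Blend density limit for P -> infinity."""
    inv = 0.0
    for _, (x, kc) in _per_material(composition, coeffs, "Kawakita coefficients").items():
        inv += x * (1.0 - kc.a) / kc.rho0
    return 1.0 / inv


_STRESS_BRACKET_MPA = 1.0e4  # upper root-finding bracket for many-component blends


def invert_compression_stress(
    target_density: float,
    composition: BlendComposition,
    coeffs: Mapping[str, KawakitaCoefficients],
    *,
    warn_low_stress: bool = True,
) -> float:
    """Compression stress (MPa) producing ``target_density`` in the blend.

    For one or two components the mixture equation is rearranged into a
    polynomial in P and solved in closed form (the quadratic case via a
    numerically stable pq-formula); the admissible root is the positive one
    at which the forward model reproduces the target. Blends with more
    components fall back to bracketed bisection-type root finding.
    """
    per = _per_material(composition, coeffs, "Kawakita coefficients")
    floor = mixture_kawakita_floor(composition, coeffs)
    ceil = mixture_kawakita_asymptote(composition, coeffs)
    if target_density <= floor:
        raise UnreachableDensityError(
            f"target density {target_density:g} g/cm3 is not above the zero-stress "
            f"blend density {floor:g} g/cm3"
        )
    if target_density >= ceil:
        raise UnreachableDensityError(
            f"target density {target_density:g} g/cm3 is at or above the blend "
            f"asymptote {ceil:g} g/cm3: unreachable density"
        )

    v = 1.0 / target_density
    if len(per) == 1:
        ((_, (x, kc)),) = per.items()
        u = x / kc.rho0
        c = (1.0 - kc.a) * kc.b
        stress = (u - v) / (v * kc.b - u * c)
    elif len(per) == 2:
        (_, (x1, k1)), (_, (x2, k2)) = per.items()
        u1, u2 = x1 / k1.rho0, x2 / k2.rho0
        c1, c2 = (1.0 - k1.a) * k1.b, (1.0 - k2.a) * k2.b
        # v (1+b1 P)(1+b2 P) = u1 (1+c1 P)(1+b2 P) + u2 (1+c2 P)(1+b1 P)
        qa = v * k1.b * k2.b - u1 * c1 * k2.b - u2 * c2 * k1.b
        qb = v * (k1.b + k2.b) - u1 * (c1 + k2.b) - u2 * (c2 + k1.b)
        qc = v - u1 - u2
        stress = _positive_quadratic_root(qa, qb, qc, target_density, composition, coeffs)
    else:
        from scipy.optimize import brentq

        def f(p: float) -> float:
            return (
                kawakita_mixture_density(p, composition, coeffs, warn_low_stress=False)
                - target_density
            )

        stress = float(brentq(f, 0.0, _STRESS_BRACKET_MPA, xtol=1e-9))

    if warn_low_stress and stress < LOW_STRESS_LIMIT_MPA:
        warnings.warn(
            f"inverted stress {stress:g} MPa lies below the "
            f"{LOW_STRESS_LIMIT_MPA:g} MPa trust limit of the Kawakita model",
            LowStressWarning,
            stacklevel=2,
        )
    return stress


def _positive_quadratic_root(qa, qb, qc, target, composition, coeffs) -> float:
    """Admissible root of qa P^2 + qb P + qc = 0 for the two-component case."""
    roots: list[float] = []
    if abs(qa) < 1e-300:  # degenerate: effectively linear
        if qb != 0.0:
            roots.append(-qc / qb)
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc >= 0.0:
            sq = math.sqrt(disc)
            q = -0.5 * (qb + math.copysign(sq, qb)) if qb != 0.0 else 0.5 * sq
            if q != 0.0:
                roots.extend((q / qa, qc / q))
            else:
                roots.append(0.0)
    best = None
    for r in roots:
        if r <= 0.0 or not math.isfinite(r):
            continue
        rho = kawakita_mixture_density(r, composition, coeffs, warn_low_stress=False)
        if abs(rho - target) <= 1e-6 * target:
            if best is None or r < best:
                best = r
    if best is None:
        raise UnreachableDensityError(
            f"no physically admissible stress reproduces density {target:g} g/cm3 "
            f"(quadratic roots {roots})"
        )
    return best


# ---------------------------------------------------------------------------
# Elastic recovery
# ---------------------------------------------------------------------------

def blend_recovery(
    composition: BlendComposition, recovery: Mapping[str, RecoveryCalibration]
) -> RecoveryCalibration:
    """Elastic-recovery calibration of a blend from its pure components.

    The three state densities at each calibration stress mix volume-additively
    (harmonic mean, mass-fraction weighted); the correction offset blends
    linearly with the mass fractions. All components must have been
    calibrated at the same pair of stresses. A single-component blend
    returns a calibration identical to the pure substance.
    """
    per = _per_material(composition, recovery, "recovery calibration")
    cals = [rc for _, (_, rc) in per.items()]
    lows = {(rc.stress_low_mpa, rc.stress_high_mpa) for rc in cals}
    if len(lows) != 1:
        raise ValueError(
            f"all components must share one pair of calibration stresses, got {sorted(lows)}"
        )
    (p_low, p_high), = lows

    def hmix(attr: str) -> float:
        inv = 0.0
        for _, (x, rc) in per.items():
            inv += x / getattr(rc, attr)
        return 1.0 / inv

    offset = sum(x * rc.correction_offset for _, (x, rc) in per.items())
    return RecoveryCalibration(
        stress_low_mpa=p_low,
        stress_high_mpa=p_high,
        rho_p_max_low=hmix("rho_p_max_low"),
        rho_p_0_low=hmix("rho_p_0_low"),
        rho_out_die_low=hmix("rho_out_die_low"),
        rho_p_max_high=hmix("rho_p_max_high"),
        rho_p_0_high=hmix("rho_p_0_high"),
        rho_out_die_high=hmix("rho_out_die_high"),
        correction_offset=offset,
    )


def out_die_density(
    stress_mpa: float,
    rho_p_max: float,
    composition: BlendComposition,
    recovery: Mapping[str, RecoveryCalibration],
) -> float:
    """Tablet density after ejection and slow relaxation (g/cm3).

    rho_out = rho_p_max - [k P + l] - mean(delta_rho_slow) + correction;
    the bracket is the instantaneous in-die recovery line fitted through the
    blend-level calibration points, the mean term the stress-independent slow
    recovery.
    """
    if stress_mpa <= 0.0 or rho_p_max <= 0.0:
        raise ValueError(f"stress and in-die density must be positive, got {(stress_mpa, rho_p_max)}")
    cal = blend_recovery(composition, recovery)
    rho = (
        rho_p_max
        - cal.delta_rho_in_die(stress_mpa)
        - cal.delta_rho_slow_avg
        + cal.correction_offset
    )
    if rho <= 0.0:
        raise ValueError(
            f"predicted out-die density {rho:g} g/cm3 is not positive: "
            "implausible recovery calibration"
        )
    return rho


# ---------------------------------------------------------------------------
# Porosity and tensile strength
# ---------------------------------------------------------------------------

def mixture_solid_density(
    composition: BlendComposition, solid_densities: Mapping[str, float]
) -> float:
    """Volume-additive (harmonic) solid density of the blend (g/cm3)."""
    return mix_bulk_density(composition, solid_densities)


def out_die_porosity(
    rho_out_die: float,
    composition: BlendComposition,
    solid_densities: Mapping[str, float],
) -> float:
    """Out-die porosity eps = 1 - rho_out_die / rho_solid,mix, in (0, 1)."""
    rho_s = mixture_solid_density(composition, solid_densities)
    if rho_out_die >= rho_s:
        raise ValueError(
            f"out-die density {rho_out_die:g} g/cm3 reaches the mixture solid "
            f"density {rho_s:g} g/cm3: porosity would not be positive"
        )
    return 1.0 - rho_out_die / rho_s


def sigma0_of_x(x: float, coeffs: StrengthMixCoefficients) -> float:
    """Zero-porosity strength sigma0 (MPa) at reference mass fraction x."""
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"mass fraction must lie in [0, 1], got {x!r}")
    return coeffs.c1 * math.exp(x * coeffs.c2) + coeffs.c3


def kb_of_x(x: float, coeffs: StrengthMixCoefficients) -> float:
    """Porosity sensitivity kb (dimensionless) at reference mass fraction x."""
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"mass fraction must lie in [0, 1], got {x!r}")
    return coeffs.m * x + coeffs.n


def tensile_strength(
    eps_out_die: float, x: float, coeffs: StrengthMixCoefficients
) -> float:
    """Tensile strength sigma = sigma0(x) * exp(-kb(x) * eps) (MPa)."""
    if not (0.0 <= eps_out_die < 1.0):
        raise ValueError(f"porosity must lie in [0, 1), got {eps_out_die!r}")
    return sigma0_of_x(x, coeffs) * math.exp(-kb_of_x(x, coeffs) * eps_out_die)
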