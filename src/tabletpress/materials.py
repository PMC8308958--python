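"""Material property containers for powder compaction.

One :class:`MaterialSpec` bundles everything the simulator needs to know
about a single powder grade: the characteristic densities, the Kawakita
compressibility coefficients, the two-point elastic-recovery calibration and
(optionally) pure-substance strength coefficients. Values use the internal
unit set g/cm3, cm, MPa throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "KawakitaCoefficients",
    "RecoveryCalibration",
    "StrengthMixCoefficients",
    "MaterialSpec",
    "MaterialWarning",
]


class MaterialWarning(UserWarning):
    """Non-fatal physical inconsistency in a material definition."""


@dataclass(frozen=True)
class KawakitaCoefficients:
    """Kawakita compressibility in the density form.

    ``rho0`` (g/cm3) is the apparent density at low stress (20 MPa by
    convention), ``a`` the dimensionless compressibility, ``b`` (1/MPa) the
    stress-scale coefficient. The pure-substance density at stress P is

        rho(P) = rho0 * (1 + b P) / (1 + (1 - a) b P)

    which rises from ``rho0`` at P = 0 to the asymptote ``rho0 / (1 - a)``.
    """

    rho0: float
    a: float
    b: float

    def __post_init__(self):
        if not (0.0 < self.a < 1.0):
            raise ValueError(f"Kawakita a must lie in (0, 1), got {self.a!r}")
        if self.b <= 0.0:
            raise ValueError(f"Kawakita b must be positive, got {self.b!r}")
        if self.rho0 <= 0.0:
            raise ValueError(f"Kawakita rho0 must be positive, got {self.rho0!r}")

    @property
    def asymptote(self) -> float:
        """Density limit for P -> infinity, rho0 / (1 - a)."""
        return self.rho0 / (1.0 - self.a)

    def density(self, stress_mpa: float) -> float:
        """Pure-substance in-die density at ``stress_mpa`` (g/cm3)."""
        if stress_mpa < 0.0:
            raise ValueError(f"stress must be non-negative, got {stress_mpa!r}")
        bp = self.b * stress_mpa
        return self.rho0 * (1.0 + bp) / (1.0 + (1.0 - self.a) * bp)


@dataclass(frozen=True)
class RecoveryCalibration:
    """Two-point elastic-recovery calibration of one powder grade.

    Densities of calibration tablets compressed at a low and a high stress
    (30 and 400 MPa in the reference experiment) are recorded in three
    states: at maximum punch closure (``rho_p_max``), at zero axial stress
    still in the die (``rho_p_0``) and out of the die after slow relaxation
    (``rho_out_die``). The instantaneous recovery rho_p_max - rho_p_0 is
    modelled linear in stress; the slow recovery rho_p_0 - rho_out_die as a
    constant, taken as the mean of the two calibration stresses.
    ``correction_offset`` (g/cm3) shifts the prediction by the measured
    minus predicted out-die residual; zero when no such data exist.
    """

    stress_low_mpa: float
    stress_high_mpa: float
    rho_p_max_low: float
    rho_p_0_low: float
    rho_out_die_low: float
    rho_p_max_high: float
    rho_p_0_high: float
    rho_out_die_high: float
    correction_offset: float = 0.0

    def __post_init__(self):
        if self.stress_high_mpa <= self.stress_low_mpa:
            raise ValueError("calibration stresses must satisfy low < high")
        for tag, (pmax, p0, out) in {
            "low": (self.rho_p_max_low, self.rho_p_0_low, self.rho_out_die_low),
            "high": (self.rho_p_max_high, self.rho_p_0_high, self.rho_out_die_high),
        }.items():
            if not (pmax >= p0 >= out > 0.0):
                raise ValueError(
                    f"{tag}-stress state densities must satisfy "
                    f"rho_p_max >= rho_p_0 >= rho_out_die > 0, got {(pmax, p0, out)}"
                )

    # derived two-point line through the instantaneous-recovery deltas
    @property
    def k_instant(self) -> float:
        """Slope of the instantaneous recovery line (g/cm3 per MPa)."""
        d_low = self.rho_p_max_low - self.rho_p_0_low
        d_high = self.rho_p_max_high - self.rho_p_0_high
        return (d_high - d_low) / (self.stress_high_mpa - self.stress_low_mpa)

    @property
    def l_instant(self) -> float:
        """Intercept of the instantaneous recovery line (g/cm3)."""
        d_low = self.rho_p_max_low - self.rho_p_0_low
        return d_low - self.k_instant * self.stress_low_mpa

    @property
    def delta_rho_slow_avg(self) -> float:
        """Mean slow-recovery density change over both stresses (g/cm3)."""
        return 0.5 * (
            (self.rho_p_0_low - self.rho_out_die_low)
            + (self.rho_p_0_high - self.rho_out_die_high)
        )

    def delta_rho_in_die(self, stress_mpa: float) -> float:
        """Instantaneous recovery at an arbitrary stress (g/cm3)."""
        return self.k_instant * stress_mpa + self.l_instant

    @classmethod
    def no_recovery(
        cls, stress_low_mpa: float, stress_high_mpa: float, rho_low: float, rho_high: float
    ) -> "RecoveryCalibration":
        """Degenerate calibration with all recovery deltas zero."""
        return cls(
            stress_low_mpa, stress_high_mpa,
            rho_low, rho_low, rho_low,
            rho_high, rho_high, rho_high,
        )


@dataclass(frozen=True)
class StrengthMixCoefficients:
    """Composition dependence of the porosity-strength law for a binary blend.

    For a blend characterised by the mass fraction ``x`` of the reference
    grade, the zero-porosity strength follows sigma0(x) = c1*exp(c2*x) + c3
    (MPa) and the porosity sensitivity kb(x) = m*x + n (dimensionless).
    """

    c1: float
    c2: float
    c3: float
    m: float
    n: float

    def __post_init__(self):
        # evaluated sigma0 and kb must stay positive over x in [0, 1]
        for x in (0.0, 1.0):
            s0 = self.c1 * math.exp(x * self.c2) + self.c3
            kb = self.m * x + self.n
            if s0 <= 0.0 or kb <= 0.0:
                raise ValueError(
                    f"sigma0(x) and kb(x) must be positive on [0,1]; at x={x} got {(s0, kb)}"
                )


@dataclass(frozen=True)
class MaterialSpec:
    """Complete description of one powder grade.

    Densities in g/cm3: ``solid_density`` (helium-pycnometer true density),
    ``bulk_density`` (poured), ``tapped_density`` (informational) and
    ``consolidated_bulk_density`` — the apparent density after die filling,
    which for well-flowing powders exceeds the cylinder bulk density because
    the paddle wheel consolidates the bed.
    """

    name: str
    solid_density: float
    bulk_density: float
    tapped_density: float
    consolidated_bulk_density: float
    kawakita: KawakitaCoefficients
    recovery: RecoveryCalibration | None = None
    sigma0_pure: float | None = None
    kb_pure: float | None = None
    x50_um: float | None = field(default=None)  # particle-size metadata only

    def __post_init__(self):
        rb, rf, rs, rt = (
            self.bulk_density,
            self.consolidated_bulk_density,
            self.solid_density,
            self.tapped_density,
        )
        if not (0.0 < rb <= rf < rs):
            raise ValueError(
                f"{self.name}: need 0 < bulk <= consolidated < solid density, "
                f"got {(rb, rf, rs)}"
            )
        if not (rb <= rt < rs):
            raise ValueError(f"{self.name}: need bulk <= tapped < solid density, got {(rb, rt, rs)}")
        if self.kawakita.rho0 >= rs:
            raise ValueError(f"{self.name}: Kawakita rho0 must be below the solid density")
        if self.kawakita.asymptote > rs:
            # fitted coefficients can extrapolate above the true density;
            # tolerated because the fit range ends well below the asymptote
            warnings.warn(
                f"{self.name}: Kawakita asymptote {self.kawakita.asymptote:.4f} g/cm3 "
                f"exceeds the solid density {rs} g/cm3; high-stress extrapolation "
                "is unphysical",
                MaterialWarning,
                stacklevel=2,
            )

    def fill_density(self, basis: str = "consolidated") -> float:
        """Apparent density used for die filling (g/cm3)."""
        if basis == "consolidated":
            return self.consolidated_bulk_density
        if basis == "bulk":
            return self.bulk_density
        raise ValueError(f"unknown fill density basis {basis!r}")
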