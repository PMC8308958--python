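"""Event-driven model of a rotary tablet press.

The press is decomposed into interacting agents: a hopper feeding a
filling pipe, the pipe itself (two concentric plug-flow regions, a fast
midstream and a slower outer ring, discretised into layers), a rotating
twelve-compartment feed frame whose interspaces behave as a cascade of
ideal mixers, and a die that is filled from several compartments, closed to
a set punch distance and finally ejects a tablet. One *event* is one
die-fill/compression/ejection cycle; with the default kinematics (20 rpm
turret, 4 stations) events occur every 0.75 s, i.e. 80 tablets per minute.

Everything is bookkept in absolute masses per ``(material, lot)`` key, so a
full conservation ledger (hopper out = pipe + inlet holdup + feed frame +
tablets) can be asserted after every event, and every tablet record carries
its lot-resolved provenance.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .blend import BlendComposition, BlendKey
from .compaction import (
    UnreachableDensityError,
    die_area_cm2,
    in_die_density,
    invert_compression_stress,
    mix_bulk_density,
    mixture_kawakita_asymptote,
    mixture_kawakita_floor,
    out_die_density,
    out_die_porosity,
    tensile_strength,
)
from .materials import KawakitaCoefficients, MaterialSpec, StrengthMixCoefficients

__all__ = [
    "PressConfig",
    "PipeLayer",
    "CompartmentState",
    "TabletRecord",
    "HopperSchedule",
    "FillingPipe",
    "FeedFrame",
    "Holdup",
    "CompressionResult",
    "SimulationResult",
    "dosing_volume",
    "build_pipe",
    "compress",
    "eject",
    "run_simulation",
    "UnderfillError",
    "MassBalanceError",
    "ConvergenceError",
]

_LEDGER_RTOL = 1e-9
_VOL_EPS = 1e-12


class UnderfillError(RuntimeError):
    """A feed-frame compartment could not supply its share of the die volume."""


class MassBalanceError(RuntimeError):
    """The conservation ledger failed: mass was created or destroyed."""


class ConvergenceError(RuntimeError):
    """The coupled punch-deflection/stress solve did not converge."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PressConfig:
    """Geometry, kinematics and calibrated structure of the rotary press.

    Defaults describe the pilot-scale press of the reference case study:
    11.28 mm round dies, 10 mm fill cam with 7 mm dosing depth, 3.2 mm
    minimal punch distance, 4 stations at 20 rpm turret and 60 rpm paddle
    speed, a 12-compartment feed frame filling the die 40/35/25 from three
    compartments, and a filling pipe whose fast midstream has a calibrated
    diameter of 33 mm moving twice as fast as the outer ring.
    ``machine_compliance_mm_per_kn`` is the press-frame elasticity: the
    actual punch distance is ``h_min + compliance * force``.
    """

    die_diameter_mm: float = 11.28
    fill_depth_mm: float = 10.0
    dosing_height_mm: float = 7.0
    min_punch_distance_mm: float = 3.2
    n_stations: int = 4
    turret_rpm: float = 20.0
    paddle_rpm: float = 60.0
    n_compartments: int = 12
    fill_ratios: tuple[float, ...] = (0.40, 0.35, 0.25)
    output_position: int = 5
    pipe_inner_diameter_mm: float = 45.0
    midstream_diameter_mm: float = 33.0
    velocity_ratio: int = 2
    pipe_height_mm: float = 200.0
    compartment_capacity_cm3: float | None = None
    machine_compliance_mm_per_kn: float = 0.0
    fill_density_basis: str = "consolidated"
    sim_duration_min: float = 25.0

    def __post_init__(self):
        if self.die_diameter_mm <= 0 or self.dosing_height_mm <= 0:
            raise ValueError("die diameter and dosing height must be positive")
        if not (0 < self.min_punch_distance_mm < self.dosing_height_mm):
            raise ValueError("need 0 < min punch distance < dosing height")
        if self.dosing_height_mm > self.fill_depth_mm:
            raise ValueError("dosing height cannot exceed the fill depth")
        if min(self.n_stations, self.n_compartments) < 1:
            raise ValueError("station and compartment counts must be positive")
        if min(self.turret_rpm, self.paddle_rpm) <= 0:
            raise ValueError("turret and paddle speed must be positive")
        ratios = tuple(float(r) for r in self.fill_ratios)
        object.__setattr__(self, "fill_ratios", ratios)
        if any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
            raise ValueError(f"fill ratios must be non-negative and sum to 1, got {ratios}")
        if len(ratios) > self.n_compartments:
            raise ValueError("more fill ratios than feed-frame compartments")
        if not (1 <= self.output_position <= self.n_compartments):
            raise ValueError("output position must be a valid compartment position")
        if self.midstream_diameter_mm >= self.pipe_inner_diameter_mm:
            raise ValueError("midstream diameter must be smaller than the pipe inner diameter")
        if int(self.velocity_ratio) != self.velocity_ratio or self.velocity_ratio < 1:
            raise ValueError("velocity ratio must be an integer >= 1")
        object.__setattr__(self, "velocity_ratio", int(self.velocity_ratio))
        if self.pipe_height_mm <= 0:
            raise ValueError("pipe height must be positive")
        if self.machine_compliance_mm_per_kn < 0:
            raise ValueError("machine compliance cannot be negative")
        if self.fill_density_basis not in ("consolidated", "bulk"):
            raise ValueError(f"unknown fill density basis {self.fill_density_basis!r}")
        if self.compartment_capacity_cm3 is None:
            object.__setattr__(self, "compartment_capacity_cm3", 3.0 * self.dosing_volume_cm3)
        if self.compartment_capacity_cm3 < self.dosing_volume_cm3 * max(ratios) - _VOL_EPS:
            raise ValueError(
                "compartment capacity must cover the largest single die-fill share"
            )

    @property
    def die_area_cm2(self) -> float:
        return die_area_cm2(self.die_diameter_mm)

    @property
    def dosing_volume_cm3(self) -> float:
        """Die volume metered at the dosing height (cm3)."""
        return self.die_area_cm2 * self.dosing_height_mm / 10.0

    @property
    def fills_per_min(self) -> float:
        return self.turret_rpm * self.n_stations

    @property
    def event_period_s(self) -> float:
        return 60.0 / self.fills_per_min

    @property
    def rotation_steps_per_event(self) -> int:
        """Compartment positions advanced per die-fill event.

        The paddle wheel passes ``paddle_rpm * n_compartments`` interspaces
        per minute over any fixed point while ``fills_per_min`` dies are
        filled, so each fill event corresponds to this many position steps
        (9 with the default kinematics).
        """
        return round(self.paddle_rpm * self.n_compartments / self.fills_per_min)


def dosing_volume(config: PressConfig) -> float:
    """Dosing volume of the die (cm3)."""
    return config.dosing_volume_cm3


# ---------------------------------------------------------------------------
# Hopper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HopperSchedule:
    """Timeline of hopper contents: ``(start_min, material, lot)`` intervals.

    Intervals are contiguous; each lasts until the next start (the final one
    is open-ended). An empty schedule means the hopper never feeds.
    """

    entries: tuple[tuple[float, str, str], ...] = ()

    def __post_init__(self):
        entries = tuple((float(t), str(m), str(lot)) for t, m, lot in self.entries)
        object.__setattr__(self, "entries", entries)
        if entries:
            starts = [t for t, _, _ in entries]
            if starts != sorted(starts) or len(set(starts)) != len(starts):
                raise ValueError("schedule starts must be strictly increasing")
            if starts[0] != 0.0:
                raise ValueError("schedule must start at t = 0")

    def key_at(self, t_min: float) -> BlendKey:
        if not self.entries:
            raise ValueError("empty hopper schedule")
        current = self.entries[0]
        for entry in self.entries:
            if entry[0] <= t_min:
                current = entry
            else:
                break
        return (current[1], current[2])

    @classmethod
    def constant(cls, material: str, lot: str = "default") -> "HopperSchedule":
        return cls(((0.0, material, lot),))


# ---------------------------------------------------------------------------
# Filling pipe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipeLayer:
    """One horizontal slice of the filling pipe (view object)."""

    midstream_composition: BlendComposition
    outer_composition: BlendComposition
    layer_height_cm: float
    midstream_volume_cm3: float
    outer_volume_cm3: float


class FillingPipe:
    """Plug-flow filling pipe with a fast central midstream.

    Both regions are discretised into layers of one shared height, chosen so
    that a single fill event's extraction — one outer-ring layer plus
    ``velocity_ratio`` midstream layers — totals exactly the dosing volume:

        h_layer = V_dos / (A_outer + velocity_ratio * A_mid)

    Layers never mix vertically or radially; each is created from the hopper
    material of the moment and travels unchanged to the outlet, which is
    what produces the residence-time distribution of the pipe.
    """

    def __init__(
        self,
        config: PressConfig,
        fill_density_of: Callable[[str], float],
        initial: BlendKey | None = None,
    ):
        mid_r_cm = config.midstream_diameter_mm / 20.0
        inner_r_cm = config.pipe_inner_diameter_mm / 20.0
        self.area_mid_cm2 = math.pi * mid_r_cm ** 2
        self.area_outer_cm2 = math.pi * (inner_r_cm ** 2 - mid_r_cm ** 2)
        self.velocity_ratio = config.velocity_ratio
        v_dos = config.dosing_volume_cm3
        self.layer_height_cm = v_dos / (
            self.area_outer_cm2 + self.velocity_ratio * self.area_mid_cm2
        )
        self.n_layers = int(config.pipe_height_mm / 10.0 / self.layer_height_cm)
        if self.n_layers < self.velocity_ratio:
            raise ValueError(
                "pipe geometry infeasible: fewer layers than the midstream "
                "advances per event; increase pipe height or midstream diameter"
            )
        self.outer_volume_cm3 = self.area_outer_cm2 * self.layer_height_cm
        self.mid_volume_cm3 = self.area_mid_cm2 * self.layer_height_cm
        self._fill_density_of = fill_density_of
        # bottom of the pipe is the left end of each deque; one entry is
        # (blend key, parcel mass in g) — layers are single-source by design
        self._outer: deque[tuple[BlendKey, float]] = deque()
        self._mid: deque[tuple[BlendKey, float]] = deque()
        self._mass = 0.0
        if initial is not None:
            rho = fill_density_of(initial[0])
            for _ in range(self.n_layers):
                self._outer.append((initial, self.outer_volume_cm3 * rho))
                self._mid.append((initial, self.mid_volume_cm3 * rho))
            self._mass = self.n_layers * (self.outer_volume_cm3 + self.mid_volume_cm3) * rho

    @property
    def mass_g(self) -> float:
        return self._mass

    def recompute_mass(self) -> float:
        """Independent re-summation of all layer masses (ledger cross-check)."""
        return sum(m for _, m in self._outer) + sum(m for _, m in self._mid)

    @property
    def layers(self) -> list[PipeLayer]:
        """Bottom-to-top view of the pipe as shared-height layers."""
        out = []
        for (okey, _), (mkey, _) in zip(self._outer, self._mid):
            out.append(
                PipeLayer(
                    midstream_composition=BlendComposition.single(*mkey),
                    outer_composition=BlendComposition.single(*okey),
                    layer_height_cm=self.layer_height_cm,
                    midstream_volume_cm3=self.mid_volume_cm3,
                    outer_volume_cm3=self.outer_volume_cm3,
                )
            )
        return out

    def advance_and_extract(self, feed: BlendKey) -> tuple[dict[BlendKey, float], float]:
        """One fill event: drop the bottom layers, refill the top from the hopper.

        Returns ``(extracted masses, newly created hopper mass)``; the
        extracted bulk volume is exactly the dosing volume.
        """
        extracted: dict[BlendKey, float] = {}
        key, m = self._outer.popleft()
        extracted[key] = extracted.get(key, 0.0) + m
        removed = m
        for _ in range(self.velocity_ratio):
            key, m = self._mid.popleft()
            extracted[key] = extracted.get(key, 0.0) + m
            removed += m
        rho = self._fill_density_of(feed[0])
        created = (self.outer_volume_cm3 + self.velocity_ratio * self.mid_volume_cm3) * rho
        self._outer.append((feed, self.outer_volume_cm3 * rho))
        for _ in range(self.velocity_ratio):
            self._mid.append((feed, self.mid_volume_cm3 * rho))
        self._mass += created - removed
        return extracted, created


def build_pipe(
    config: PressConfig,
    materials: Mapping[str, MaterialSpec],
    initial: BlendKey,
) -> FillingPipe:
    """Construct a filling pipe homogeneously filled with one material."""
    fill_density_of = lambda mat: materials[mat].fill_density(config.fill_density_basis)
    return FillingPipe(config, fill_density_of, initial)


# ---------------------------------------------------------------------------
# Feed frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentState:
    """Snapshot of one feed-frame compartment."""

    index: int
    position: int
    composition: BlendComposition
    fill_volume_cm3: float
    bulk_density_g_cm3: float


class Holdup:
    """Powder parked between the pipe outlet and the feed-frame inlet."""

    def __init__(self):
        self._masses: dict[BlendKey, float] = {}

    def add(self, masses: Mapping[BlendKey, float]) -> None:
        for key, m in masses.items():
            self._masses[key] = self._masses.get(key, 0.0) + m

    @property
    def mass_g(self) -> float:
        return sum(self._masses.values())

    def volume_cm3(self, fill_density_of: Callable[[str], float]) -> float:
        return sum(m / fill_density_of(k[0]) for k, m in self._masses.items())

    def draw(self, volume_cm3: float, fill_density_of: Callable[[str], float]) -> dict[BlendKey, float]:
        """Remove up to ``volume_cm3`` of well-mixed powder."""
        have = self.volume_cm3(fill_density_of)
        if have <= _VOL_EPS or volume_cm3 <= 0.0:
            return {}
        frac = min(volume_cm3 / have, 1.0)
        out = {}
        for key in list(self._masses):
            take = self._masses[key] * frac
            out[key] = take
            remaining = self._masses[key] - take
            if remaining <= 0.0:
                del self._masses[key]
            else:
                self._masses[key] = remaining
        return out


class _Compartment:
    __slots__ = ("index", "masses")

    def __init__(self, index: int, masses: dict[BlendKey, float]):
        self.index = index
        self.masses = masses

    def volume_cm3(self, fill_density_of) -> float:
        return sum(m / fill_density_of(k[0]) for k, m in self.masses.items())

    def mass_g(self) -> float:
        return sum(self.masses.values())


class FeedFrame:
    """Rotating feed frame: twelve interspaces acting as stirred tanks.

    ``slots[p - 1]`` is the compartment currently at position ``p``;
    position 1 is the inlet under the pipe, ``output_position`` sits over
    the die. Per fill event the wheel advances ``rotation_steps_per_event``
    positions; every compartment that lands on or sweeps past the inlet is
    topped up to capacity from the inlet holdup, instantaneously and
    ideally mixed with its residual powder.
    """

    def __init__(
        self,
        config: PressConfig,
        fill_density_of: Callable[[str], float],
        initial: BlendKey | None = None,
    ):
        self.config = config
        self._fill_density_of = fill_density_of
        self.capacity_cm3 = config.compartment_capacity_cm3
        n = config.n_compartments
        self.slots: list[_Compartment] = []
        for i in range(n):
            masses: dict[BlendKey, float] = {}
            if initial is not None:
                masses[initial] = self.capacity_cm3 * fill_density_of(initial[0])
            self.slots.append(_Compartment(i + 1, masses))

    # -- inspection --------------------------------------------------------

    @property
    def mass_g(self) -> float:
        return sum(c.mass_g() for c in self.slots)

    def states(self) -> list[CompartmentState]:
        out = []
        for pos, comp in enumerate(self.slots, start=1):
            if comp.mass_g() <= 0.0:
                continue
            blend = BlendComposition.from_masses(comp.masses)
            vol = comp.volume_cm3(self._fill_density_of)
            out.append(
                CompartmentState(
                    index=comp.index,
                    position=pos,
                    composition=blend,
                    fill_volume_cm3=vol,
                    bulk_density_g_cm3=comp.mass_g() / vol,
                )
            )
        return out

    # -- behaviour ---------------------------------------------------------

    def donor_positions(self) -> list[int]:
        """Positions feeding the die, in the order they cross it.

        The compartment at the output position donates first; as the wheel
        turns, the compartments behind it (position - 1, - 2, ...) cross the
        die and donate the remaining, descending shares.
        """
        n = self.config.n_compartments
        p0 = self.config.output_position
        return [(p0 - 1 - j) % n + 1 for j in range(len(self.config.fill_ratios))]

    def fill_die(self) -> dict[BlendKey, float]:
        """Drain the die volume from the donor compartments.

        Each donor gives ``fill_ratio * V_dos`` of bulk volume; the donated
        masses keep the donor's composition. Raises :class:`UnderfillError`
        if a donor cannot supply its share.
        """
        v_dos = self.config.dosing_volume_cm3
        die_masses: dict[BlendKey, float] = {}
        for ratio, pos in zip(self.config.fill_ratios, self.donor_positions()):
            if ratio == 0.0:
                continue
            comp = self.slots[pos - 1]
            need = ratio * v_dos
            have = comp.volume_cm3(self._fill_density_of)
            if have < need - _VOL_EPS:
                raise UnderfillError(
                    f"compartment {comp.index} at position {pos} holds "
                    f"{have:.4g} cm3 but must donate {need:.4g} cm3"
                )
            frac = min(need / have, 1.0)
            for key in list(comp.masses):
                moved = comp.masses[key] * frac
                die_masses[key] = die_masses.get(key, 0.0) + moved
                remaining = comp.masses[key] - moved
                if remaining <= 0.0:
                    del comp.masses[key]
                else:
                    comp.masses[key] = remaining
        return die_masses

    def refill_compartment(self, comp: _Compartment, holdup: Holdup) -> None:
        """Top one compartment up to capacity from the inlet holdup."""
        void = self.capacity_cm3 - comp.volume_cm3(self._fill_density_of)
        if void <= _VOL_EPS:
            return
        incoming = holdup.draw(void, self._fill_density_of)
        for key, m in incoming.items():
            comp.masses[key] = comp.masses.get(key, 0.0) + m
        if comp.volume_cm3(self._fill_density_of) > self.capacity_cm3 * (1.0 + 1e-9):
            raise ValueError(f"compartment {comp.index} overfilled beyond capacity")

    def rotate(self, holdup: Holdup) -> None:
        """Advance all compartments; refill the ones passing the inlet.

        Compartments are refilled in the order in which they reach position
        1 during the sweep, so the earliest passer gets first access to the
        holdup.
        """
        n = self.config.n_compartments
        k = self.config.rotation_steps_per_event
        passers: list[tuple[int, int]] = []  # (steps until inlet, old position)
        for pos in range(1, n + 1):
            steps = (1 - pos) % n
            if 1 <= steps <= k or (steps == 0 and k >= n):
                passers.append((steps if steps else n, pos))
        for _, pos in sorted(passers):
            self.refill_compartment(self.slots[pos - 1], holdup)
        new_slots = [None] * n
        for pos in range(1, n + 1):
            new_slots[(pos - 1 + k) % n] = self.slots[pos - 1]
        self.slots = new_slots  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Compression and ejection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompressionResult:
    stress_mpa: float
    force_kn: float
    punch_distance_mm: float
    in_die_density_g_cm3: float


def compress(
    tablet_mass_g: float,
    composition: BlendComposition,
    config: PressConfig,
    kawakita: Mapping[str, KawakitaCoefficients],
) -> CompressionResult:
    """Solve the coupled punch-deflection/compression-stress system.

    The rigid-press case (zero compliance) inverts the Kawakita mixture
    model at the set minimal punch distance. With compliance c the punch
    distance is h = h_min + c F(P) and P must satisfy the self-consistency
    P = invert(rho(h(P))); that residual is monotone in P and is solved by
    bracketed root finding to 1e-6 MPa, after which (P, F, h) are exactly
    consistent by construction.
    """
    if tablet_mass_g <= 0.0:
        raise ValueError(f"tablet mass must be positive, got {tablet_mass_g!r}")
    area_mm2 = config.die_area_cm2 * 100.0
    h_min = config.min_punch_distance_mm
    c = config.machine_compliance_mm_per_kn

    def rho_at(h_mm: float) -> float:
        return in_die_density(tablet_mass_g, config.die_diameter_mm, h_mm)

    def force_kn(p_mpa: float) -> float:
        return p_mpa * area_mm2 / 1000.0  # MPa * mm2 = N

    if c == 0.0:
        rho = rho_at(h_min)
        stress = invert_compression_stress(rho, composition, kawakita, warn_low_stress=False)
        return CompressionResult(stress, force_kn(stress), h_min, rho)

    floor = mixture_kawakita_floor(composition, kawakita)
    ceil = mixture_kawakita_asymptote(composition, kawakita)

    def residual(p_mpa: float) -> float:
        rho = rho_at(h_min + c * force_kn(p_mpa))
        if rho >= ceil:  # punch still too close: any finite stress undershoots
            return p_mpa - 1e12
        if rho <= floor:
            return p_mpa
        return p_mpa - invert_compression_stress(
            rho, composition, kawakita, warn_low_stress=False
        )

    from scipy.optimize import brentq

    lo, hi = 0.0, 64.0
    try:
        while residual(hi) < 0.0:
            lo, hi = hi, hi * 4.0
            if hi > 1e8:
                raise ConvergenceError(
                    f"no compression stress below 1e8 MPa closes the punch gap for "
                    f"mass {tablet_mass_g:.4g} g"
                )
        stress = float(brentq(residual, lo, hi, xtol=1e-6, maxiter=100))
    except UnreachableDensityError as exc:  # pragma: no cover - defensive
        raise ConvergenceError(str(exc)) from exc
    force = force_kn(stress)
    h = h_min + c * force
    return CompressionResult(stress, force, h, rho_at(h))


@dataclass(frozen=True)
class TabletRecord:
    """Complete quality-attribute record of one tablet, with provenance."""

    index: int
    ejection_time_s: float
    mass_g: float
    composition: BlendComposition
    fill_density_g_cm3: float
    in_die_density_g_cm3: float
    compression_stress_mpa: float
    compression_force_kn: float
    punch_distance_mm: float
    out_die_density_g_cm3: float
    out_die_porosity: float
    tensile_strength_mpa: float | None

    def __post_init__(self):
        if self.out_die_density_g_cm3 > self.in_die_density_g_cm3 * (1.0 + 1e-12):
            raise ValueError("out-die density cannot exceed the in-die density")
        positives = (
            self.mass_g,
            self.fill_density_g_cm3,
            self.in_die_density_g_cm3,
            self.compression_stress_mpa,
            self.compression_force_kn,
            self.punch_distance_mm,
            self.out_die_density_g_cm3,
            self.out_die_porosity,
        )
        if min(positives) <= 0.0:
            raise ValueError(f"tablet quantities must be positive, got {positives}")


def eject(
    compression: CompressionResult,
    composition: BlendComposition,
    materials: Mapping[str, MaterialSpec],
    *,
    strength: StrengthMixCoefficients | None = None,
    reference_material: str | None = None,
    index: int = 0,
    ejection_time_s: float = 0.0,
    tablet_mass_g: float | None = None,
    fill_density_g_cm3: float | None = None,
) -> TabletRecord:
    """Apply the ejection physics and assemble the tablet record."""
    recovery = {}
    solids = {}
    for mat in composition.materials():
        spec = materials[mat]
        if spec.recovery is None:
            raise ValueError(f"material {mat!r} has no recovery calibration")
        recovery[mat] = spec.recovery
        solids[mat] = spec.solid_density
    rho_out = out_die_density(
        compression.stress_mpa, compression.in_die_density_g_cm3, composition, recovery
    )
    eps = out_die_porosity(rho_out, composition, solids)
    sigma = None
    if strength is not None:
        if reference_material is None:
            raise ValueError("strength mixing needs a reference material")
        sigma = tensile_strength(eps, composition.fraction_of(reference_material), strength)
    if tablet_mass_g is None or fill_density_g_cm3 is None:
        raise ValueError("tablet mass and fill density must be provided")
    return TabletRecord(
        index=index,
        ejection_time_s=ejection_time_s,
        mass_g=tablet_mass_g,
        composition=composition,
        fill_density_g_cm3=fill_density_g_cm3,
        in_die_density_g_cm3=compression.in_die_density_g_cm3,
        compression_stress_mpa=compression.stress_mpa,
        compression_force_kn=compression.force_kn,
        punch_distance_mm=compression.punch_distance_mm,
        out_die_density_g_cm3=rho_out,
        out_die_porosity=eps,
        tensile_strength_mpa=sigma,
    )


# ---------------------------------------------------------------------------
# Simulation loop
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Tablet records plus the bookkeeping evidence of one run."""

    records: list[TabletRecord]
    config: PressConfig
    hopper_dispensed_g: float
    ledger_max_rel_error: float
    event_log: list[dict] = field(default_factory=list)

    def to_frame(self):
        """Tablet records as a pandas DataFrame (one row per tablet)."""
        import pandas as pd

        rows = []
        lot_keys = sorted({k for r in self.records for k in r.composition.keys()})
        for r in self.records:
            row = {
                "index": r.index,
                "time_s": r.ejection_time_s,
                "time_min": r.ejection_time_s / 60.0,
                "mass_g": r.mass_g,
                "fill_density_g_cm3": r.fill_density_g_cm3,
                "in_die_density_g_cm3": r.in_die_density_g_cm3,
                "compression_stress_MPa": r.compression_stress_mpa,
                "compression_force_kN": r.compression_force_kn,
                "punch_distance_mm": r.punch_distance_mm,
                "out_die_density_g_cm3": r.out_die_density_g_cm3,
                "out_die_porosity": r.out_die_porosity,
                "tensile_strength_MPa": r.tensile_strength_mpa,
            }
            agg = r.composition.by_material()
            for mat in sorted({m for m, _ in lot_keys}):
                row[f"x_{mat}"] = agg.get(mat, 0.0)
            for mat, lot in lot_keys:
                row[f"x_{mat}:{lot}"] = r.composition[(mat, lot)]
            rows.append(row)
        return pd.DataFrame(rows)


def run_simulation(
    config: PressConfig,
    materials: Mapping[str, MaterialSpec],
    schedule: HopperSchedule,
    *,
    strength: StrengthMixCoefficients | None = None,
    reference_material: str | None = None,
    duration_min: float | None = None,
    record_events: bool = False,
) -> SimulationResult:
    """Run the full press event loop and return every tablet's record.

    Per event: fill the die from the feed-frame donors, advance the pipe by
    one extraction (creating fresh layers from the hopper), rotate the feed
    frame (refilling inlet passers from the extracted powder), compress and
    eject. Entirely deterministic; the mass-conservation ledger is asserted
    after every event at relative 1e-9.
    """
    if duration_min is None:
        duration_min = config.sim_duration_min
    if not schedule.entries:
        return SimulationResult([], config, 0.0, 0.0)
    for _, mat, _ in schedule.entries:
        if mat not in materials:
            raise KeyError(f"schedule references unknown material {mat!r}")

    fill_density_of = lambda mat: materials[mat].fill_density(config.fill_density_basis)
    fill_densities = {m: fill_density_of(m) for m in materials}
    kawakita = {m: spec.kawakita for m, spec in materials.items()}

    initial = schedule.key_at(0.0)
    pipe = FillingPipe(config, fill_density_of, initial)
    frame = FeedFrame(config, fill_density_of, initial)
    holdup = Holdup()

    dispensed = pipe.mass_g + frame.mass_g
    tablets_mass = 0.0
    records: list[TabletRecord] = []
    event_log: list[dict] = []
    max_rel = 0.0

    n_events = int(math.floor(duration_min * config.fills_per_min + 1e-9))
    for i in range(1, n_events + 1):
        t_s = i * config.event_period_s
        t_min = t_s / 60.0

        die_masses = frame.fill_die()
        extracted, created = pipe.advance_and_extract(schedule.key_at(t_min))
        holdup.add(extracted)
        dispensed += created
        frame.rotate(holdup)

        mass = sum(die_masses.values())
        composition = BlendComposition.from_masses(die_masses)
        fill_density = mix_bulk_density(composition, fill_densities)
        compression = compress(mass, composition, config, kawakita)
        record = eject(
            compression,
            composition,
            materials,
            strength=strength,
            reference_material=reference_material,
            index=i,
            ejection_time_s=t_s,
            tablet_mass_g=mass,
            fill_density_g_cm3=fill_density,
        )
        records.append(record)
        tablets_mass += mass

        holdings = pipe.recompute_mass() + holdup.mass_g + frame.mass_g + tablets_mass
        rel = abs(dispensed - holdings) / dispensed
        max_rel = max(max_rel, rel)
        if rel > _LEDGER_RTOL:
            raise MassBalanceError(
                f"mass ledger violated at t = {t_min:.4f} min: hopper dispensed "
                f"{dispensed:.9f} g but holdings sum to {holdings:.9f} g "
                f"(relative error {rel:.3e})"
            )
        if record_events:
            event_log.append(
                {
                    "event": i,
                    "time_s": t_s,
                    "die_mass_g": mass,
                    "holdup_volume_cm3": holdup.volume_cm3(fill_density_of),
                    "stress_MPa": compression.stress_mpa,
                    "ledger_rel_error": rel,
                }
            )

    return SimulationResult(records, config, dispensed, max_rel, event_log)
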