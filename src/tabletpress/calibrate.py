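"""Model calibration from tabular compaction data, plus sensitivity sweeps.

Three sub-models are fitted from measurements of calibration tablets:

* Kawakita compressibility from (stress, in-die density) curves,
* the two-point elastic-recovery model from state-density triplets of
  tablets compressed at a low and a high stress,
* the porosity-strength exponential from (porosity, tensile strength)
  compactability curves, whose pure-substance and 50:50 fits are then
  condensed into the composition mixing rule for sigma0 and kb.

The sweep helpers mirror the structural-parameter calibration of the press
model: simulate a material-changeover scenario over a grid of candidate
values and score each run against a reference tablet-weight series with the
mean absolute relative error f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .materials import KawakitaCoefficients, RecoveryCalibration, StrengthMixCoefficients

__all__ = [
    "CompressibilityDataset",
    "CompactabilityDataset",
    "KawakitaFitResult",
    "RDFitResult",
    "SweepResult",
    "fit_kawakita",
    "fit_recovery",
    "fit_rd",
    "derive_strength_mixing",
    "error_metric_f",
    "sample_series",
    "sweep_midstream_diameter",
    "sweep_fill_ratios",
]

DEFAULT_FIT_RANGE_MPA = (20.0, 350.0)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompressibilityDataset:
    """In-die density versus compression stress for one material."""

    material: str
    stress_mpa: tuple[float, ...]
    density_g_cm3: tuple[float, ...]

    def __post_init__(self):
        s = np.asarray(self.stress_mpa, dtype=float)
        d = np.asarray(self.density_g_cm3, dtype=float)
        if s.size != d.size or s.size == 0:
            raise ValueError("stress and density columns must be non-empty and equal length")
        if np.any(np.diff(s) <= 0.0):
            raise ValueError("stresses must be strictly increasing")
        if np.any(d <= 0.0):
            raise ValueError("densities must be positive")
        object.__setattr__(self, "stress_mpa", tuple(map(float, s)))
        object.__setattr__(self, "density_g_cm3", tuple(map(float, d)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stress_MPa": self.stress_mpa, "density_g_cm3": self.density_g_cm3}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, material: str = "") -> "CompressibilityDataset":
        frame = frame.sort_values("stress_MPa")
        return cls(material, tuple(frame["stress_MPa"]), tuple(frame["density_g_cm3"]))


@dataclass(frozen=True)
class CompactabilityDataset:
    """Tensile strength versus out-die porosity for one composition."""

    label: str
    porosity: tuple[float, ...]
    tensile_strength_mpa: tuple[float, ...]

    def __post_init__(self):
        e = np.asarray(self.porosity, dtype=float)
        s = np.asarray(self.tensile_strength_mpa, dtype=float)
        if e.size != s.size or e.size == 0:
            raise ValueError("porosity and strength columns must be non-empty and equal length")
        if np.any((e <= 0.0) | (e >= 1.0)):
            raise ValueError("porosities must lie strictly inside (0, 1)")
        if np.any(s <= 0.0):
            raise ValueError("tensile strengths must be positive")
        object.__setattr__(self, "porosity", tuple(map(float, e)))
        object.__setattr__(self, "tensile_strength_mpa", tuple(map(float, s)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"porosity": self.porosity, "tensile_strength_MPa": self.tensile_strength_mpa}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "") -> "CompactabilityDataset":
        return cls(label, tuple(frame["porosity"]), tuple(frame["tensile_strength_MPa"]))


@dataclass(frozen=True)
class SweepResult:
    """One sweep point: the candidate parameter value and its error f."""

    parameter: object
    f: float

    def __post_init__(self):
        if self.f < 0.0:
            raise ValueError("mean absolute relative error cannot be negative")


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KawakitaFitResult:
    coefficients: KawakitaCoefficients
    r_squared: float
    n_points: int
    stress_range_mpa: tuple[float, float]


def fit_kawakita(
    data: CompressibilityDataset,
    stress_range_mpa: tuple[float, float] = DEFAULT_FIT_RANGE_MPA,
) -> KawakitaFitResult:
    """Nonlinear least squares of the Kawakita density form.

    Fits rho(P) = rho0 (1 + b P) / (1 + (1 - a) b P) to all rows inside
    ``stress_range_mpa`` (the model is not trusted below 20 MPa). Starting
    values come from the data: rho0 from the lowest retained stress, a from
    a 5 %-above-maximum asymptote guess, b = 0.01 / MPa.
    """
    from scipy.optimize import curve_fit

    s = np.asarray(data.stress_mpa)
    d = np.asarray(data.density_g_cm3)
    lo, hi = stress_range_mpa
    keep = (s >= lo) & (s <= hi)
    s, d = s[keep], d[keep]
    if s.size < 4:
        raise ValueError(
            f"need at least 4 points inside {stress_range_mpa} MPa, got {s.size}"
        )

    def model(p, rho0, a, b):
        bp = b * p
        return rho0 * (1.0 + bp) / (1.0 + (1.0 - a) * bp)

    rho0_init = float(d[0])
    a_init = min(max(1.0 - rho0_init / (1.05 * float(d.max())), 0.05), 0.95)
    p0 = (rho0_init, a_init, 0.01)
    try:
        popt, _ = curve_fit(
            model,
            s,
            d,
            p0=p0,
            bounds=([1e-6, 1e-6, 1e-9], [np.inf, 1.0 - 1e-9, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Kawakita fit did not converge from initial values {p0}"
        ) from exc
    resid = d - model(s, *popt)
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return KawakitaFitResult(
        KawakitaCoefficients(rho0=float(popt[0]), a=float(popt[1]), b=float(popt[2])),
        r_squared=r2,
        n_points=int(s.size),
        stress_range_mpa=stress_range_mpa,
    )


def fit_recovery(measurements: pd.DataFrame) -> RecoveryCalibration:
    """Two-point recovery calibration from replicate state-density triplets.

    ``measurements`` needs columns ``stress_MPa``, ``rho_p_max``,
    ``rho_p_0`` and ``rho_out_die`` with exactly two distinct stress levels
    (replicates are averaged per level). The instantaneous-recovery line is
    the exact line through the two averaged points; the slow recovery is
    the mean of the two levels; the correction offset absorbs the residual
    between measured and interpolated out-die densities (zero by
    construction for two-point data).
    """
    required = {"stress_MPa", "rho_p_max", "rho_p_0", "rho_out_die"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    means = measurements.groupby("stress_MPa", sort=True).mean(numeric_only=True)
    if len(means) != 2:
        raise ValueError(
            f"need exactly two distinct calibration stresses, got {len(means)}"
        )
    (p_low, row_low), (p_high, row_high) = means.iterrows()
    cal = RecoveryCalibration(
        stress_low_mpa=float(p_low),
        stress_high_mpa=float(p_high),
        rho_p_max_low=float(row_low["rho_p_max"]),
        rho_p_0_low=float(row_low["rho_p_0"]),
        rho_out_die_low=float(row_low["rho_out_die"]),
        rho_p_max_high=float(row_high["rho_p_max"]),
        rho_p_0_high=float(row_high["rho_p_0"]),
        rho_out_die_high=float(row_high["rho_out_die"]),
    )
    # measured-minus-predicted out-die residual at the calibration stresses
    resid = 0.0
    for p, row in ((p_low, row_low), (p_high, row_high)):
        predicted = (
            row["rho_p_max"] - cal.delta_rho_in_die(float(p)) - cal.delta_rho_slow_avg
        )
        resid += float(row["rho_out_die"]) - predicted
    offset = resid / 2.0
    if abs(offset) < 1e-12:
        return cal
    return replace(cal, correction_offset=offset)


@dataclass(frozen=True)
class RDFitResult:
    sigma0_mpa: float
    kb: float
    r_squared: float
    n_points: int


def fit_rd(data: CompactabilityDataset) -> RDFitResult:
    """Porosity-strength exponential by linear least squares on ln(sigma).

    kb is minus the slope of ln(sigma) over porosity, sigma0 the
    exponentiated intercept; R^2 is reported on the fitted (log) variable.
    """
    eps = np.asarray(data.porosity)
    sig = np.asarray(data.tensile_strength_mpa)
    if eps.size < 3:
        raise ValueError(f"need at least 3 points, got {eps.size}")
    if float(np.ptp(eps)) < 1e-12:
        raise ValueError("porosities are ill-conditioned: no spread to fit a slope")
    log_sig = np.log(sig)
    slope, intercept = np.polyfit(eps, log_sig, 1)
    fitted = slope * eps + intercept
    ss_tot = float(np.sum((log_sig - log_sig.mean()) ** 2))
    r2 = 1.0 - float(np.sum((log_sig - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return RDFitResult(
        sigma0_mpa=float(np.exp(intercept)),
        kb=float(-slope),
        r_squared=r2,
        n_points=int(eps.size),
    )


def derive_strength_mixing(
    supports: Sequence[tuple[float, float, float]]
) -> StrengthMixCoefficients:
    """Mixing-rule coefficients from fits at x = 0, 1/2 and 1.

    Each support is ``(x, sigma0, kb)``. The exponential sigma0 rule is
    solved exactly through the three points: with equally spaced supports,
    (s1 - s0)/(s05 - s0) = e^{c2/2} + 1, giving c2 in closed form, then c1
    and c3 by linear solve. The linear kb rule is a least-squares line.
    """
    if len(supports) != 3:
        raise ValueError("need exactly three support points (x = 0, 0.5, 1)")
    by_x = {round(float(x), 12): (float(s0), float(kb)) for x, s0, kb in supports}
    if set(by_x) != {0.0, 0.5, 1.0}:
        raise ValueError(f"supports must sit at x = 0, 0.5 and 1, got {sorted(by_x)}")
    s0, kb0 = by_x[0.0]
    s05, kb05 = by_x[0.5]
    s1, kb1 = by_x[1.0]
    if not (s1 > s05 > s0):
        raise ValueError(
            f"sigma0 supports must increase strictly with x, got {(s0, s05, s1)}: "
            "the exponential form cannot be fitted"
        )
    ratio = (s1 - s0) / (s05 - s0)
    if ratio <= 2.0:
        raise ValueError(
            f"sigma0 supports are not convex enough for an exponential rule "
            f"(growth ratio {ratio:.4g} <= 2)"
        )
    half = ratio - 1.0  # e^{c2/2}
    c2 = 2.0 * math.log(half)
    c1 = (s05 - s0) / (half - 1.0)
    c3 = s0 - c1
    xs = np.array([0.0, 0.5, 1.0])
    kbs = np.array([kb0, kb05, kb1])
    m, n = np.polyfit(xs, kbs, 1)
    return StrengthMixCoefficients(c1=c1, c2=c2, c3=c3, m=float(m), n=float(n))


# ---------------------------------------------------------------------------
# Error metric and sweeps
# ---------------------------------------------------------------------------

def error_metric_f(expected: Iterable[float], simulated: Iterable[float]) -> float:
    """Mean absolute relative error f = mean(|exp - sim| / sim).

    The denominator is the simulated value. Series must be matched sample
    by sample (equal length); zero simulated values are rejected.
    """
    exp = np.asarray(list(expected), dtype=float)
    sim = np.asarray(list(simulated), dtype=float)
    if exp.size != sim.size or exp.size == 0:
        raise ValueError("series must be matched, non-empty and of equal length")
    if np.any(sim == 0.0):
        raise ValueError("simulated series contains zeros: relative error undefined")
    return float(np.mean(np.abs(exp - sim) / np.abs(sim)))


def sample_series(
    frame: pd.DataFrame,
    times_min: Sequence[float],
    column: str = "mass_g",
    time_column: str = "time_min",
) -> np.ndarray:
    """Value of ``column`` at the tablet nearest each sampling time."""
    t = frame[time_column].to_numpy()
    v = frame[column].to_numpy()
    idx = np.abs(t[None, :] - np.asarray(times_min, dtype=float)[:, None]).argmin(axis=1)
    return v[idx]


def _sweep(scenario, configs, parameters, reference: pd.DataFrame) -> list[SweepResult]:
    times = reference["time_min"].to_numpy()
    exp = reference["tablet_weight_g"].to_numpy()
    results = []
    for parameter, config in zip(parameters, configs):
        frame = scenario.run(config=config).to_frame()
        sim = sample_series(frame, times, column="mass_g")
        results.append(SweepResult(parameter=parameter, f=error_metric_f(exp, sim)))
    return results


def sweep_midstream_diameter(
    scenario,
    diameters_mm: Sequence[float],
    reference: pd.DataFrame,
) -> list[SweepResult]:
    """Changeover-scenario error f over a grid of midstream diameters.

    ``reference`` needs columns ``time_min`` and ``tablet_weight_g``; each
    candidate diameter reruns the scenario and scores the simulated tablet
    weight at the reference sampling times.
    """
    for d in diameters_mm:
        if d >= scenario.config.pipe_inner_diameter_mm:
            raise ValueError(
                f"midstream diameter {d} mm must stay below the pipe inner "
                f"diameter {scenario.config.pipe_inner_diameter_mm} mm"
            )
    configs = [
        replace(scenario.config, midstream_diameter_mm=float(d)) for d in diameters_mm
    ]
    return _sweep(scenario, configs, list(diameters_mm), reference)


def sweep_fill_ratios(
    scenario,
    ratio_sets: Sequence[Sequence[float]],
    reference: pd.DataFrame,
) -> list[SweepResult]:
    """Changeover-scenario error f over candidate die-filling patterns."""
    configs = [
        replace(scenario.config, fill_ratios=tuple(float(r) for r in rs))
        for rs in ratio_sets
    ]
    parameters = [tuple(float(r) for r in rs) for rs in ratio_sets]
    return _sweep(scenario, configs, parameters, reference)
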