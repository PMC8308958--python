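"""Ready-to-run scenarios and synthetic dataset generators.

The centrepiece is the anhydrous dicalcium phosphate (DCPA) material
changeover: a press running on the coarse grade A150 is switched to the
fine grade A60 after one minute and back twelve minutes later, and the
per-tablet quality attributes trace the transition as the new material
works its way through the filling pipe and feed frame.

The module also generates every synthetic dataset the calibration fits
need — compressibility curves, compactability curves, recovery triplets and
noisy reference time series — from known ground-truth coefficients, so that
parameter-recovery tests close the loop without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import CompactabilityDataset, CompressibilityDataset, sample_series
from .compaction import kb_of_x, sigma0_of_x
from .materials import (
    KawakitaCoefficients,
    MaterialSpec,
    RecoveryCalibration,
    StrengthMixCoefficients,
)
from .press import HopperSchedule, PressConfig, SimulationResult, run_simulation

__all__ = [
    "CaseStudyScenario",
    "SyntheticDatasetSpec",
    "build_case_study",
    "case_study_materials",
    "case_study_strength",
    "make_recovery_calibration",
    "generate_compressibility_data",
    "generate_compactability_data",
    "generate_recovery_data",
    "generate_reference_series",
    "generate_dataset",
    "CASE_STUDY_SAMPLING_MIN",
]

# Calibration stresses of the recovery experiment (MPa)
RECOVERY_STRESSES_MPA = (30.0, 400.0)
# The six stresses at which calibration tablets are compressed (MPa)
CALIBRATION_STRESSES_MPA = (30.0, 50.0, 100.0, 200.0, 300.0, 400.0)

# Sampling grid of the changeover experiment: every minute, except every
# two minutes between minutes 8 and 18.
CASE_STUDY_SAMPLING_MIN: tuple[float, ...] = tuple(
    float(t) for t in (*range(1, 9), 10, 12, 14, 16, 18, *range(19, 26))
)

# Elastic recovery assumed for the DCPA grades (no state-density triplets
# are published): instantaneous recovery grows linearly to 3 % of the
# in-die density at 400 MPa; slow post-ejection relaxation is a constant
# 0.015 g/cm3. Both are modest, as expected for a brittle, predominantly
# fragmenting excipient.
INSTANT_RECOVERY_AT_HIGH = 0.03
SLOW_RECOVERY_G_CM3 = 0.015


def make_recovery_calibration(
    kawakita: KawakitaCoefficients,
    *,
    stresses_mpa: tuple[float, float] = RECOVERY_STRESSES_MPA,
    instant_fraction_at_high: float = INSTANT_RECOVERY_AT_HIGH,
    slow_recovery_g_cm3: float = SLOW_RECOVERY_G_CM3,
) -> RecoveryCalibration:
    """Synthesize a two-point recovery calibration from a compressibility fit.

    The in-die densities at the calibration stresses come from the Kawakita
    model; the recovery magnitudes are assumptions (see module docstring).
    """
    p_low, p_high = stresses_mpa
    rho_low = kawakita.density(p_low)
    rho_high = kawakita.density(p_high)
    k = instant_fraction_at_high * rho_high / p_high  # linear through the origin
    return RecoveryCalibration(
        stress_low_mpa=p_low,
        stress_high_mpa=p_high,
        rho_p_max_low=rho_low,
        rho_p_0_low=rho_low - k * p_low,
        rho_out_die_low=rho_low - k * p_low - slow_recovery_g_cm3,
        rho_p_max_high=rho_high,
        rho_p_0_high=rho_high - k * p_high,
        rho_out_die_high=rho_high - k * p_high - slow_recovery_g_cm3,
    )


def case_study_materials() -> dict[str, MaterialSpec]:
    """The two DCPA grades of the changeover case study.

    Characteristic densities and Kawakita coefficients are the published
    values for DI-CAFOS A150 (coarse, x50 = 167 um) and A60 (fine,
    x50 = 64 um), both blended with 1 wt% magnesium stearate. The
    consolidated bulk densities (0.73 / 1.41 g/cm3) are the apparent
    after-filling densities; paddle-wheel consolidation puts them above the
    cylinder bulk densities.
    """
    import warnings

    a150_kawakita = KawakitaCoefficients(rho0=1.22954, a=0.4981, b=0.0072)
    a60_kawakita = KawakitaCoefficients(rho0=1.62302, a=0.4891, b=0.0041)
    a150 = MaterialSpec(
        name="A150",
        solid_density=2.842,
        bulk_density=0.68,
        tapped_density=0.75,
        consolidated_bulk_density=0.73,
        kawakita=a150_kawakita,
        recovery=make_recovery_calibration(a150_kawakita),
        x50_um=167.0,
    )
    with warnings.catch_warnings():
        # the published A60 fit extrapolates above the solid density
        warnings.simplefilter("ignore")
        a60 = MaterialSpec(
            name="A60",
            solid_density=2.849,
            bulk_density=1.33,
            tapped_density=1.51,
            consolidated_bulk_density=1.41,
            kawakita=a60_kawakita,
            recovery=make_recovery_calibration(a60_kawakita),
            x50_um=64.0,
        )
    return {"A150": a150, "A60": a60}


def case_study_strength() -> StrengthMixCoefficients:
    """Published sigma0/kb mixing coefficients (x = mass fraction of A150)."""
    return StrengthMixCoefficients(c1=19.99, c2=5.56, c3=28.32, m=3.80, n=15.09)


@dataclass(frozen=True)
class CaseStudyScenario:
    """A fully specified changeover run: press, materials, hopper timeline."""

    materials: dict[str, MaterialSpec]
    config: PressConfig
    schedule: HopperSchedule
    strength: StrengthMixCoefficients
    reference_material: str = "A150"
    sampling_times_min: tuple[float, ...] = CASE_STUDY_SAMPLING_MIN

    def run(self, config: PressConfig | None = None) -> SimulationResult:
        """Simulate the scenario (optionally under a modified press config)."""
        return run_simulation(
            config if config is not None else self.config,
            self.materials,
            self.schedule,
            strength=self.strength,
            reference_material=self.reference_material,
        )


# Press-frame compliance used for the case study (mm/kN). The punch
# distance grows with compression force; this value reconciles the
# simulated stresses with the reported operating points of the experiment
# (about 60 MPa on pure A150, about 200 MPa around 75 wt% A60).
CASE_STUDY_COMPLIANCE_MM_PER_KN = 0.048

# The changeover is induced after 1 min and resettled 12 min later.
CHANGEOVER_START_MIN = 1.0
CHANGEOVER_END_MIN = 13.0


def build_case_study(
    *,
    duration_min: float = 25.0,
    changeover_start_min: float = CHANGEOVER_START_MIN,
    changeover_end_min: float = CHANGEOVER_END_MIN,
) -> CaseStudyScenario:
    """The DCPA A150 -> A60 -> A150 changeover scenario, from constants only."""
    config = PressConfig(
        machine_compliance_mm_per_kn=CASE_STUDY_COMPLIANCE_MM_PER_KN,
        sim_duration_min=duration_min,
    )
    schedule = HopperSchedule(
        (
            (0.0, "A150", "pre"),
            (changeover_start_min, "A60", "feed"),
            (changeover_end_min, "A150", "post"),
        )
    )
    return CaseStudyScenario(
        materials=case_study_materials(),
        config=config,
        schedule=schedule,
        strength=case_study_strength(),
    )


# ---------------------------------------------------------------------------
# Synthetic dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Recipe for one synthetic calibration dataset.

    ``model`` selects the generator (``compressibility``, ``compactability``
    or ``recovery``); ``noise`` is ``none``, ``multiplicative_gaussian`` or
    ``lognormal`` with relative level ``sigma``; a fixed ``seed`` makes the
    realisation reproducible.
    """

    model: str
    noise: str = "none"
    sigma: float = 0.0
    seed: int = 0
    grid: tuple[float, ...] = ()
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in ("compressibility", "compactability", "recovery"):
            raise ValueError(f"unknown synthetic model {self.model!r}")
        if self.noise not in ("none", "multiplicative_gaussian", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.sigma < 0.0:
            raise ValueError("noise level cannot be negative")


def _noise_factors(noise: str, sigma: float, size: int, seed: int | None) -> np.ndarray:
    if noise == "none" or sigma == 0.0:
        return np.ones(size)
    rng = np.random.default_rng(seed)
    if noise == "multiplicative_gaussian":
        return 1.0 + sigma * rng.standard_normal(size)
    if noise == "lognormal":
        return rng.lognormal(mean=0.0, sigma=sigma, size=size)
    raise ValueError(f"unknown noise model {noise!r}")


def generate_compressibility_data(
    coefficients: KawakitaCoefficients,
    *,
    material: str = "",
    stresses_mpa: Sequence[float] = CALIBRATION_STRESSES_MPA,
    noise: str = "none",
    sigma: float = 0.0,
    seed: int | None = None,
) -> CompressibilityDataset:
    """Synthetic density-versus-stress curve from known Kawakita truth."""
    s = np.asarray(sorted(stresses_mpa), dtype=float)
    d = np.array([coefficients.density(p) for p in s])
    d = d * _noise_factors(noise, sigma, d.size, seed)
    return CompressibilityDataset(material, tuple(s), tuple(d))


def generate_compactability_data(
    strength: StrengthMixCoefficients,
    x_reference: float,
    *,
    label: str = "",
    porosities: Sequence[float] = (0.15, 0.22, 0.30, 0.38, 0.46, 0.55),
    noise: str = "none",
    sigma: float = 0.0,
    seed: int | None = None,
) -> CompactabilityDataset:
    """Synthetic strength-versus-porosity curve for one blend composition."""
    eps = np.asarray(sorted(porosities), dtype=float)
    s0 = sigma0_of_x(x_reference, strength)
    kb = kb_of_x(x_reference, strength)
    sig = s0 * np.exp(-kb * eps)
    sig = sig * _noise_factors(noise, sigma, sig.size, seed)
    return CompactabilityDataset(label, tuple(eps), tuple(sig))


def generate_recovery_data(
    calibration: RecoveryCalibration,
    *,
    n_replicates: int = 10,
    noise: str = "none",
    sigma: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate state-density triplets at the two calibration stresses."""
    rows = []
    truth = [
        (calibration.stress_low_mpa, calibration.rho_p_max_low,
         calibration.rho_p_0_low, calibration.rho_out_die_low),
        (calibration.stress_high_mpa, calibration.rho_p_max_high,
         calibration.rho_p_0_high, calibration.rho_out_die_high),
    ]
    factors = _noise_factors(noise, sigma, 2 * 3 * n_replicates, seed).reshape(2, n_replicates, 3)
    for (stress, pmax, p0, out), level in zip(truth, factors):
        for rep in range(n_replicates):
            f1, f2, f3 = level[rep]
            rows.append(
                {
                    "stress_MPa": stress,
                    "rho_p_max": pmax * f1,
                    "rho_p_0": min(p0 * f2, pmax * f1),
                    "rho_out_die": min(out * f3, p0 * f2),
                }
            )
    return pd.DataFrame(rows)


def generate_dataset(spec: SyntheticDatasetSpec):
    """Realise a :class:`SyntheticDatasetSpec`."""
    if spec.model == "compressibility":
        kwargs = dict(spec.params)
        coeffs = kwargs.pop("coefficients")
        if spec.grid:
            kwargs["stresses_mpa"] = spec.grid
        return generate_compressibility_data(
            coeffs, noise=spec.noise, sigma=spec.sigma, seed=spec.seed, **kwargs
        )
    if spec.model == "compactability":
        kwargs = dict(spec.params)
        strength = kwargs.pop("strength")
        x = kwargs.pop("x_reference")
        if spec.grid:
            kwargs["porosities"] = spec.grid
        return generate_compactability_data(
            strength, x, noise=spec.noise, sigma=spec.sigma, seed=spec.seed, **kwargs
        )
    kwargs = dict(spec.params)
    calibration = kwargs.pop("calibration")
    return generate_recovery_data(
        calibration, noise=spec.noise, sigma=spec.sigma, seed=spec.seed, **kwargs
    )


def generate_reference_series(
    scenario: CaseStudyScenario,
    *,
    weight_noise_cv: float = 0.0,
    fraction_noise_rsd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulated tablet series sampled on the experimental schedule.

    Stands in for a measured reference: runs the scenario, picks the tablet
    nearest each sampling time and optionally perturbs the weights with a
    multiplicative coefficient of variation (1.5 % mirrors the replicate
    scatter of weight measurements) and the changeover-material mass
    fraction with a relative standard deviation (11.7 % mirrors the dye
    assay scatter).
    """
    frame = scenario.run().to_frame()
    times = np.asarray(scenario.sampling_times_min, dtype=float)
    ref = pd.DataFrame({"time_min": times})
    for out_col, col in [
        ("tablet_weight_g", "mass_g"),
        ("compression_stress_MPa", "compression_stress_MPa"),
        ("out_die_porosity", "out_die_porosity"),
        ("tensile_strength_MPa", "tensile_strength_MPa"),
    ]:
        ref[out_col] = sample_series(frame, times, column=col)
    changeover = next(
        (m for m in scenario.materials if m != scenario.reference_material), None
    )
    if changeover is not None:
        col = f"x_{changeover}"
        if col in frame.columns:
            ref[col] = sample_series(frame, times, column=col)
        else:  # the material never reached a tablet within the run
            ref[col] = 0.0
    rng = np.random.default_rng(seed)
    if weight_noise_cv > 0.0:
        ref["tablet_weight_g"] *= 1.0 + weight_noise_cv * rng.standard_normal(len(ref))
    if fraction_noise_rsd > 0.0 and changeover is not None:
        col = f"x_{changeover}"
        noisy = ref[col] * (1.0 + fraction_noise_rsd * rng.standard_normal(len(ref)))
        ref[col] = noisy.clip(lower=0.0, upper=1.0)
    return ref
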