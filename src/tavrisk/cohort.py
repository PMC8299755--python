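"""Seeded synthetic cohort generator.

Emulates the study population the pipeline is meant for: elderly
aortic-stenosis patients treated with a self-expanding prosthesis, with
leaflet calcium deposits whose size and angular placement drive the risk of
conduction block.  Marginal distributions target the reported cohort
statistics (48 patients: 28 male / 20 female; age mean 79, range 71-88; BMI
mean 29.3, range 21.3-42.5; deposit thickness mean 3.2 mm, max 6.8 mm;
calcified volume roughly 318-683 mm^3; device sizes 23/26/29/31 mm).

Class labels come from a documented generative model: a linear score on the
conduction-zone stress summary (computed with the same forward physics as the
prediction pipeline, at a coarse labeling resolution) plus clinical terms,
passed through a logistic link.  Class balance is enforced by quota (28:20 at
n = 48, proportional otherwise) on the noisy latent score, which reproduces
the reported class split exactly while keeping the label's dependence on the
score intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .forward import ForwardModel
from .records import AorticRootGeometry, CalciumDeposit, PatientRecord
from .valves import AVAILABLE_SIZES, snap_size

__all__ = [
    "TruncNormal",
    "GroundTruthModel",
    "GeneratorParams",
    "generate_cohort",
    "assign_label",
    "sample_deposit_thickness",
]


@dataclass(frozen=True)
class TruncNormal:
    """Truncated normal distribution settings (mean/sd before truncation)."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not self.lower < self.upper:
            raise ValueError(f"invalid bounds ({self.lower}, {self.upper})")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng
        )


@dataclass(frozen=True)
class GroundTruthModel:
    """Generative label model: linear score -> logistic link -> label.

    The score combines the area-weighted mean conduction-zone von Mises
    stress (computed at the complete-frame configuration, theta = 0, with the
    patient's applied device size) with calcified volume and a few clinical
    factors.  ``noise_scale`` is the logistic temperature: 0 makes the label a
    deterministic function of the score sign (score 0 resolves to label 0).
    """

    stress_coeff: float = 1.5
    stress_center: float = 1.25  # MPa, typical summary at the applied size
    stress_scale: float = 0.3  # MPa, its across-cohort spread
    volume_coeff: float = 0.6
    volume_center: float = 500.0  # mm^3, midpoint of the total-volume range
    volume_scale: float = 105.0  # mm^3, uniform(318, 683) standard deviation
    sex_coeff: float = 0.25  # male = 1
    bmi_coeff: float = 0.2
    bmi_center: float = 29.3
    bmi_scale: float = 4.5
    diabetes_coeff: float = 0.3
    afib_coeff: float = 0.3
    intercept: float = -0.66
    noise_scale: float = 0.25
    label_resolution: tuple[int, int, int] = (16, 3, 1)
    band_height: float = 4.0
    half_angle_deg: float = 45.0

    def stress_summary(self, record: PatientRecord) -> float:
        """Forward-physics stress summary at the applied size, complete frame."""
        from .valves import ValveDesign

        fm = ForwardModel(
            record.geometry,
            record.deposits,
            resolution=self.label_resolution,
            band_height=self.band_height,
            half_angle_deg=self.half_angle_deg,
        )
        return fm.summary(ValveDesign(size=record.applied_valve_size, theta_deg=0.0))

    def score(self, record: PatientRecord, stress_summary: float | None = None) -> float:
        if stress_summary is None:
            stress_summary = self.stress_summary(record)
        return (
            self.intercept
            + self.stress_coeff * (stress_summary - self.stress_center) / self.stress_scale
            + self.volume_coeff
            * (record.calcified_volume - self.volume_center) / self.volume_scale
            + self.sex_coeff * (1.0 if record.sex == "male" else 0.0)
            + self.bmi_coeff * (record.bmi - self.bmi_center) / self.bmi_scale
            + self.diabetes_coeff * (1.0 if record.diabetes else 0.0)
            + self.afib_coeff * (1.0 if record.afib_history else 0.0)
        )


def assign_label(
    record: PatientRecord,
    truth: GroundTruthModel,
    seed: int,
    stress_summary: float | None = None,
) -> int:
    """Draw one AVB label: Bernoulli(logistic(score / noise_scale)).

    With ``noise_scale == 0`` the label is deterministic in the score sign;
    the boundary score 0 resolves to label 0.  ``stress_summary`` may be
    passed to reuse a precomputed forward solve.
    """
    score = truth.score(record, stress_summary)
    if truth.noise_scale == 0.0:
        return int(score > 0.0)
    p = 1.0 / (1.0 + math.exp(-score / truth.noise_scale))
    rng = np.random.default_rng(seed)
    return int(rng.random() < p)


@dataclass(frozen=True)
class GeneratorParams:
    """All distribution settings of the synthetic cohort generator.

    Quotas reproduce the reported 28:20 male:female and no-AVB:AVB splits.
    Blood-pressure and LVEF distributions are conventional clinical ranges
    (none are reported for this cohort); comorbidity prevalences default to
    0.3 for the same reason.
    """

    male_fraction: float = 28.0 / 48.0
    avb_fraction: float = 20.0 / 48.0
    age: TruncNormal = TruncNormal(79.0, 4.0, 71.0, 88.0)
    bmi: TruncNormal = TruncNormal(29.3, 4.5, 21.3, 42.5)
    systolic_bp: TruncNormal = TruncNormal(135.0, 15.0, 90.0, 200.0)
    diastolic_bp: TruncNormal = TruncNormal(75.0, 10.0, 50.0, 110.0)
    lvef: TruncNormal = TruncNormal(55.0, 8.0, 20.0, 75.0)
    comorbidity_prevalence: float = 0.3
    annulus_diameter: TruncNormal = TruncNormal(24.0, 2.0, 20.0, 28.0)
    wall_thickness_range: tuple[float, float] = (1.5, 2.5)
    annulus_height: float = 10.0
    wall_stiffness: float = 10.0
    root_volume_range: tuple[float, float] = (7000.0, 11000.0)
    leaflet_volume_range: tuple[float, float] = (1500.0, 3000.0)
    oversize_ratio: float = 1.15
    deposit_count_range: tuple[int, int] = (2, 6)
    deposit_thickness: TruncNormal = TruncNormal(3.2, 1.2, 0.5, 6.8)
    total_volume_range: tuple[float, float] = (318.0, 683.0)
    deposit_length_range: tuple[float, float] = (4.0, 12.0)
    irregular_fraction: float = 0.3
    cusp_probs: tuple[float, float, float] = (0.35, 0.35, 0.30)  # NCC, RCC, LCC
    center_radius_fraction: tuple[float, float] = (0.5, 0.85)
    truth: GroundTruthModel = field(default_factory=GroundTruthModel)

    def __post_init__(self) -> None:
        for name in (
            "wall_thickness_range",
            "root_volume_range",
            "leaflet_volume_range",
            "total_volume_range",
            "deposit_length_range",
            "center_radius_fraction",
        ):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: invalid bounds ({lo}, {hi})")
        if not 0 < self.deposit_count_range[0] <= self.deposit_count_range[1]:
            raise ValueError(f"invalid deposit count range {self.deposit_count_range}")
        if not (0.0 <= self.male_fraction <= 1.0 and 0.0 < self.avb_fraction < 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.cusp_probs) - 1.0) > 1e-9:
            raise ValueError(f"cusp probabilities must sum to 1, got {self.cusp_probs}")


def sample_deposit_thickness(
    n: int, rng: np.random.Generator, params: GeneratorParams | None = None
) -> np.ndarray:
    """Draw deposit thicknesses (mm) from the configured truncated normal."""
    params = params or GeneratorParams()
    return params.deposit_thickness.sample(n, rng)


#: Angular placement ranges per cusp: NCC and RCC flank the conduction zone
#: (within +-60 deg of the commissure); LCC lies opposite.
_CUSP_ANGLES = {"NCC": (0.0, 60.0), "RCC": (300.0, 360.0), "LCC": (60.0, 300.0)}


def _sample_deposits(
    rng: np.random.Generator, params: GeneratorParams, geom: AorticRootGeometry
) -> list[CalciumDeposit]:
    lo, hi = params.deposit_count_range
    count = int(rng.integers(lo, hi + 1))
    total_volume = float(rng.uniform(*params.total_volume_range))
    shares = rng.dirichlet(np.ones(count))
    thicknesses = params.deposit_thickness.sample(count, rng)
    cusps = rng.choice(["NCC", "RCC", "LCC"], size=count, p=params.cusp_probs)
    deposits = []
    a = geom.inner_radius
    for k in range(count):
        cusp = str(cusps[k])
        phi = float(rng.uniform(*_CUSP_ANGLES[cusp])) % 360.0
        r = float(rng.uniform(*params.center_radius_fraction)) * a
        z = float(rng.uniform(0.0, geom.annulus_height))
        length = float(rng.uniform(*params.deposit_length_range))
        irregular = bool(rng.random() < params.irregular_fraction)
        endpoints = None
        shape = "regular"
        if irregular:
            shape = "irregular"
            # rod tilted out of the tangent plane by a random pitch
            pitch = float(rng.uniform(-30.0, 30.0))
            yaw = float(rng.uniform(0.0, 360.0))
            direction = np.array(
                [
                    np.cos(np.deg2rad(pitch)) * np.cos(np.deg2rad(yaw)),
                    np.cos(np.deg2rad(pitch)) * np.sin(np.deg2rad(yaw)),
                    np.sin(np.deg2rad(pitch)),
                ]
            )
            from .records import cart_to_cyl, cyl_to_cart

            c_cart = cyl_to_cart((r, phi, z))
            half = min(length / 2.0, 0.95 * a)
            e1 = cart_to_cyl(c_cart - half * direction)
            e2 = cart_to_cyl(c_cart + half * direction)
            endpoints = (e1, e2)
        deposits.append(
            CalciumDeposit(
                center=(r, phi, z),
                thickness=float(thicknesses[k]),
                length=length,
                volume=float(total_volume * shares[k]),
                cusp=cusp,
                shape=shape,
                endpoints=endpoints,
            )
        )
    return deposits


def generate_cohort(
    n: int, seed: int, params: GeneratorParams | None = None
) -> list[PatientRecord]:
    """Generate ``n`` synthetic patients with ground-truth AVB labels.

    Identical ``(n, seed, params)`` produce identical cohorts.  Sex and class
    labels follow deterministic quotas; everything else is drawn from the
    configured distributions.
    """
    if n < 2:
        raise ValueError(f"need at least 2 patients to form two classes, got {n}")
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)

    n_male = int(round(n * params.male_fraction))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)

    ages = params.age.sample(n, rng)
    bmis = params.bmi.sample(n, rng)
    sys_bp = params.systolic_bp.sample(n, rng)
    dia_bp = params.diastolic_bp.sample(n, rng)
    lvefs = params.lvef.sample(n, rng)
    comorbid = rng.random((n, 4)) < params.comorbidity_prevalence

    records: list[PatientRecord] = []
    for i in range(n):
        diameter = float(params.annulus_diameter.sample(1, rng)[0])
        geom = AorticRootGeometry(
            annulus_circumference=np.pi * diameter,
            wall_thickness=float(rng.uniform(*params.wall_thickness_range)),
            annulus_height=params.annulus_height,
            wall_stiffness=params.wall_stiffness,
            root_volume=float(rng.uniform(*params.root_volume_range)),
            leaflet_volume=float(rng.uniform(*params.leaflet_volume_range)),
        )
        deposits = _sample_deposits(rng, params, geom)
        size = snap_size(params.oversize_ratio * diameter, AVAILABLE_SIZES)
        records.append(
            PatientRecord(
                id=i + 1,
                sex=str(sexes[i]),
                age=float(ages[i]),
                bmi=float(bmis[i]),
                systolic_bp=float(sys_bp[i]),
                diastolic_bp=float(dia_bp[i]),
                lvef=float(lvefs[i]),
                diabetes=bool(comorbid[i, 0]),
                afib_history=bool(comorbid[i, 1]),
                stroke_history=bool(comorbid[i, 2]),
                icb_history=bool(comorbid[i, 3]),
                geometry=geom,
                deposits=deposits,
                avb_label=0,
                applied_valve_size=size,
            )
        )

    truth = params.truth
    scores = np.array([truth.score(r) for r in records])
    latent = scores + truth.noise_scale * rng.logistic(0.0, 1.0, size=n)
    n_pos = int(round(n * params.avb_fraction))
    n_pos = min(max(n_pos, 1), n - 1)  # always both classes
    positive = np.argsort(-latent, kind="stable")[:n_pos]
    labels = np.zeros(n, dtype=int)
    labels[positive] = 1
    return [replace(r, avb_label=int(labels[i])) for i, r in enumerate(records)]
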