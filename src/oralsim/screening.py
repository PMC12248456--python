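"""Screening programs overlaid on the natural-history simulation.

A program screens the cohort at a fixed interval. At each round an invitee
may attend, a pre-malignant lesion (leukoplakia or erythroleukoplakia) may be
detected, and a detected lesion is cured with probability
compliance x efficacy, returning the individual to the normal state with
progression re-sampled at the individual's current intensities (relapse is
therefore possible). Optionally a health-education arm makes attendees cease
betel-quid chewing and smoking at their first attended screen, after which
the two pre-malignant transition intensities are recomputed. Screen-detected
cancer still counts as incident cancer: screening reduces incidence only by
treating premalignancy.

Effectiveness is the percentage reduction in cumulative incidence relative
to a no-intervention arm simulated from the same natural-history random
numbers (common random numbers; screening-specific draws come from a
separate stream, so an attendance of zero reproduces the control arm
exactly).

Two aspects of a real program are not pinned down by a single attendance and
compliance figure and are config-exposed here: whether attendance is re-drawn
independently at every round (the default) or is a persistent
attender/never-attender split, and whether an individual may receive
treatment repeatedly (the default) or a capped number of courses. See the
methods note for how these choices move the projected effectiveness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .nathist import (
    SCREENING_HORIZON,
    IndividualTrajectory,
    SimConfig,
    sample_trajectories,
)
from .profiles import RiskFactorProfile
from .scoring import (
    DEFAULT_BASELINES,
    BaselineHazards,
    CoefficientSet,
    assign_deciles,
    composite_scores,
    linear_predictors,
    transition_intensities,
)

__all__ = [
    "ScreeningConfig",
    "ProgramResult",
    "apply_screen",
    "apply_education",
    "run_program",
    "incidence_reduction",
]


@dataclass(frozen=True)
class ScreeningConfig:
    """Operating parameters of a screening program."""

    interval_years: float = 1.0
    attendance: float = 0.60
    compliance: float = 0.80
    efficacy: float = 0.50
    education: bool = False
    cessation_probability: float = 1.0
    first_screen_offset: float = 0.0
    sensitivity_leukoplakia: float = 1.0
    sensitivity_erythroleukoplakia: float = 1.0
    #: "per_round": an independent Bernoulli draw at every round;
    #: "persistent": a fixed attender subset of the cohort (the attendance
    #: probability selects who ever attends).
    attendance_model: str = "per_round"
    #: Maximum number of treatment courses per individual (None = unlimited).
    max_treatment_courses: int | None = None

    def __post_init__(self) -> None:
        if not self.interval_years > 0:
            raise ValueError("screening interval must be positive")
        for name in (
            "attendance",
            "compliance",
            "efficacy",
            "cessation_probability",
            "sensitivity_leukoplakia",
            "sensitivity_erythroleukoplakia",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.first_screen_offset < 0:
            raise ValueError("first screen offset must be nonnegative")
        if self.attendance_model not in ("persistent", "per_round"):
            raise ValueError(f"unknown attendance model {self.attendance_model!r}")
        if self.max_treatment_courses is not None and self.max_treatment_courses < 0:
            raise ValueError("max_treatment_courses must be nonnegative or None")

    def screen_times(self, horizon: float) -> np.ndarray:
        return np.arange(self.first_screen_offset, horizon, self.interval_years)


def apply_screen(
    trajectory: IndividualTrajectory,
    screen_time: float,
    rates: tuple[float, float, float],
    config: ScreeningConfig,
    rng: np.random.Generator,
) -> IndividualTrajectory:
    """One individual's single screening round.

    If the individual attends, occupies a pre-malignant state and is
    detected, then with probability compliance x efficacy the lesion is
    cured: the individual returns to the normal state and future progression
    is re-sampled at ``rates``. Cancer (state 4) is unaffected.
    """
    state = trajectory.state_at(screen_time)
    if state not in (2, 3):
        return trajectory
    if rng.random() >= config.attendance:
        return trajectory
    sensitivity = (
        config.sensitivity_leukoplakia
        if state == 2
        else config.sensitivity_erythroleukoplakia
    )
    if rng.random() >= sensitivity:
        return trajectory
    if rng.random() >= config.compliance * config.efficacy:
        return trajectory
    lam12, lam23, lam34 = rates
    t12 = screen_time + rng.exponential(1.0 / lam12)
    t23 = t12 + rng.exponential(1.0 / lam23)
    t34 = t23 + rng.exponential(1.0 / lam34)
    return IndividualTrajectory(t12, t23, t34)


def apply_education(
    profile: RiskFactorProfile,
    cessation_probability: float,
    rng: np.random.Generator,
) -> RiskFactorProfile:
    """Cessation intervention: betel and smoking drop to the reference level.

    With the given probability both exposure categories are set to 0 from
    this time onward (the two pre-malignant intensities are then recomputed
    by the caller); genotype, HPV and miRNA flags are unchanged.
    """
    if not 0 <= cessation_probability <= 1:
        raise ValueError("cessation probability must lie in [0, 1]")
    if rng.random() < cessation_probability:
        return replace(profile, betel_category=0, smoking_category=0)
    return profile


def incidence_reduction(screened_incidence: float, control_incidence: float) -> float:
    """Percentage reduction 100 x (1 - screened/control)."""
    if control_incidence <= 0:
        raise ZeroDivisionError(
            "incidence reduction undefined: control incidence is zero"
        )
    return 100.0 * (1.0 - screened_incidence / control_incidence)


def _reduction_se_pct(ps: float, pc: float, ns: int, nc: int) -> float:
    """Delta-method SE of the percentage reduction, treating arms as
    independent (conservative under common random numbers)."""
    if pc == 0:
        return float("nan")
    vs = ps * (1 - ps) / ns
    vc = pc * (1 - pc) / nc
    return 100.0 * np.sqrt(vs / pc**2 + (ps**2) * vc / pc**4)


@dataclass
class ProgramResult:
    """Screened-vs-control incidence and percentage reduction."""

    screening: ScreeningConfig
    horizon_years: float
    n: int
    control_cancers: int
    screened_cancers: int
    control_incidence: float
    screened_incidence: float
    reduction_pct: float
    reduction_se_pct: float
    undefined: bool
    decile_table: pd.DataFrame | None
    control_cancer: np.ndarray | None = None
    screened_cancer: np.ndarray | None = None


def _resample_from_state(
    mask: np.ndarray,
    state_floor: int,
    now: float,
    t12: np.ndarray,
    t23: np.ndarray,
    t34: np.ndarray,
    lam12: np.ndarray,
    lam23: np.ndarray,
    lam34: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Re-sample future event times for ``mask`` individuals, in place.

    ``state_floor`` is the state progression restarts from: 1 re-samples all
    three residual sojourns, 2 only the two remaining ones.
    """
    m = int(mask.sum())
    if m == 0:
        return
    if state_floor == 1:
        t12[mask] = now + rng.standard_exponential(m) / lam12[mask]
        t23[mask] = t12[mask] + rng.standard_exponential(m) / lam23[mask]
    else:
        t23[mask] = now + rng.standard_exponential(m) / lam23[mask]
    t34[mask] = t23[mask] + rng.standard_exponential(m) / lam34[mask]


def run_program(
    profiles: pd.DataFrame,
    screening: ScreeningConfig = ScreeningConfig(),
    sim: SimConfig = SimConfig(horizon_years=SCREENING_HORIZON),
    seed: int | None = None,
    coeffs: CoefficientSet | None = None,
    baselines: BaselineHazards = DEFAULT_BASELINES,
    deciles=None,
    keep_indicators: bool = False,
) -> ProgramResult:
    """Simulate a screened arm and a control arm on the same cohort.

    The pre-intervention trajectories of the two arms use common random
    numbers; screening-specific draws (attendance, detection, treatment,
    cessation, post-cure re-sampling) come from a separate stream. Returns
    overall and per-decile percentage reductions in cumulative incidence
    within the horizon.
    """
    if len(profiles) == 0:
        raise ValueError("empty cohort")
    if coeffs is None:
        coeffs = CoefficientSet.printed()
    if seed is None:
        seed = sim.seed
    horizon = sim.horizon_years

    intens = transition_intensities(profiles, coeffs, baselines)
    lam12 = intens["lambda12"].to_numpy()
    lam23 = intens["lambda23"].to_numpy()
    lam34 = intens["lambda34"].to_numpy()

    # Intensities after betel/smoking cessation: strip the exposure part of
    # the linear predictor from the two pre-malignant transitions.
    betel = profiles["betel_category"].to_numpy(dtype=int)
    smoking = profiles["smoking_category"].to_numpy(dtype=int)
    exposure12 = (
        coeffs.category_array("N->L", "betel")[betel]
        + coeffs.category_array("N->L", "smoking")[smoking]
    )
    exposure23 = (
        coeffs.category_array("L->E", "betel")[betel]
        + coeffs.category_array("L->E", "smoking")[smoking]
    )
    lam12_ceased = lam12 * np.exp(-exposure12)
    lam23_ceased = lam23 * np.exp(-exposure23)

    if deciles is None:
        deciles = assign_deciles(composite_scores(linear_predictors(profiles, coeffs)))
    else:
        deciles = np.asarray(deciles)

    n = len(profiles)
    rng_nat = np.random.default_rng(seed)
    rng_scr = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))

    # Control arm (shared natural-history draws).
    c_t12, c_t23, c_t34 = sample_trajectories(lam12, lam23, lam34, rng_nat)
    control_cancer = c_t34 <= horizon

    # Screened arm starts from the identical trajectories.
    t12, t23, t34 = c_t12.copy(), c_t23.copy(), c_t34.copy()
    cur12, cur23 = lam12.copy(), lam23.copy()
    ceased = np.zeros(n, dtype=bool)
    education_drawn = np.zeros(n, dtype=bool)
    courses = np.zeros(n, dtype=np.int32)
    if screening.attendance_model == "persistent":
        attender = rng_scr.random(n) < screening.attendance

    for when in screening.screen_times(horizon):
        active = t34 > when
        if screening.attendance_model == "persistent":
            attend = active & attender
        else:
            attend = active & (rng_scr.random(n) < screening.attendance)

        if screening.education:
            first = attend & ~education_drawn
            education_drawn |= first
            cease_now = first & (
                rng_scr.random(n) < screening.cessation_probability
            )
            if cease_now.any():
                ceased |= cease_now
                cur12[cease_now] = lam12_ceased[cease_now]
                cur23[cease_now] = lam23_ceased[cease_now]
                # Memorylessness: the residual sojourn in the current state is
                # re-drawn at the post-cessation rate.
                in_state1 = cease_now & (when < t12)
                in_state2 = cease_now & (t12 <= when) & (when < t23)
                _resample_from_state(
                    in_state1, 1, when, t12, t23, t34, cur12, cur23, lam34, rng_scr
                )
                _resample_from_state(
                    in_state2, 2, when, t12, t23, t34, cur12, cur23, lam34, rng_scr
                )

        state2 = attend & (t12 <= when) & (when < t23)
        state3 = attend & (t23 <= when) & (when < t34)
        u_detect = rng_scr.random(n)
        detected = (state2 & (u_detect < screening.sensitivity_leukoplakia)) | (
            state3 & (u_detect < screening.sensitivity_erythroleukoplakia)
        )
        if screening.max_treatment_courses is not None:
            detected &= courses < screening.max_treatment_courses
        treated = detected & (rng_scr.random(n) < screening.compliance)
        courses[treated] += 1
        cured = treated & (rng_scr.random(n) < screening.efficacy)
        _resample_from_state(
            cured, 1, when, t12, t23, t34, cur12, cur23, lam34, rng_scr
        )

    screened_cancer = t34 <= horizon

    pc = float(control_cancer.mean())
    ps = float(screened_cancer.mean())
    undefined = pc == 0
    reduction = float("nan") if undefined else incidence_reduction(ps, pc)

    rows = []
    for d in range(1, 11):
        mask = deciles == d
        nd = int(mask.sum())
        if nd == 0:
            raise ValueError(f"decile {d} is empty")
        pcd = float(control_cancer[mask].mean())
        psd = float(screened_cancer[mask].mean())
        rows.append(
            {
                "decile": d,
                "n": nd,
                "control_risk_per_1e5": pcd * 1e5,
                "screened_risk_per_1e5": psd * 1e5,
                "reduction_pct": (
                    float("nan") if pcd == 0 else incidence_reduction(psd, pcd)
                ),
                "reduction_se_pct": _reduction_se_pct(psd, pcd, nd, nd),
            }
        )

    return ProgramResult(
        screening=screening,
        horizon_years=horizon,
        n=n,
        control_cancers=int(control_cancer.sum()),
        screened_cancers=int(screened_cancer.sum()),
        control_incidence=pc,
        screened_incidence=ps,
        reduction_pct=reduction,
        reduction_se_pct=_reduction_se_pct(ps, pc, n, n),
        undefined=undefined,
        decile_table=pd.DataFrame(rows),
        control_cancer=control_cancer if keep_indicators else None,
        screened_cancer=screened_cancer if keep_indicators else None,
    )
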