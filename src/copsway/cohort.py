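"""Synthetic quiet-standing cohorts with planted group structure.

Real stabilometric recordings of children with hyperkinetic movement
disorders are rarely shared, so the analysis pipeline is exercised on a
generator that emulates their statistical signature. Each of the three
phenotypes — dystonia, chorea and mixed chorea–dystonia — produces COP
trials as the sum of three components per axis:

* an Ornstein–Uhlenbeck (OU) drift, the slow mean-reverting wander of the
  postural control loop (exact discretization, so any sampling rate gives
  the same continuous-time law);
* a sinusoidal oscillation with per-trial random frequency and phase,
  standing in for rhythmic involuntary movement;
* a Poisson train of brief half-sine pulses ("jerks"), standing in for
  abrupt involuntary excursions.

Subject-level heterogeneity enters as a multiplicative amplitude scale
``exp(b_i + age_slope·(age_i − age_mean) + therapy_effect·therapy_i)`` with
``b_i ~ N(0, subject_sd²)``: a log-linear structure a linear mixed model
with a per-subject random intercept can recover. The planted intercepts,
scales and expected feature orderings are returned as ground truth for
recovery tests.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import signal, stats

from .metrics import CopTrajectory

__all__ = [
    "GROUP_LABELS",
    "EXPECTED_ORDERINGS",
    "GroupPhenotype",
    "SimulationDesign",
    "CohortTrial",
    "GroundTruth",
    "default_phenotypes",
    "default_design",
    "simulate_ou",
    "simulate_trial",
    "draw_subjects",
    "simulate_cohort",
    "simulate_mixed_outcome",
]

#: Movement-disorder groups; the first is the analysis reference level.
GROUP_LABELS: tuple[str, ...] = ("dystonia", "chorea", "chorea_dystonia")

#: Direction of the group contrasts the generator is calibrated to plant,
#: as (feature, group, '<' or '>', other group).
EXPECTED_ORDERINGS: tuple[tuple[str, str, str, str], ...] = (
    ("MD_AP", "chorea", "<", "dystonia"),
    ("RMS_AP", "chorea", "<", "dystonia"),
    ("VEL_AP", "chorea", "<", "dystonia"),
    ("FREQ_COP", "chorea", ">", "dystonia"),
    ("FREQ_ML", "chorea", ">", "dystonia"),
    ("VEL_AP", "chorea_dystonia", ">", "dystonia"),
    ("FREQ_ML", "chorea_dystonia", ">", "dystonia"),
)

#: Duration of the half-sine jerk pulse, seconds. Fixed by convention;
#: only the rate and height are phenotype parameters.
JERK_PULSE_DURATION_S = 0.15


def _load_defaults() -> dict:
    text = (
        importlib.resources.files("copsway") / "defaults.yaml"
    ).read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class GroupPhenotype:
    """Sway-generator settings for one movement-disorder group."""

    label: str
    ou_theta: float          # 1/s, OU mean-reversion rate
    ou_sigma_ap: float       # mm/sqrt(s), AP diffusion scale
    ou_sigma_ml: float       # mm/sqrt(s), ML diffusion scale
    osc_amp: float           # mm, oscillation amplitude
    osc_freq_band: tuple[float, float]  # Hz, [f_lo, f_hi]
    jerk_rate: float         # events/s
    jerk_amp: float          # mm

    def __post_init__(self) -> None:
        if self.ou_theta <= 0:
            raise ValueError("ou_theta must be positive")
        for name in ("ou_sigma_ap", "ou_sigma_ml", "osc_amp",
                     "jerk_rate", "jerk_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        f_lo, f_hi = self.osc_freq_band
        if not 0 < f_lo < f_hi:
            raise ValueError("osc_freq_band must satisfy 0 < f_lo < f_hi")
        object.__setattr__(self, "osc_freq_band", (float(f_lo), float(f_hi)))


def default_phenotypes() -> dict[str, GroupPhenotype]:
    """The calibrated phenotype settings shipped with the package."""
    raw = _load_defaults()["phenotypes"]
    return {
        label: GroupPhenotype(label=label, **{
            **params, "osc_freq_band": tuple(params["osc_freq_band"]),
        })
        for label, params in raw.items()
    }


def _as_group_map(value, groups: Sequence[str]) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(groups) - set(value)
        if missing:
            raise ValueError(f"missing per-group values for {sorted(missing)}")
        return {g: float(value[g]) for g in groups}
    return {g: float(value) for g in groups}


@dataclass
class SimulationDesign:
    """Cohort-level generator parameters.

    Defaults reproduce the reference study composition: 16 subjects in
    three groups (6 dystonia / 5 chorea / 5 chorea–dystonia), 6 trials of
    60 s each, ages 10.68 ± 3.62 years truncated to [4.29, 18.22], and the
    observed per-group therapy fractions. ``age_slope`` and
    ``therapy_effect`` may be scalars or per-group mappings (per-group
    values plant group × covariate interactions).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(_load_defaults()["design"]["n_per_group"]))
    n_trials: int = 6
    duration_s: float = 60.0
    fs: float = 50.0
    age_mean: float = 10.68
    age_sd: float = 3.62
    age_range: tuple[float, float] = (4.29, 18.22)
    therapy_probability: dict[str, float] = field(
        default_factory=lambda: dict(
            _load_defaults()["design"]["therapy_probability"]))
    subject_sd: float = 0.2
    age_slope: float | dict[str, float] = -0.02
    therapy_effect: float | dict[str, float] = -0.15
    seed: int = 0
    phenotypes: dict[str, GroupPhenotype] = field(
        default_factory=default_phenotypes)

    def __post_init__(self) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group must name at least one group")
        for g, n in self.n_per_group.items():
            if n <= 0:
                raise ValueError(f"group {g!r} must have a positive count")
            if g not in self.phenotypes:
                raise ValueError(f"no phenotype defined for group {g!r}")
        for g in self.n_per_group:
            p = self.therapy_probability.get(g)
            if p is None or not 0 <= p <= 1:
                raise ValueError(
                    f"therapy_probability[{g!r}] must lie in [0, 1]")
        if self.n_trials <= 0 or self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("n_trials, duration_s and fs must be positive")
        if self.subject_sd < 0 or self.age_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        # validate per-group covariate maps eagerly
        self.age_slope_map()
        self.therapy_effect_map()

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.n_per_group)

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group.values())

    def age_slope_map(self) -> dict[str, float]:
        return _as_group_map(self.age_slope, self.groups)

    def therapy_effect_map(self) -> dict[str, float]:
        return _as_group_map(self.therapy_effect, self.groups)


def default_design(**overrides) -> SimulationDesign:
    """The shipped reference design, optionally with fields overridden."""
    return SimulationDesign(**overrides)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(seed)


def simulate_ou(
    theta: float, sigma: float, fs: float, duration_s: float, seed
) -> np.ndarray:
    """Exact-discretization Ornstein–Uhlenbeck path started at 0 [mm].

    ``x[n+1] = x[n]·exp(−θΔt) + ξ·sqrt(σ²/(2θ)·(1 − exp(−2θΔt)))`` with
    ξ standard normal, so the sampled path follows the continuous-time OU
    law exactly at any sampling rate. The stationary variance is σ²/(2θ).
    Identical seeds give bit-identical paths.
    """
    if theta <= 0 or fs <= 0 or duration_s <= 0:
        raise ValueError("theta, fs and duration_s must be positive")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = _as_rng(seed)
    n_steps = round(duration_s * fs)
    a = float(np.exp(-theta / fs))
    step_sd = float(np.sqrt(sigma ** 2 / (2.0 * theta) * (1.0 - a * a)))
    x = np.empty(n_steps + 1)
    x[0] = 0.0
    noise = step_sd * rng.standard_normal(n_steps)
    # lfilter implements the AR(1) recursion y[n] = noise[n] + a·y[n−1]
    x[1:] = signal.lfilter([1.0], [1.0, -a], noise)
    return x


def _jerk_train(
    rate: float, amp: float, fs: float, duration_s: float,
    n_samples: int, rng: np.random.Generator,
) -> np.ndarray:
    path = np.zeros(n_samples)
    n_events = rng.poisson(rate * duration_s)
    if n_events == 0:
        return path
    starts = rng.integers(0, n_samples, size=n_events)
    signs = rng.choice([-1.0, 1.0], size=n_events)
    pulse_len = max(2, round(JERK_PULSE_DURATION_S * fs))
    pulse = amp * np.sin(np.pi * np.linspace(0.0, 1.0, pulse_len))
    for start, sgn in zip(starts, signs):
        stop = min(start + pulse_len, n_samples)
        path[start:stop] += sgn * pulse[: stop - start]
    return path


def simulate_trial(
    phenotype: GroupPhenotype,
    subject_scale: float,
    fs: float,
    duration_s: float,
    seed,
) -> CopTrajectory:
    """One quiet-standing trial for a subject of the given phenotype.

    Both axes are ``subject_scale × (OU drift + oscillation + jerk
    train)``; the draw order is fixed, so the same seed gives the same
    trial bit-for-bit and the path is exactly linear in ``subject_scale``.
    """
    if subject_scale <= 0:
        raise ValueError("subject_scale must be positive")
    rng = _as_rng(seed)
    n_steps = round(duration_s * fs)
    time = np.arange(n_steps + 1) / fs

    axes = []
    for sigma in (phenotype.ou_sigma_ap, phenotype.ou_sigma_ml):
        drift = simulate_ou(phenotype.ou_theta, sigma, fs, duration_s, rng)
        f_lo, f_hi = phenotype.osc_freq_band
        osc_freq = rng.uniform(f_lo, f_hi)
        osc_phase = rng.uniform(0.0, 2.0 * np.pi)
        osc = phenotype.osc_amp * np.sin(
            2.0 * np.pi * osc_freq * time + osc_phase)
        jerks = _jerk_train(
            phenotype.jerk_rate, phenotype.jerk_amp, fs, duration_s,
            len(time), rng)
        axes.append(subject_scale * (drift + osc + jerks))

    return CopTrajectory(time=time, ap=axes[0], ml=axes[1])


@dataclass(frozen=True)
class CohortTrial:
    """One generated (or ingested) trial with its subject metadata."""

    subject_id: str
    trial_id: int
    trajectory: CopTrajectory
    group: str | None = None
    age_years: float | None = None
    therapy: int | None = None


@dataclass
class GroundTruth:
    """Planted parameters of a simulated cohort, for recovery tests."""

    subjects: pd.DataFrame  # subject_id, group, age_years, therapy,
                            # intercept, scale
    age_slope: dict[str, float]
    therapy_effect: dict[str, float]
    subject_sd: float
    seed: int
    expected_orderings: tuple[tuple[str, str, str, str], ...] = (
        EXPECTED_ORDERINGS)

    def to_json_dict(self) -> dict:
        return {
            "subjects": self.subjects.to_dict(orient="records"),
            "age_slope": self.age_slope,
            "therapy_effect": self.therapy_effect,
            "subject_sd": self.subject_sd,
            "seed": self.seed,
            "expected_orderings": [list(o) for o in self.expected_orderings],
        }


def draw_subjects(
    design: SimulationDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the subject table: group, age, therapy, random intercept, scale.

    Ages are truncated normal within ``design.age_range``; therapy flags
    are Bernoulli with the per-group probability; the amplitude scale is
    ``exp(b_i + age_slope_g·(age_i − age_mean) + therapy_effect_g·therapy_i)``.
    """
    slope = design.age_slope_map()
    effect = design.therapy_effect_map()
    lo, hi = design.age_range
    a = (lo - design.age_mean) / design.age_sd if design.age_sd > 0 else -np.inf
    b = (hi - design.age_mean) / design.age_sd if design.age_sd > 0 else np.inf

    rows = []
    idx = 0
    for group in design.groups:
        for _ in range(design.n_per_group[group]):
            idx += 1
            if design.age_sd > 0:
                age = float(stats.truncnorm.rvs(
                    a, b, loc=design.age_mean, scale=design.age_sd,
                    random_state=rng))
            else:
                age = design.age_mean
            therapy = int(rng.random() < design.therapy_probability[group])
            intercept = float(rng.normal(0.0, design.subject_sd))
            scale = float(np.exp(
                intercept
                + slope[group] * (age - design.age_mean)
                + effect[group] * therapy))
            rows.append({
                "subject_id": f"S{idx:02d}",
                "group": group,
                "age_years": age,
                "therapy": therapy,
                "intercept": intercept,
                "scale": scale,
            })
    return pd.DataFrame(rows)


def simulate_cohort(
    design: SimulationDesign,
) -> tuple[list[CohortTrial], GroundTruth]:
    """Generate a full cohort of trials plus its planted ground truth.

    Fully deterministic in ``design`` (including ``design.seed``): subject
    draws and every trial get independent child streams of one seed
    sequence, so the output is byte-identical across runs.
    """
    root = np.random.SeedSequence(design.seed)
    n_total = design.n_subjects * design.n_trials
    children = root.spawn(1 + n_total)
    subjects = draw_subjects(design, np.random.default_rng(children[0]))

    truth = GroundTruth(
        subjects=subjects,
        age_slope=design.age_slope_map(),
        therapy_effect=design.therapy_effect_map(),
        subject_sd=design.subject_sd,
        seed=design.seed,
    )

    trials: list[CohortTrial] = []
    stream = 1
    for row in subjects.itertuples(index=False):
        phenotype = design.phenotypes[row.group]
        for trial_id in range(1, design.n_trials + 1):
            traj = simulate_trial(
                phenotype, row.scale, design.fs, design.duration_s,
                children[stream])
            stream += 1
            trials.append(CohortTrial(
                subject_id=row.subject_id,
                trial_id=trial_id,
                trajectory=traj,
                group=row.group,
                age_years=row.age_years,
                therapy=row.therapy,
            ))
    return trials, truth


def simulate_mixed_outcome(
    design: SimulationDesign,
    beta: Mapping[str, float],
    resid_sd: float,
    seed=None,
    outcome: str = "y",
) -> pd.DataFrame:
    """Trial-level table whose outcome follows the group/age/therapy linear
    mixed model exactly.

    The subject table is drawn as in :func:`simulate_cohort`; the response
    is ``y = Xβ + b_i + ε`` with the same fixed-effect design matrix the
    analysis fits (age centered at the realized sample mean), Gaussian
    residuals of sd ``resid_sd`` and random intercepts of sd
    ``design.subject_sd``. ``beta`` maps term names (see
    :data:`copsway.analysis.TERMS`) to coefficients; omitted terms are 0.
    Used as the oracle for coefficient-recovery, CI-coverage and
    type-I-error simulations, bypassing the trajectory generator.
    """
    from .analysis import TERMS, build_design_matrix

    unknown = set(beta) - set(TERMS)
    if unknown:
        raise ValueError(f"unknown terms in beta: {sorted(unknown)}")
    rng = _as_rng(design.seed if seed is None else seed)
    subjects = draw_subjects(design, rng)
    df = subjects.loc[
        subjects.index.repeat(design.n_trials),
        ["subject_id", "group", "age_years", "therapy"],
    ].reset_index(drop=True)
    df["trial_id"] = np.tile(
        np.arange(1, design.n_trials + 1), len(subjects))

    x_mat, names, _ = build_design_matrix(df)
    beta_vec = np.array([float(beta.get(name, 0.0)) for name in names])
    b_subject = dict(zip(subjects["subject_id"],
                         rng.normal(0.0, design.subject_sd, len(subjects))))
    df[outcome] = (
        x_mat @ beta_vec
        + df["subject_id"].map(b_subject).to_numpy()
        + rng.normal(0.0, resid_sd, len(df))
    )
    return df
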