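"""Seeded synthetic sepsis-cohort generator with known trajectory archetypes.

The generator emulates the statistical structure of a multi-center ICU sepsis
cohort in which risk trajectories bifurcate after a rapid latent transition:

* 28 clinical variables observed at feature-specific, irregular times
  (homogeneous Poisson sampling; vitals roughly hourly, lactate every ~11 h);
* a latent sepsis -> pre-shock transition event at which lactate and heart
  rate rise and blood pressures fall in a coordinated sigmoid completing
  within 30-60 minutes;
* G trajectory archetypes that share a common pre-transition baseline
  distribution but plateau at archetype-specific post-transition severities;
* fluid bolus, vasopressor and antibiotic order events whose timing relative
  to the transition is graded by archetype (the most severe archetypes are
  treated latest relative to deterioration, the mildest are often treated
  before it);
* septic-shock and mortality outcomes drawn per archetype, with shock-state
  confirmation gated by when a lactate measurement actually exceeds
  2 mmol/L -- in mild archetypes the lactate plateau sits near the 2 mmol/L
  criterion, so confirmation waits for a favourable (late) sample, which is
  what stretches their time from early warning to labeled shock onset.

Everything is reproducible from ``SynthConfig.seed`` via per-patient
``numpy.random.SeedSequence`` streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigError
from .features import FEATURES, FEATURE_BY_NAME, PRESSOR_RESPONSIVE
from .records import HOUR, GroundTruth, PatientRecord

# Per-archetype anchor defaults (4 archetypes, most to least severe). Other
# values of G interpolate linearly between the ends of these ladders.
_DEF_PREVALENCE = (0.76, 0.46, 0.26, 0.10)
_DEF_MORTALITY = (0.43, 0.34, 0.22, 0.18)
_DEF_SEVERITY = (1.0, 0.78, 0.65, 0.50)
_DEF_WEIGHTS = (0.17, 0.30, 0.39, 0.14)
_DEF_VASO_OFFSET = (3.5, 5.5, 9.0, 18.0)
_DEF_FLUID_OFFSET = (2.0, 1.5, 1.0, -0.5)
_DEF_ABX_OFFSET = (1.5, 0.75, 0.0, -1.0)
_DEF_LACTATE_TRIGGER = (0.95, 0.85, 0.70, 0.60)
_DEF_EARLY_VASO = (0.08, 0.22, 0.35, 0.55)


def _interp(values: tuple[float, ...], g: int) -> tuple[float, ...]:
    """Resize a 4-anchor per-archetype ladder to ``g`` levels."""
    if g == len(values):
        return tuple(float(v) for v in values)
    x = np.linspace(0.0, 1.0, g)
    xp = np.linspace(0.0, 1.0, len(values))
    return tuple(float(v) for v in np.interp(x, xp, values))


@dataclass
class SynthConfig:
    """Configuration of the synthetic cohort.

    Per-archetype tuples are ordered from the most to the least severe
    archetype; tuples of a length different from ``n_archetypes`` raise a
    :class:`~shocktraj.exceptions.ConfigError`, unless left at their defaults,
    in which case they are interpolated to ``n_archetypes`` levels.
    """

    n_patients: int = 400
    n_archetypes: int = 4
    shock_prevalence_by_archetype: tuple[float, ...] = _DEF_PREVALENCE
    mortality_by_archetype: tuple[float, ...] = _DEF_MORTALITY
    severity_by_archetype: tuple[float, ...] = _DEF_SEVERITY
    archetype_weights: tuple[float, ...] = _DEF_WEIGHTS
    transition_jump_minutes: tuple[float, float] = (30.0, 60.0)
    transition_window_h: tuple[float, float] = (14.0, 24.0)
    horizon_hours: float = 60.0
    feature_schedule: dict[str, float] | None = None  # overrides interval_h
    # intervention timing relative to the transition (hours, signed);
    # the vasopressor offset is the start of the definitive sustained
    # infusion that marks refractory hypotension in shock-bound patients
    intervention_vaso_offset_h: tuple[float, ...] = _DEF_VASO_OFFSET
    intervention_fluid_offset_h: tuple[float, ...] = _DEF_FLUID_OFFSET
    intervention_abx_offset_h: tuple[float, ...] = _DEF_ABX_OFFSET
    vaso_offset_sd_h: float = 1.5
    # transient early pressor support (weaned before the definitive course);
    # its probability grades how often shock patients are already on
    # vasopressors by the time of early prediction
    early_vaso_prob: tuple[float, ...] = _DEF_EARLY_VASO
    early_vaso_offset_h: float = -2.0
    early_vaso_sd_h: float = 0.8
    early_vaso_duration_h: tuple[float, float] = (1.0, 2.0)
    fluid_offset_sd_h: float = 1.0
    abx_offset_sd_h: float = 1.5
    # probability that deterioration triggers a prompt lactate order
    lactate_trigger_prob: tuple[float, ...] = _DEF_LACTATE_TRIGGER
    lactate_trigger_window_h: tuple[float, float] = (1.0, 3.0)
    nonshock_fluid_prob: float = 0.8
    # blood-pressure response to vasopressors
    pressor_response_frac: float = 0.85
    pressor_response_tau_h: float = 0.75
    # treatment response of patients who never reach shock: their latent
    # deterioration recedes slowly and partially after the first intervention
    nonshock_recovery_frac: float = 0.8
    nonshock_recovery_tau_h: float = 5.0
    # hyperlactatemia scales convexly with severity, keeping only the mildest
    # archetype's lactate plateau near the 2 mmol/L shock criterion
    lactate_severity_exponent: float = 1.6
    nonshock_los_after_transition_h: tuple[float, float] = (12.0, 20.0)
    shock_record_tail_h: float = 14.0
    # latent severity observation noise used by severity_trajectory_matrix;
    # the default puts adjacent archetype plateaus 4 noise-SDs apart
    severity_noise_sd: float = 0.0325
    bolus_ml: float = 500.0
    bolus_interval_min: float = 20.0
    resus_target_ml_per_kg: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        g = self.n_archetypes
        for name in ("shock_prevalence_by_archetype", "mortality_by_archetype",
                     "severity_by_archetype", "archetype_weights",
                     "intervention_vaso_offset_h", "intervention_fluid_offset_h",
                     "intervention_abx_offset_h", "lactate_trigger_prob",
                     "early_vaso_prob"):
            val = tuple(getattr(self, name))
            if len(val) != g:
                default = next(f.default for f in dataclasses.fields(self)
                               if f.name == name)
                if val == default:
                    val = _interp(val, g)
                else:
                    raise ConfigError(f"{name}: expected {g} entries, got {len(val)}")
            setattr(self, name, val)
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients: must be >= 0")
        if self.n_archetypes < 2:
            raise ConfigError("n_archetypes: must be >= 2")
        lo, hi = self.transition_jump_minutes
        if not lo < hi:
            raise ConfigError("transition_jump_minutes: low must be < high")
        for name in ("shock_prevalence_by_archetype", "mortality_by_archetype",
                     "lactate_trigger_prob", "early_vaso_prob"):
            vals = getattr(self, name)
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
        if self.horizon_hours <= 0:
            raise ConfigError("horizon_hours: must be > 0")
        if self.feature_schedule is not None:
            for k, v in self.feature_schedule.items():
                if v <= 0:
                    raise ConfigError(f"feature_schedule[{k}]: interval must be > 0")
        if not 0.0 <= self.nonshock_fluid_prob <= 1.0:
            raise ConfigError("nonshock_fluid_prob: must lie in [0, 1]")

    def interval_h(self, feature: str) -> float:
        if self.feature_schedule and feature in self.feature_schedule:
            return float(self.feature_schedule[feature])
        return FEATURE_BY_NAME[feature].interval_h


# --------------------------------------------------------------------- latent
def latent_curve(feature: str, times: np.ndarray, *, baseline: float,
                 severity: float, transition: float, width: float,
                 vaso_time: float | None = None,
                 pressor_frac: float = 0.85,
                 pressor_tau_min: float = 45.0,
                 recovery_time: float | None = None,
                 recovery_frac: float = 0.85,
                 recovery_tau_min: float = 360.0) -> np.ndarray:
    """Latent (noise-free) value of ``feature`` at ``times`` (minutes).

    A stationary baseline shifts by ``severity * spec.shift`` through a
    logistic sigmoid centered at ``transition``; the logistic scale is
    ``width / 10`` so ~98.7% of the shift completes inside the jump window.
    Two treatment-response layers act on the shift: blood pressures partially
    recover toward baseline once hemodynamic support (fluid resuscitation or
    vasopressors) is running (``vaso_time`` names the earlier of the two),
    and - for patients whose sepsis responds to treatment - the whole
    deterioration recedes exponentially from ``recovery_time`` on.
    """
    spec = FEATURE_BY_NAME[feature]
    t = np.asarray(times, dtype=float)
    sig = expit((t - transition) / (width / 10.0))
    shift = spec.shift * severity * sig
    if vaso_time is not None and feature in PRESSOR_RESPONSIVE:
        dt = np.clip(t - vaso_time, 0.0, None)
        recovery = pressor_frac * (1.0 - np.exp(-dt / pressor_tau_min))
        shift = shift * (1.0 - recovery)
    if recovery_time is not None:
        dt = np.clip(t - recovery_time, 0.0, None)
        recovery = recovery_frac * (1.0 - np.exp(-dt / recovery_tau_min))
        shift = shift * (1.0 - recovery)
    return baseline + shift


def _poisson_times(rng: np.random.Generator, interval_min: float,
                   end: float) -> np.ndarray:
    """Homogeneous Poisson event times on (0, end]."""
    if end <= 0:
        return np.empty(0)
    n_guess = max(8, int(end / interval_min * 2.0) + 8)
    gaps = rng.exponential(interval_min, size=n_guess)
    t = np.cumsum(gaps)
    while t[-1] <= end:  # pragma: no cover - astronomically rare with 2x margin
        t = np.concatenate([t, t[-1] + np.cumsum(
            rng.exponential(interval_min, size=n_guess))])
    return t[t <= end]


def simulate_patient(archetype: int, config: SynthConfig,
                     rng: np.random.Generator,
                     patient_id: str = "p0") -> tuple[PatientRecord, dict]:
    """Simulate one patient; returns the record and its ground-truth row.

    The ground-truth dict carries the archetype, latent transition time,
    per-feature baselines and (for shock patients) the intended shock onset.
    """
    if not 0 <= archetype < config.n_archetypes:
        raise ConfigError(f"archetype: must be < n_archetypes, got {archetype}")
    g = archetype
    horizon = config.horizon_hours * HOUR
    severity = config.severity_by_archetype[g]

    weight = float(np.clip(rng.normal(80.0, 15.0), 40.0, 160.0))
    icu_admit = float(rng.uniform(0.0, 120.0))
    infection_time = float(rng.uniform(0.0, 60.0))
    transition = float(rng.uniform(*config.transition_window_h)) * HOUR
    width = float(rng.uniform(*config.transition_jump_minutes))

    shock = bool(rng.random() < config.shock_prevalence_by_archetype[g])
    died = bool(rng.random() < config.mortality_by_archetype[g])

    # ----------------------------------------------------------- intervention
    abx_time = transition + rng.normal(config.intervention_abx_offset_h[g],
                                       config.abx_offset_sd_h) * HOUR
    abx_time = float(max(abx_time, 5.0))

    fluid_events = np.empty((0, 2))
    fluid_start = None
    if shock or rng.random() < config.nonshock_fluid_prob:
        fluid_start = transition + rng.normal(config.intervention_fluid_offset_h[g],
                                              config.fluid_offset_sd_h) * HOUR
        fluid_start = float(max(fluid_start, 5.0))
        n_boluses = int(np.ceil(config.resus_target_ml_per_kg * weight
                                / config.bolus_ml))
        times = fluid_start + np.arange(n_boluses) * config.bolus_interval_min
        fluid_events = np.column_stack([times, np.full(n_boluses, config.bolus_ml)])

    vaso_events = np.empty((0, 2))
    vaso_time = None  # definitive sustained infusion (shock-bound patients)
    if shock:
        vaso_time = transition + rng.normal(config.intervention_vaso_offset_h[g],
                                            config.vaso_offset_sd_h) * HOUR
        vaso_time = float(max(vaso_time, 45.0))
        events = []
        if rng.random() < config.early_vaso_prob[g]:
            t1 = transition + rng.normal(config.early_vaso_offset_h,
                                         config.early_vaso_sd_h) * HOUR
            t1 = float(max(t1, 5.0))
            t2 = t1 + rng.uniform(*config.early_vaso_duration_h) * HOUR
            if t2 < vaso_time:  # transient support, weaned before the infusion
                events += [[t1, 1.0], [t2, 0.0]]
            else:  # merges into one continuous course
                vaso_time = min(vaso_time, t1)
        events.append([vaso_time, 1.0])
        vaso_events = np.array(sorted(events))

    # -------------------------------------------------------------- baselines
    baselines = {}
    for spec in FEATURES:
        baselines[spec.name] = float(rng.normal(spec.baseline_mean, spec.baseline_sd))

    pressor_tau_min = config.pressor_response_tau_h * HOUR
    # blood pressures respond to hemodynamic support of either kind
    bp_support = [t for t in (fluid_start, vaso_time) if t is not None]
    bp_support_time = float(max(min(bp_support), transition)) if bp_support else None
    # patients who never progress to shock respond to treatment: their latent
    # deterioration recedes after the first intervention
    recovery_time = None
    if not shock:
        candidates = [abx_time]
        if fluid_start is not None:
            candidates.append(fluid_start)
        recovery_time = float(max(min(candidates), transition))

    def latent(feature: str, t: np.ndarray) -> np.ndarray:
        sev = severity
        if feature == "lactate":
            sev = severity ** config.lactate_severity_exponent
        return latent_curve(feature, t, baseline=baselines[feature],
                            severity=sev, transition=transition, width=width,
                            vaso_time=bp_support_time,
                            pressor_frac=config.pressor_response_frac,
                            pressor_tau_min=pressor_tau_min,
                            recovery_time=recovery_time,
                            recovery_frac=config.nonshock_recovery_frac,
                            recovery_tau_min=config.nonshock_recovery_tau_h * HOUR)

    # --------------------------------------------------------- observations
    rows = []
    for spec in FEATURES:
        t = _poisson_times(rng, config.interval_h(spec.name) * HOUR, horizon)
        if spec.name == "lactate" and rng.random() < config.lactate_trigger_prob[g]:
            # deterioration prompts a lactate order shortly after the transition
            trig = transition + rng.uniform(*config.lactate_trigger_window_h) * HOUR
            t = np.sort(np.append(t, trig))
        if not t.size:
            continue
        vals = latent(spec.name, t) + rng.normal(0.0, spec.noise_sd, size=t.size)
        vals = np.clip(vals, spec.lo, spec.hi)
        rows.append(pd.DataFrame({"time": t, "feature": spec.name, "value": vals}))
    obs = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["time", "feature", "value"])

    # ------------------------------------------------- intended shock onset
    true_onset = np.nan
    if shock:
        lact = obs[obs["feature"] == "lactate"]
        confirmed = lact[lact["value"] > 2.0]
        if len(confirmed):
            confirm_time = float(confirmed["time"].min())
            # MAP back over 65 mmHg on pressors (analytic recovery crossing)
            map_shift = FEATURE_BY_NAME["map"].shift * severity
            map_floor = baselines["map"] + map_shift
            support = bp_support_time if bp_support_time is not None else vaso_time
            if map_floor >= 65.0:
                map_ok = vaso_time
            else:
                needed = (65.0 - map_floor) / (-map_shift * config.pressor_response_frac)
                if 0.0 < needed < 1.0:
                    map_ok = support - pressor_tau_min * np.log1p(-needed)
                else:  # support cannot restore MAP; criterion met per lenient gate
                    map_ok = support
            resus_est = float(fluid_events[-1, 0]) if fluid_events.size else np.inf
            true_onset = float(max(confirm_time, vaso_time, map_ok,
                                   min(resus_est, fluid_start or np.inf)))
            if true_onset > horizon:
                true_onset = np.nan

    # ---------------------------------------------------------- record end
    if shock and np.isfinite(true_onset):
        end = min(horizon, true_onset + config.shock_record_tail_h * HOUR)
    elif shock:
        end = horizon  # deteriorated but never confirmed inside the horizon
    else:
        end = min(horizon, transition
                  + rng.uniform(*config.nonshock_los_after_transition_h) * HOUR)
    obs = obs[obs["time"] <= end].reset_index(drop=True)
    if fluid_events.size:
        fluid_events = fluid_events[fluid_events[:, 0] <= end]

    record = PatientRecord(
        patient_id=patient_id, weight_kg=weight, icu_admit=icu_admit,
        suspected_infection_time=infection_time, observations=obs,
        fluid_events=fluid_events, vasopressor_events=vaso_events,
        antibiotic_order_time=abx_time if abx_time <= end else None,
        died=died, end_time=float(end))
    truth = {"patient_id": patient_id, "archetype": g, "severity": severity,
             "transition_time": transition, "jump_width": width, "shock": shock,
             "died": died, "true_shock_onset": true_onset,
             "vaso_time": vaso_time if vaso_time is not None else np.nan,
             **{f"baseline_{k}": v for k, v in baselines.items()}}
    return record, truth


def generate_cohort(config: SynthConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a seeded cohort of patients with known archetypes."""
    config.validate()
    n = config.n_patients
    base_cols = ["patient_id", "archetype", "severity", "transition_time",
                 "jump_width", "shock", "died", "true_shock_onset", "vaso_time"]
    if n == 0:
        empty = pd.DataFrame(columns=base_cols)
        return [], GroundTruth(frame=empty, baselines=pd.DataFrame())
    ss = np.random.SeedSequence(config.seed)
    parent = np.random.default_rng(ss)
    weights = np.asarray(config.archetype_weights, dtype=float)
    weights = weights / weights.sum()
    archetypes = parent.choice(config.n_archetypes, size=n, p=weights)
    width = len(str(n - 1))
    records, truths = [], []
    for i, child in enumerate(ss.spawn(n)):
        rec, truth = simulate_patient(int(archetypes[i]), config,
                                      np.random.default_rng(child),
                                      patient_id=f"p{i:0{width}d}")
        records.append(rec)
        truths.append(truth)
    frame = pd.DataFrame(truths)
    baselines = frame[[c for c in frame.columns if c.startswith("baseline_")]]
    baselines = baselines.rename(columns=lambda c: c[len("baseline_"):])
    baselines.index = pd.Index(frame["patient_id"], name="patient_id")
    return records, GroundTruth(frame=frame[base_cols].copy(), baselines=baselines)


def severity_trajectory_matrix(truth: GroundTruth, config: SynthConfig,
                               window_h: int = 12, seed: int | None = None):
    """Latent severity trajectories aligned at the transition (hourly grid).

    Row ``i`` is the patient's latent severity ramp sampled at hours
    ``0..window_h`` after the latent transition, plus i.i.d. Gaussian noise of
    ``config.severity_noise_sd``. This is the noise-free risk proxy the risk
    model is meant to track; it gives a clustering substrate whose
    within-archetype spread is exactly the configured noise.
    """
    from .traj import TrajectoryMatrix  # local import avoids a cycle

    frame = truth.frame
    rng = np.random.default_rng(config.seed if seed is None else seed)
    hours = np.arange(window_h + 1, dtype=float)
    sev = frame["severity"].to_numpy(dtype=float)[:, None]
    scale = (frame["jump_width"].to_numpy(dtype=float) / 10.0)[:, None]
    values = sev * expit(hours[None, :] * HOUR / scale)
    values = values + rng.normal(0.0, config.severity_noise_sd, size=values.shape)
    return TrajectoryMatrix(
        patient_ids=list(frame["patient_id"]), anchor_kind="latent_transition",
        relative_times_h=hours, values=values, window=(0.0, float(window_h)),
        step_h=1.0, complete=np.ones(len(frame), dtype=bool))
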