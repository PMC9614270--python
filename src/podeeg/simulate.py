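"""Synthetic intraoperative cohorts.

No public EEG/POD dataset with this structure exists, so the pipeline is
exercised end-to-end on simulated cohorts that carry the statistical
structure the classifiers assume:

* ~20 % POD prevalence and agent-dependent EEG spectra,
* a 1/f ("pink") background plus a narrow-band alpha oscillation whose
  power is reduced in POD patients (``alpha_power_ratio_pod``),
* intermittent suppression episodes (amplitude attenuated x0.05) whose
  expected total fraction is raised in POD patients (``bsr_shift_pod``),
* isolated high-amplitude artifact spikes (10x the patient's 99 %
  amplitude quantile, 0.1-0.5 s),
* clinical covariates (age, ASA, operation length, benzodiazepine
  premedication) with class offsets matching the source cohort's gaps.

Every planted quantity (suppression mask and fraction, longest run,
artifact sample indices) is recorded as ground truth so downstream
detectors can be validated against it.  The same spec + seed reproduces a
cohort bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .preprocess import FRONTAL_CHANNELS, EEGRecording

MAINTENANCE_AGENTS = ("Propofol", "Desflurane", "Sevoflurane", "Other")
INDUCTION_AGENTS = ("Propofol", "Thiopental", "Etomidate")

#: Agent-dependent alpha oscillation: relative amplitude gain and spectral
#: peak location (Hz).  Propofol anesthesia shows the strongest frontal
#: alpha; volatile agents a weaker, slightly slower one.
AGENT_ALPHA = {
    "Propofol": (1.3, 10.0),
    "Desflurane": (0.9, 9.0),
    "Sevoflurane": (1.0, 9.5),
    "Other": (0.8, 9.0),
}

SUPPRESSION_ATTENUATION = 0.05


@dataclass
class ClinicalShifts:
    """Additive class offsets (POD minus no-POD) on the clinical covariates."""

    age_years: float = 2.7
    asa: float = 0.24
    op_length_h: float = 1.27
    benzodiazepine: float = 0.011

    def scaled(self, factor: float) -> "ClinicalShifts":
        return ClinicalShifts(
            self.age_years * factor,
            self.asa * factor,
            self.op_length_h * factor,
            self.benzodiazepine * factor,
        )


@dataclass
class ClinicalBaseline:
    """Population moments of the no-POD class."""

    age_mean: float = 69.2
    age_sd: float = 6.06
    asa_mean: float = 2.41
    asa_sd: float = 0.59
    op_length_mean_h: float = 2.61
    op_length_sd_h: float = 1.53
    benzodiazepine_rate: float = 0.058


@dataclass
class CohortSpec:
    """Generative conditions for one synthetic cohort."""

    n_patients: int = 240
    pod_prevalence: float = 0.19
    agent_mix: dict = field(
        default_factory=lambda: {
            "Propofol": 0.28,
            "Desflurane": 0.37,
            "Sevoflurane": 0.34,
            "Other": 0.01,
        }
    )
    sampling_rate: float = 128.0
    duration_range_min: tuple = (25.0, 45.0)
    alpha_power_ratio_pod: float = 0.6
    bsr_shift_pod: float = 0.10
    clinical_shifts: ClinicalShifts = field(default_factory=ClinicalShifts)
    clinical_baseline: ClinicalBaseline = field(default_factory=ClinicalBaseline)
    #: population-wide offsets applied to both classes (covariate shift
    #: between studies; zero by default)
    population_shift: ClinicalShifts = field(
        default_factory=lambda: ClinicalShifts(0.0, 0.0, 0.0, 0.0)
    )
    artifact_rate_per_min: float = 0.5
    base_suppression: float = 0.15
    suppression_sd: float = 0.07
    alpha_patient_sd: float = 0.2      # lognormal sigma of per-patient alpha amplitude
    pink_amp_uv: float = 8.0           # RMS of the 1/f background (microvolts)
    alpha_amp_uv: float = 10.0         # baseline RMS of the alpha oscillation
    drift_amp_uv: float = 10.0         # RMS of the common-mode baseline wander
    pop_rate_per_min: float = 0.3      # electrode-pop transients per minute
    pop_amp_factor: float = 5.0        # pop plateau amplitude in EEG SDs
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.agent_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"agent_mix proportions sum to {total}, not 1")
        if unknown := set(self.agent_mix) - set(MAINTENANCE_AGENTS):
            raise ConfigError(f"unknown maintenance agents: {sorted(unknown)}")
        if not 0.0 < self.pod_prevalence < 1.0:
            raise ConfigError("pod_prevalence must be in (0, 1)")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.duration_range_min[0] < 20.0:
            raise ConfigError(
                "duration_range_min must start at >= 20 min so no patient is "
                "excluded by the clean-duration rule unless deliberately planted"
            )
        if self.duration_range_min[1] < self.duration_range_min[0]:
            raise ConfigError("duration range must be (min, max) with min <= max")


@dataclass
class ClinicalRecord:
    patient_id: str
    age: float
    asa: int
    op_length_h: float
    benzodiazepine: int
    induction_agent: str
    maintenance_agent: str
    pod_label: int


@dataclass
class GroundTruth:
    suppression_fraction: float
    longest_run_s: float
    suppression_mask: np.ndarray       # bool per sample
    artifact_indices: np.ndarray       # planted 10x amplitude-spike sample indices
    pop_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


@dataclass
class SyntheticPatient:
    patient_id: str
    recording: EEGRecording
    clinical: ClinicalRecord
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------

def _pink_noise(n: int, fs: float, rng: np.random.Generator, n_channels: int = 4) -> np.ndarray:
    """1/f-power background via spectral shaping of white noise; each
    channel normalized to unit standard deviation."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 0.3))
    spectrum = amp * (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    )
    x = np.fft.irfft(spectrum, n=n, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _narrowband(
    n: int,
    fs: float,
    center_hz: float,
    sigma_hz: float,
    rng: np.random.Generator,
    n_channels: int = 1,
) -> np.ndarray:
    """Narrow-band stochastic oscillator(s): white noise shaped by a
    Gaussian spectral bump, unit RMS per channel."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.exp(-((freqs - center_hz) ** 2) / (2 * sigma_hz**2))
    spectrum = amp * (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    )
    x = np.fft.irfft(spectrum, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x if n_channels > 1 else x[0]


def _runs_from_mask(mask: np.ndarray):
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    return np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)


def renewal_suppression_mask(
    n: int,
    fs: float,
    fraction: float,
    rng: np.random.Generator,
    mean_episode_s: float = 8.0,
    min_episode_s: float = 1.0,
) -> np.ndarray:
    """Alternating-renewal suppression mask with the given expected
    fraction: exponential episode and inter-episode durations."""
    if fraction <= 0:
        return np.zeros(n, dtype=bool)
    mean_gap_s = mean_episode_s * (1.0 - fraction) / fraction
    mask = np.zeros(n, dtype=bool)
    # start mid-gap so recordings do not all open with a burst boundary
    t = int(rng.exponential(mean_gap_s / 2) * fs)
    while t < n:
        dur = int((min_episode_s + rng.exponential(mean_episode_s - min_episode_s)) * fs)
        mask[t : t + dur] = True
        t += dur + int((min_episode_s + rng.exponential(mean_gap_s)) * fs)
    return mask


def plant_suppression_mask(
    n: int,
    fs: float,
    fraction: float,
    longest_run_s: float,
    rng: np.random.Generator,
    mean_episode_s: float = 8.0,
    gap_s: float = 3.0,
) -> np.ndarray:
    """Constructive suppression mask with an *exact* total fraction and an
    exact longest run, for ground-truth validation of the detectors.

    The longest run is placed first; shorter exponential episodes are then
    added at random positions (separated by at least ``gap_s`` so runs
    never merge) until the target suppressed-sample count is met, trimming
    the last episode to land exactly on the target.
    """
    if fraction <= 0:
        return np.zeros(n, dtype=bool)
    target = int(round(fraction * n))
    longest = int(round(longest_run_s * fs))
    if longest > target:
        raise ConfigError("longest run exceeds the total suppression budget")
    gap = int(round(gap_s * fs))
    blocked = np.zeros(n, dtype=bool)   # suppression plus exclusion halo
    mask = np.zeros(n, dtype=bool)

    def place(dur: int) -> bool:
        for _ in range(200):
            start = int(rng.integers(gap, n - dur - gap))
            if not blocked[start - gap : start + dur + gap].any():
                mask[start : start + dur] = True
                blocked[max(0, start - gap) : start + dur + gap] = True
                return True
        return False

    if not place(longest):
        raise ConfigError("recording too short to place the longest suppression run")
    remaining = target - longest
    max_extra = max(int(fs), longest - gap)   # keep the planted longest run unique
    failures = 0
    while remaining > int(fs * 0.5) and failures < 200:
        dur = int((0.5 + rng.exponential(mean_episode_s)) * fs)
        dur = min(dur, max_extra, remaining)
        dur = max(dur, int(fs * 0.5))
        if not place(dur):
            failures += 1
        remaining = target - int(mask.sum())
    if remaining > int(fs):
        raise ConfigError("could not reach the requested suppression fraction")
    return mask


def _place_pops(
    signal: np.ndarray,
    fs: float,
    rate_per_min: float,
    amp_factor: float,
    suppression_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add flat-topped common-mode "electrode pop" transients (2-5 s).

    Their plateau amplitude (``amp_factor`` EEG standard deviations) puts
    them far above the background, so the patient's top-1 % amplitude
    tail consists of a few long clustered excursions — the structure real
    high-amplitude artifacts have and the quantile mask relies on.  Being
    common-mode, they are removed exactly by the common average
    reference.  Returns the affected sample indices.
    """
    n = signal.shape[1]
    minutes = n / fs / 60.0
    if rate_per_min <= 0:
        return np.empty(0, dtype=int)
    n_events = rng.poisson(rate_per_min * minutes)
    # floor: pops must cover comfortably more than the top-1% amplitude
    # tail, otherwise the quantile threshold dips into scattered
    # background peaks and segmentation shreds the recording
    target = int(0.02 * n)
    amp = amp_factor * signal.std()
    halo = int(1.5 * fs)   # keep clear of suppression so edge pads cannot
    from scipy.signal.windows import tukey   # truncate planted runs

    planted: list = []
    placed = 0
    attempts = 0
    while (len(planted) < n_events or placed < target) and attempts < 500:
        attempts += 1
        dur = int(rng.uniform(2.0, 5.0) * fs)
        for _ in range(50):
            start = int(rng.integers(halo, n - dur - halo))
            if not suppression_mask[start - halo : start + dur + halo].any():
                break
        else:
            continue
        bump = amp * tukey(dur, alpha=0.3) * rng.choice([-1.0, 1.0])
        signal[:, start : start + dur] += bump[None, :]
        planted.append(np.arange(start, start + dur))
        placed += dur
    if not planted:
        return np.empty(0, dtype=int)
    return np.unique(np.concatenate(planted))


def _place_artifacts(
    signal: np.ndarray,
    fs: float,
    rate_per_min: float,
    suppression_mask: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add isolated high-amplitude spikes; returns planted sample indices.

    Spikes last 0.1-0.5 s at 10x the patient's 99 % amplitude quantile and
    are kept clear of suppression episodes so the planted burst-suppression
    ground truth stays meaningful after artifact removal.
    """
    n = signal.shape[1]
    minutes = n / fs / 60.0
    n_events = rng.poisson(rate_per_min * minutes)
    if n_events == 0:
        return np.empty(0, dtype=int)
    amp = 10.0 * np.quantile(np.abs(signal), 0.99)
    halo = int(1.5 * fs)
    planted = []
    for _ in range(n_events):
        dur = int(rng.uniform(0.1, 0.5) * fs)
        for _ in range(50):
            start = int(rng.integers(halo, n - dur - halo))
            if not suppression_mask[start - halo : start + dur + halo].any():
                break
        else:
            continue
        bump = amp * np.sin(np.linspace(0, np.pi, dur)) * rng.choice([-1.0, 1.0])
        channels = rng.random(signal.shape[0]) < 0.6
        if not channels.any():
            channels[rng.integers(signal.shape[0])] = True
        signal[np.ix_(channels, np.arange(start, start + dur))] += bump
        planted.append(np.arange(start, start + dur))
    if not planted:
        return np.empty(0, dtype=int)
    return np.unique(np.concatenate(planted))


# ---------------------------------------------------------------------------
# patient-level simulation
# ---------------------------------------------------------------------------

def simulate_eeg(
    label: int,
    agent: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    duration_s: float | None = None,
    patient_id: str = "",
    force_suppression_fraction: float | None = None,
    force_longest_run_s: float | None = None,
) -> tuple[EEGRecording, GroundTruth]:
    """Simulate one intraoperative 4-channel recording with ground truth."""
    if agent not in MAINTENANCE_AGENTS:
        raise ConfigError(f"unsupported maintenance agent {agent!r}")
    fs = spec.sampling_rate
    if duration_s is None:
        duration_s = 60.0 * rng.uniform(*spec.duration_range_min)
    if duration_s <= 0:
        raise ConfigError("duration must be positive")
    n = int(round(duration_s * fs))

    gain, peak = AGENT_ALPHA[agent]
    peak = peak + rng.normal(0.0, 0.5)
    alpha_amp = (
        spec.alpha_amp_uv
        * gain
        * np.exp(rng.normal(0.0, spec.alpha_patient_sd))
        * np.sqrt(spec.alpha_power_ratio_pod if label else 1.0)
    )
    # channel-independent alpha oscillators (survive the common average
    # reference) with per-channel gains
    alpha = _narrowband(n, fs, peak, 0.75, rng, n_channels=4)
    channel_gain = rng.uniform(0.8, 1.2, size=4)
    signal = (
        spec.pink_amp_uv * _pink_noise(n, fs, rng)
        + alpha_amp * channel_gain[:, None] * alpha
    )
    # mild common-mode baseline wander (electrode drift); removed exactly
    # by the common average reference
    if spec.drift_amp_uv > 0:
        signal += spec.drift_amp_uv * _narrowband(n, fs, 0.05, 0.03, rng)[None, :]

    # suppression episodes
    if force_suppression_fraction is not None:
        if force_longest_run_s is not None:
            mask = plant_suppression_mask(
                n, fs, force_suppression_fraction, force_longest_run_s, rng
            )
        else:
            mask = renewal_suppression_mask(n, fs, force_suppression_fraction, rng)
    else:
        frac = rng.normal(spec.base_suppression, spec.suppression_sd)
        frac += spec.bsr_shift_pod if label else 0.0
        frac = float(np.clip(frac, 0.0, 0.6))
        mask = renewal_suppression_mask(n, fs, frac, rng)
    signal[:, mask] *= SUPPRESSION_ATTENUATION

    pop_idx = _place_pops(
        signal, fs, spec.pop_rate_per_min, spec.pop_amp_factor, mask, rng
    )
    artifact_idx = _place_artifacts(signal, fs, spec.artifact_rate_per_min, mask, rng)

    starts, stops = _runs_from_mask(mask)
    longest = int((stops - starts).max()) if starts.size else 0
    truth = GroundTruth(
        suppression_fraction=float(mask.mean()),
        longest_run_s=longest / fs,
        suppression_mask=mask,
        artifact_indices=artifact_idx,
        pop_indices=pop_idx,
    )
    rec = EEGRecording(signal, fs, FRONTAL_CHANNELS, patient_id)
    return rec, truth


def simulate_clinical(
    label: int, agent: str, spec: CohortSpec, rng: np.random.Generator, patient_id: str = ""
) -> ClinicalRecord:
    base, gap, pop = spec.clinical_baseline, spec.clinical_shifts, spec.population_shift
    shift = float(label)
    age = rng.normal(base.age_mean + shift * gap.age_years + pop.age_years, base.age_sd)
    asa_latent = rng.normal(base.asa_mean + shift * gap.asa + pop.asa, base.asa_sd)
    asa = int(np.clip(np.round(asa_latent), 1, 4))
    op = rng.normal(
        base.op_length_mean_h + shift * gap.op_length_h + pop.op_length_h,
        base.op_length_sd_h,
    )
    op = float(max(op, 0.5))
    benzo_p = np.clip(
        base.benzodiazepine_rate + shift * gap.benzodiazepine + pop.benzodiazepine,
        0.0,
        1.0,
    )
    benzo = int(rng.random() < benzo_p)
    induction = rng.choice(INDUCTION_AGENTS, p=[0.90, 0.07, 0.03])
    return ClinicalRecord(
        patient_id=patient_id,
        age=float(max(age, 60.0)),
        asa=asa,
        op_length_h=op,
        benzodiazepine=benzo,
        induction_agent=str(induction),
        maintenance_agent=agent,
        pod_label=int(label),
    )


# ---------------------------------------------------------------------------
# cohort-level simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortPlan:
    """Patient-level draws that do not require signal generation."""

    patient_ids: list
    labels: np.ndarray
    agents: list
    durations_s: np.ndarray
    child_seeds: list


def draw_cohort_plan(spec: CohortSpec) -> CohortPlan:
    """Labels, agents, durations and per-patient RNG seeds for a cohort.

    Separated from signal synthesis so prevalence/covariate checks and
    streaming generation share one deterministic source of randomness.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    if n < 1:
        raise ConfigError("n_patients must be >= 1")
    labels = (rng.random(n) < spec.pod_prevalence).astype(int)
    agents = list(
        rng.choice(list(spec.agent_mix), size=n, p=list(spec.agent_mix.values()))
    )
    durations = 60.0 * rng.uniform(*spec.duration_range_min, size=n)
    child_seeds = list(np.random.SeedSequence(spec.seed).spawn(n))
    ids = [f"P{i:04d}" for i in range(n)]
    return CohortPlan(ids, labels, agents, durations, child_seeds)


def iter_cohort(spec: CohortSpec):
    """Yield :class:`SyntheticPatient` one at a time (memory-friendly)."""
    plan = draw_cohort_plan(spec)
    for pid, label, agent, dur, seed in zip(
        plan.patient_ids, plan.labels, plan.agents, plan.durations_s, plan.child_seeds
    ):
        rng = np.random.default_rng(seed)
        rec, truth = simulate_eeg(
            label, agent, spec, rng, duration_s=dur, patient_id=pid
        )
        clinical = simulate_clinical(label, agent, spec, rng, patient_id=pid)
        yield SyntheticPatient(pid, rec, clinical, truth)


def simulate_cohort(spec: CohortSpec) -> list:
    """Materialize the whole cohort; identical spec + seed reproduces it
    bit-exactly."""
    return list(iter_cohort(spec))


def clinical_table(patients_or_records):
    """Cohort-level clinical table as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for p in patients_or_records:
        rec = p.clinical if isinstance(p, SyntheticPatient) else p
        rows.append(
            {
                "patient_id": rec.patient_id,
                "age": rec.age,
                "asa": rec.asa,
                "op_length_h": rec.op_length_h,
                "benzodiazepine": rec.benzodiazepine,
                "induction_agent": rec.induction_agent,
                "maintenance_agent": rec.maintenance_agent,
                "pod_label": rec.pod_label,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
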