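"""Class-conditional synthetic EEG with a planted microstate structure.

The generator emulates the statistical skeleton of eyes-closed resting
EEG as seen through a microstate lens: a piecewise-constant latent
sequence over four dipolar template topographies (segment durations
drawn uniformly from the canonical 60–120 ms range), band-specific
amplitude-modulated carriers at each band's geometric-mean frequency,
spatially white sensor noise, and class-conditional effects —

* **HC**: sustained posterior-dominant alpha, weak low frequencies;
* **AD**: multiplicative alpha attenuation ("alpha dropout"), a mild
  diffuse theta elevation, and Poisson-scheduled transient broadband
  delta bursts riding the momentary template;
* **FTD**: delta bursts locked to Class-C periods with a frontally
  weighted Class-C topography (the "frontal shift").

Every subject is a pure function of its seed, so planted ground truth
(state sequence, per-band templates, class label) is available to every
downstream test.  This is test scaffolding, not a biophysical forward
model: there are no head geometry, volume conduction or artifact
processes, and effect sizes are free parameters of the cohort spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io_core import Recording, write_edf
from .montage import Montage, standard_1020_19

__all__ = [
    "MicrostatePrototype",
    "GroundTruth",
    "CohortSpec",
    "make_prototypes",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "null_spec",
]

CLASS_LABELS = ("A", "B", "C", "D")

#: geometric-mean carrier frequency per band (Hz)
BAND_CARRIERS = {
    "delta": (0.5 * 4.0) ** 0.5,
    "theta": (4.0 * 8.0) ** 0.5,
    "alpha": (8.0 * 13.0) ** 0.5,
    "beta": (13.0 * 30.0) ** 0.5,
    "gamma": (30.0 * 45.0) ** 0.5,
}

#: baseline carrier amplitudes (arbitrary units; alpha-dominant awake
#: eyes-closed resting EEG with weak, noise-dominated slow activity, so
#: pathological delta bursts stand out as topography — not just power)
BASE_AMPLITUDE = {"delta": 0.10, "theta": 0.25, "alpha": 1.00, "beta": 0.20, "gamma": 0.08}

#: overall output scale to land in a physiological microvolt range
OUTPUT_SCALE_UV = 20.0


@dataclass(frozen=True)
class MicrostatePrototype:
    """One canonical microstate topography: unit norm, zero channel mean."""

    label: str
    map: np.ndarray


@dataclass
class GroundTruth:
    """Planted structure of one simulated subject."""

    state_sequence: np.ndarray  # per-sample int in 0..3 (A..D)
    segment_durations_ms: np.ndarray
    band_templates: dict[str, np.ndarray]  # band -> (4, n_channels)
    class_label: str


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated cohort.

    Effect sizes: ``alpha_attenuation`` multiplies the AD alpha carrier
    (1 = no effect); ``delta_burst_rate_per_min`` schedules transient
    bursts for both patient groups; ``burst_gain`` is the burst carrier
    amplitude (same units as the baseline amplitudes, cf. alpha = 1);
    ``ftd_frontal_gain`` weights the Class-C burst topography toward
    frontal channels; ``ad_theta_gain`` models diffuse theta elevation.
    """

    n_per_class: dict[str, int] = field(default_factory=lambda: {"AD": 4, "FTD": 4, "HC": 4})
    duration_s: float = 300.0
    rate: float = 256.0
    seed: int = 0
    noise_sd: float = 0.40
    alpha_attenuation: float = 0.25
    delta_burst_rate_per_min: float = 10.0
    burst_gain: float = 4.0
    ftd_frontal_gain: float = 3.0
    ad_theta_gain: float = 1.8
    #: FTD alpha is relatively preserved compared to AD but still reduced
    #: against HC (mild generalized slowing accompanies the focal signs)
    ftd_alpha_attenuation: float = 0.55

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_per_class.values()):
            raise ValueError("subject counts must be >= 0")
        if self.rate <= 0 or self.duration_s <= 0:
            raise ValueError("rate and duration must be positive")
        if min(self.alpha_attenuation, self.delta_burst_rate_per_min, self.burst_gain,
               self.ftd_frontal_gain, self.noise_sd) < 0:
            raise ValueError("effect sizes must be >= 0")


def null_spec(n_per_class: dict[str, int] | None = None, duration_s: float = 35.0, seed: int = 0) -> CohortSpec:
    """A cohort spec with every class effect switched off.

    All groups share one generative process, so any above-chance LOSO
    accuracy on such a cohort indicates leakage somewhere in the pipeline.
    """
    return CohortSpec(
        n_per_class=n_per_class or {"AD": 5, "FTD": 0, "HC": 5},
        duration_s=duration_s,
        seed=seed,
        alpha_attenuation=1.0,
        delta_burst_rate_per_min=0.0,
        burst_gain=0.0,
        ftd_frontal_gain=0.0,
        ad_theta_gain=1.0,
        ftd_alpha_attenuation=1.0,
    )


def _zero_mean_unit(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    return v / np.linalg.norm(v)


def make_prototypes(montage: Montage | None = None) -> list[MicrostatePrototype]:
    """Dipolar prototype maps for the four canonical classes.

    A: right-anterior to left-posterior diagonal; B: the mirrored
    diagonal; C: anterior–posterior gradient concentrated on the midline;
    D: focal symmetric posterior/parietal distribution.  All maps are
    zero-mean and unit-norm with pairwise |correlation| < 0.9.
    """
    montage = montage or standard_1020_19()
    x, y = montage.positions[:, 0], montage.positions[:, 1]
    a = _zero_mean_unit(x + y)
    b = _zero_mean_unit(y - x)
    c = _zero_mean_unit(y * np.exp(-(x**2) / (2 * 0.45**2)))
    d = _zero_mean_unit(np.exp(-((x**2) + (y + 0.65) ** 2) / (2 * 0.35**2)))
    protos = [MicrostatePrototype(lbl, m) for lbl, m in zip(CLASS_LABELS, (a, b, c, d))]
    for i in range(4):
        for j in range(i + 1, 4):
            rho = abs(float(protos[i].map @ protos[j].map))
            if rho >= 0.9:
                raise ValueError(
                    f"prototypes {protos[i].label}/{protos[j].label} too similar (|rho|={rho:.2f})"
                )
    return protos


def _latent_sequence(n: int, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant labels with segment durations uniform on [60, 120] ms."""
    labels = np.empty(n, dtype=np.int64)
    durations = []
    pos = 0
    current = int(rng.integers(4))
    while pos < n:
        dur_ms = rng.uniform(60.0, 120.0)
        length = max(1, int(round(dur_ms / 1000.0 * rate)))
        length = min(length, n - pos)
        labels[pos : pos + length] = current
        durations.append(length / rate * 1000.0)
        pos += length
        nxt = int(rng.integers(3))  # uniform over the other three states
        current = nxt if nxt < current else nxt + 1
    return labels, np.asarray(durations)


def _envelope(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Slow positive amplitude modulation around 1 (waxing/waning rhythm)."""
    raw = rng.standard_normal(n)
    smooth = uniform_filter1d(raw, size=max(3, int(rate // 2)))
    smooth = smooth / (np.std(smooth) + 1e-12)
    return np.clip(1.0 + 0.4 * smooth, 0.15, None)


def _burst_windows(n: int, rate: float, rate_per_min: float, rng: np.random.Generator) -> np.ndarray:
    """Additive envelope of Poisson-scheduled smooth (Hann) bursts."""
    env = np.zeros(n)
    lam = rate_per_min * (n / rate) / 60.0
    for _ in range(rng.poisson(lam)):
        dur = int(rng.uniform(0.2, 0.4) * rate)
        start = int(rng.integers(0, max(1, n - dur)))
        env[start : start + dur] += np.hanning(dur)
    return env


def simulate_subject(
    class_label: str,
    duration_s: float | None = None,
    rate: float | None = None,
    seed: int | np.random.SeedSequence = 0,
    spec: CohortSpec | None = None,
    subject_id: str = "sim-000",
    montage: Montage | None = None,
) -> tuple[Recording, GroundTruth]:
    """Simulate one subject's 19-channel recording with known ground truth."""
    if class_label not in ("AD", "FTD", "HC"):
        raise ValueError(f"unknown class label {class_label!r}")
    spec = spec or CohortSpec()
    duration_s = spec.duration_s if duration_s is None else duration_s
    rate = spec.rate if rate is None else rate
    montage = montage or standard_1020_19()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate

    protos = make_prototypes(montage)
    maps = np.stack([p.map for p in protos])  # (4, C)
    labels, _ = _latent_sequence(n, rate, rng)

    ftd_burst_env = None
    if class_label == "FTD":
        # frontal delta bursts lock the latent state onto Class C for their
        # duration (0.5–1 s), mimicking intermittent rhythmic frontal delta
        ftd_burst_env = np.zeros(n)
        lam = spec.delta_burst_rate_per_min * duration_s / 60.0
        for _ in range(rng.poisson(lam)):
            dur = int(rng.uniform(0.5, 1.0) * rate)
            start = int(rng.integers(0, max(1, n - dur)))
            ftd_burst_env[start : start + dur] = np.maximum(
                ftd_burst_env[start : start + dur], np.hanning(dur)
            )
            labels[start : start + dur] = 2

    seg_ms = np.array([length / rate * 1000.0 for _, length in _rle(labels)])
    tmpl_t = maps[labels]  # (n, C) topography of the active state

    amp = dict(BASE_AMPLITUDE)
    if class_label == "AD":
        amp["alpha"] *= spec.alpha_attenuation
        amp["theta"] *= spec.ad_theta_gain
    elif class_label == "FTD":
        amp["alpha"] *= spec.ftd_alpha_attenuation

    drive = np.zeros(n)
    for band, freq in BAND_CARRIERS.items():
        carrier = np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        drive += amp[band] * _envelope(n, rate, rng) * carrier

    signal = tmpl_t * drive[:, None]  # (n, C)

    # transient delta bursts
    if class_label in ("AD", "FTD"):
        delta_carrier = np.sin(2 * np.pi * BAND_CARRIERS["delta"] * t + rng.uniform(0, 2 * np.pi))
        if class_label == "AD":
            # broadband delta bursts riding whatever template is active
            burst_env = _burst_windows(n, rate, spec.delta_burst_rate_per_min, rng)
            signal += (spec.burst_gain * burst_env * delta_carrier)[:, None] * tmpl_t
        else:
            # frontally weighted Class-C topography during the burst windows
            x, y = montage.positions[:, 0], montage.positions[:, 1]
            frontal = np.exp(-((y - 0.8) ** 2 + x**2) / (2 * 0.5**2))
            frontal_c = _zero_mean_unit(maps[2] * (1.0 + spec.ftd_frontal_gain * frontal))
            env = spec.burst_gain * ftd_burst_env * delta_carrier
            signal += env[:, None] * frontal_c[None, :]

    signal += rng.normal(0.0, spec.noise_sd, size=signal.shape)
    rec = Recording(
        subject_id=subject_id,
        group=class_label,
        channels=montage.names,
        rate=float(rate),
        data=(signal * OUTPUT_SCALE_UV).T,
        reference="synthetic",
    )
    truth = GroundTruth(
        state_sequence=labels,
        segment_durations_ms=seg_ms,
        band_templates={band: maps.copy() for band in BAND_CARRIERS},
        class_label=class_label,
    )
    return rec, truth


def simulate_cohort(spec: CohortSpec, montage: Montage | None = None) -> list[tuple[Recording, GroundTruth]]:
    """Simulate a labeled cohort; per-subject seeds derive from spec.seed."""
    out: list[tuple[Recording, GroundTruth]] = []
    idx = 0
    for cls in ("AD", "FTD", "HC"):
        for _ in range(spec.n_per_class.get(cls, 0)):
            ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(idx,))
            out.append(
                simulate_subject(
                    cls,
                    seed=ss,
                    spec=spec,
                    subject_id=f"sim-{idx:03d}",
                    montage=montage,
                )
            )
            idx += 1
    return out


def _rle(labels: np.ndarray) -> list[list[int]]:
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [[int(labels[s]), int(e - s)] for s, e in zip(starts, ends)]


def write_cohort(cohort: list[tuple[Recording, GroundTruth]], out_dir: str | Path) -> None:
    """Export a cohort as EDF files plus ground-truth JSON sidecars.

    The sidecar stores the class label and the run-length-encoded state
    sequence as ``[[state, n_samples], ...]`` with states 0–3 = A–D.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec, truth in cohort:
        write_edf(rec, out_dir / f"{rec.subject_id}.edf")
        sidecar = {
            "subject_id": rec.subject_id,
            "class_label": truth.class_label,
            "rate": rec.rate,
            "state_sequence_rle": _rle(truth.state_sequence),
        }
        (out_dir / f"{rec.subject_id}_truth.json").write_text(json.dumps(sidecar))
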