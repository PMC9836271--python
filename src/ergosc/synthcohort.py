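"""Synthetic spontaneous-ERG cohorts with matching clinical metadata.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage of the pipeline can be exercised against known ground
truth:

* **Signals** are sums of band-limited oscillatory components (white noise
  band-pass filtered around a center frequency, or a pure sinusoid when the
  bandwidth is zero), sitting on 1/f^alpha background noise, with optional
  Poisson-placed biphasic blink artifacts whose peak amplitude exceeds the
  +/-100 uV rejection rule.  Disease effects are expressed as signed
  per-band peak-frequency shifts and component-amplitude changes.
* **Metadata** are drawn from truncated normals with the published group
  means and dispersions of the clinical characteristics table, then
  rejection-sampled until the labeling rules re-derive the declared group.

Human control signals carry components near 0.5, 15, and 27 Hz (one inside
each of the 0.3-2, 10-20, and 20-40 Hz bands); disease profiles shift the
20-40 Hz component upward and change slow-band power.  Rodent profiles place
activity in the 0.1-10 Hz range with disease reducing the mid-low peak.

Absolute oscillation amplitudes are free parameters (published signals are
shown normalized): defaults are 4/3/3 uV component RMS over 1 uV noise.

Everything is deterministic under (configuration, seed); per-subject and
per-recording streams are derived with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy import stats as _stats

from . import clinlabel
from .preprocess import Recording

__all__ = [
    "OscComponent",
    "GroupProfile",
    "SyntheticSubject",
    "simulate_recording",
    "simulate_metadata",
    "make_cohort",
    "human_control_profile",
    "human_disease_profile",
    "human_group_profile",
    "rodent_control_profile",
    "rodent_week_profile",
    "TABLE1_STATS",
]


@dataclass(frozen=True)
class OscComponent:
    """One band-limited oscillatory process.

    ``center_freq`` in Hz; ``bandwidth`` is the half-power width of the
    band-limited process (0 -> pure sinusoid); ``amplitude_sd`` is its RMS
    contribution in uV; ``label`` ties the component to a band for
    peak-shift application.
    """

    center_freq: float
    bandwidth: float = 0.0
    amplitude_sd: float = 1.0
    phase_mode: str = "random"
    label: str = ""

    def __post_init__(self) -> None:
        if self.center_freq <= 0:
            raise ValueError("center_freq must be positive")
        if self.bandwidth < 0 or self.amplitude_sd < 0:
            raise ValueError("bandwidth and amplitude_sd must be >= 0")
        if self.phase_mode not in ("random", "fixed"):
            raise ValueError("phase_mode must be 'random' or 'fixed'")


@dataclass(frozen=True)
class GroupProfile:
    """Signal-generation profile for one study group."""

    group: str
    components: tuple[OscComponent, ...]
    noise_exponent: float = 1.0  # 1/f^alpha background
    noise_sd: float = 1.0  # uV RMS
    artifact_rate: float = 0.0  # blink events per minute
    artifact_amplitude: float = 150.0  # uV peak
    peak_shift: Mapping[str, float] = field(default_factory=dict)  # band label -> Hz

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.artifact_rate > 0 and self.artifact_amplitude <= 100.0:
            raise ValueError(
                "artifact_amplitude must exceed 100 uV so artifacts trip the rejection rule"
            )

    def shifted_center(self, comp: OscComponent) -> float:
        return comp.center_freq + float(self.peak_shift.get(comp.label, 0.0))


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    metadata: pd.Series
    recordings: list[Recording]


# ---------------------------------------------------------------------------
# signal synthesis

def simulate_recording(
    profile: GroupProfile,
    duration_s: float,
    fs: float,
    seed,
    subject_id: str = "sim",
    eye: str = "right",
    state: str = "photopic",
    species: str = "human",
    device: str = "synth",
) -> Recording:
    """Synthesize one spontaneous ERG recording from a group profile.

    Deterministic under (profile, seed).  Requires ``fs`` at least twice the
    highest (shifted) component center frequency.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    centers = [profile.shifted_center(c) for c in profile.components]
    if centers and fs < 2 * max(centers):
        raise ValueError(
            f"fs={fs} Hz violates Nyquist for component at {max(centers)} Hz"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    nyq = fs / 2.0
    for comp, f0 in zip(profile.components, centers):
        if comp.amplitude_sd == 0:
            # keep the stream position stable regardless of amplitude
            if comp.phase_mode == "random":
                rng.uniform(0.0, 2 * np.pi)
            if comp.bandwidth > 0:
                rng.standard_normal(n)
            continue
        if comp.bandwidth == 0:
            phase = rng.uniform(0.0, 2 * np.pi) if comp.phase_mode == "random" else 0.0
            x += np.sqrt(2.0) * comp.amplitude_sd * np.sin(2 * np.pi * f0 * t + phase)
        else:
            lo = max(f0 - comp.bandwidth / 2.0, 1e-3)
            hi = min(f0 + comp.bandwidth / 2.0, 0.99 * nyq)
            sos = _sig.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
            y = _sig.sosfiltfilt(sos, rng.standard_normal(n))
            sd = y.std()
            if sd > 0:
                x += y * (comp.amplitude_sd / sd)
    if profile.noise_sd > 0:
        x += _colored_noise(rng, n, fs, profile.noise_exponent, profile.noise_sd)
    if profile.artifact_rate > 0:
        x += _blink_train(rng, n, fs, duration_s, profile.artifact_rate, profile.artifact_amplitude)
    return Recording(
        fs=fs, samples=x, subject_id=subject_id, eye=eye, state=state,
        species=species, device=device,
    )


def _colored_noise(rng, n: int, fs: float, exponent: float, sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    if exponent == 0:
        y = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        gain = np.zeros_like(f)
        gain[1:] = f[1:] ** (-exponent / 2.0)
        y = np.fft.irfft(spec * gain, n)
    y = y - y.mean()
    s = y.std()
    return y * (sd / s) if s > 0 else y


def _blink_train(rng, n, fs, duration_s, rate_per_min, amplitude) -> np.ndarray:
    # biphasic 200 ms transient: one full sine cycle, peak = amplitude
    out = np.zeros(n)
    n_events = rng.poisson(rate_per_min * duration_s / 60.0)
    wlen = int(round(0.2 * fs))
    wave = amplitude * np.sin(2 * np.pi * np.arange(wlen) / wlen)
    for start in rng.integers(0, max(n - wlen, 1), size=n_events):
        out[start : start + wlen] += wave[: n - start]
    return out


# ---------------------------------------------------------------------------
# stock profiles

def human_control_profile(
    noise_sd: float = 1.0, artifact_rate: float = 0.0
) -> GroupProfile:
    """Metabolically healthy human profile: peaks inside bands I/II/III."""
    comps = (
        OscComponent(0.5, 0.4, 4.0, label="I"),
        OscComponent(15.0, 4.0, 3.0, label="II"),
        OscComponent(27.0, 4.0, 3.0, label="III"),
    )
    return GroupProfile(
        "control", comps, noise_exponent=1.0, noise_sd=noise_sd,
        artifact_rate=artifact_rate,
    )


def human_disease_profile(
    shift_iii_hz: float = 2.0,
    slow_delta_uv: float = 3.0,
    noise_sd: float = 1.0,
    artifact_rate: float = 0.0,
    group: str = "disease",
) -> GroupProfile:
    """Pooled-disease human profile: raised 20-40 Hz peak, altered slow power."""
    comps = (
        OscComponent(0.5, 0.4, 4.0 + slow_delta_uv, label="I"),
        OscComponent(15.0, 4.0, 3.0, label="II"),
        OscComponent(27.0, 4.0, 3.0, label="III"),
    )
    return GroupProfile(
        group, comps, noise_exponent=1.0, noise_sd=noise_sd,
        artifact_rate=artifact_rate, peak_shift={"III": shift_iii_hz},
    )


_GRADED_SHIFT = {"control": 0.0, "overweight": 0.5, "obesity": 1.0, "mets": 1.5, "dm_no_dr": 2.0}


def human_group_profile(group: str, noise_sd: float = 1.0) -> GroupProfile:
    """Per-group human profile with effects graded by disease stage."""
    if group not in _GRADED_SHIFT:
        raise ValueError(f"unknown group {group!r}")
    shift = _GRADED_SHIFT[group]
    if shift == 0:
        return human_control_profile(noise_sd=noise_sd)
    return human_disease_profile(
        shift_iii_hz=shift, slow_delta_uv=1.5 * shift, noise_sd=noise_sd, group=group
    )


def rodent_control_profile(noise_sd: float = 1.0) -> GroupProfile:
    """Rodent profile with low / mid-low / mid activity in the 0.1-10 Hz range."""
    comps = (
        OscComponent(0.4, 0.3, 4.0, label="L"),
        OscComponent(1.4, 0.5, 3.0, label="M1"),
        OscComponent(3.0, 1.0, 2.0, label="M2"),
    )
    return GroupProfile("control", comps, noise_exponent=1.0, noise_sd=noise_sd)


def rodent_week_profile(week: int, noise_sd: float = 1.0) -> GroupProfile:
    """Diseased-rodent profile at a given week: mid-low peak drifts down."""
    base = rodent_control_profile(noise_sd=noise_sd)
    return GroupProfile(
        f"week_{week}", base.components, noise_exponent=base.noise_exponent,
        noise_sd=noise_sd, peak_shift={"M1": -0.025 * week},
    )


# ---------------------------------------------------------------------------
# clinical metadata

# Published group means and dispersions (mean, dispersion-as-printed).
TABLE1_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {
        "age": (41.49, 1.88), "weight": (58.38, 1.23), "waist": (83.13, 1.30),
        "hip": (82.28, 1.25), "bmi": (22.39, 0.31), "glucose": (86.77, 0.79),
        "hba1c": (5.30, 0.03), "insulin": (7.36, 0.44), "tg": (100.37, 4.79),
        "ct": (179.55, 3.61), "hdl": (56.92, 2.02), "ldl": (105.0, 2.72),
        "vldl": (17.23, 1.08), "creatinine": (0.79, 0.02),
        "sbp": (114.73, 2.23), "dbp": (71.64, 1.16),
    },
    "overweight": {
        "age": (42.70, 2.08), "weight": (72.47, 1.40), "waist": (96.05, 1.38),
        "hip": (93.80, 1.38), "bmi": (26.85, 0.25), "glucose": (87.75, 1.21),
        "hba1c": (5.47, 0.05), "insulin": (9.54, 0.91), "tg": (104.70, 6.99),
        "ct": (185.12, 4.37), "hdl": (54.64, 1.75), "ldl": (117.27, 3.73),
        "vldl": (17.62, 1.98), "creatinine": (0.77, 0.02),
        "sbp": (114.79, 2.82), "dbp": (74.05, 1.65),
    },
    "obesity": {
        "age": (39.57, 2.93), "weight": (79.12, 3.97), "waist": (104.14, 4.26),
        "hip": (99.46, 3.94), "bmi": (29.93, 1.82), "glucose": (91.43, 3.09),
        "hba1c": (5.39, 0.10), "insulin": (11.15, 1.74), "tg": (104.94, 12.56),
        "ct": (192.19, 8.05), "hdl": (56.90, 3.36), "ldl": (118.25, 7.97),
        "vldl": (17.05, 1.94), "creatinine": (0.75, 0.04),
        "sbp": (124.14, 7.75), "dbp": (73.14, 3.21),
    },
    "mets": {
        "age": (60.45, 1.79), "weight": (69.65, 4.41), "waist": (88.0, 3.77),
        "hip": (96.36, 3.96), "bmi": (27.12, 1.08), "glucose": (144.82, 20.06),
        "hba1c": (8.41, 0.69), "insulin": (9.84, 1.70), "tg": (132.55, 21.37),
        "ct": (190.17, 12.66), "hdl": (48.84, 5.21), "ldl": (113.06, 11.02),
        "vldl": (26.51, 4.27), "creatinine": (1.09, 0.18),
        "sbp": (125.64, 4.72), "dbp": (85.82, 4.31),
    },
    "dm_no_dr": {
        "age": (65.86, 1.49), "weight": (76.48, 1.86), "waist": (102.91, 1.53),
        "hip": (103.17, 1.18), "bmi": (30.14, 0.63), "glucose": (147.48, 6.39),
        "hba1c": (7.67, 0.24), "insulin": (21.50, 2.89), "tg": (180.61, 11.05),
        "ct": (183.36, 4.39), "hdl": (46.13, 1.45), "ldl": (108.55, 3.84),
        "vldl": (30.34, 2.37), "creatinine": (0.79, 0.05),
        "sbp": (131.33, 2.62), "dbp": (82.61, 1.50),
    },
}

_DM_CUT = clinlabel.MGDL_PER_MMOL * 7.0  # 126 mg/dl

# Per-group truncation bounds keeping draws inside the declared label's
# feasible region; remaining inconsistencies are handled by rejection.
_GROUP_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {"bmi": (18.5, 24.99), "glucose": (0.0, _DM_CUT)},
    "overweight": {"bmi": (25.0, 29.99), "glucose": (0.0, _DM_CUT)},
    "obesity": {"bmi": (30.0, np.inf), "glucose": (0.0, _DM_CUT)},
    "mets": {"glucose": (0.0, _DM_CUT)},
    "dm_no_dr": {"glucose": (_DM_CUT, np.inf)},
}

_POSITIVE = ("weight", "waist", "hip", "bmi", "glucose", "hba1c", "insulin",
             "tg", "ct", "hdl", "ldl", "vldl", "creatinine", "sbp", "dbp")


def _draw_row(rng, group: str, stats, bounds, thresholds, dispersion_scale) -> dict:
    row: dict = {"sex": "male" if rng.random() < 0.5 else "female"}
    if group == "mets":
        bounds = dict(bounds)
        waist_cut = (thresholds.waist_male_cm if row["sex"] == "male"
                     else thresholds.waist_female_cm)
        bounds["waist"] = (waist_cut, np.inf)
    for name, (mu, disp) in stats.items():
        sd = disp * dispersion_scale
        lo, hi = bounds.get(name, (0.0 if name in _POSITIVE else -np.inf, np.inf))
        if name == "age":
            lo, hi = 30.0, 80.0  # study inclusion range
        a, b = (lo - mu) / sd, (hi - mu) / sd
        row[name] = float(_stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
    row["height"] = float(np.sqrt(row["weight"] / row["bmi"]))
    row["diabetes_dx"] = group == "dm_no_dr"
    return clinlabel.derive_indices(row)


def simulate_metadata(
    group: str,
    n: int,
    seed,
    dispersion_scale: float = 1.0,
    thresholds: clinlabel.MetSThresholds = clinlabel.DEFAULT_THRESHOLDS,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Sample ``n`` metadata rows whose derived label equals ``group``.

    Rows are drawn from truncated normals with the published group means and
    dispersions, then rejection-sampled until :func:`clinlabel.assign_group`
    re-derives the declared group.  Deterministic under ``seed``.
    """
    if group not in TABLE1_STATS:
        raise ValueError(f"unknown group {group!r}; expected one of {list(TABLE1_STATS)}")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    stats = TABLE1_STATS[group]
    bounds = _GROUP_BOUNDS[group]
    rows = []
    for i in range(n):
        for attempt in range(max_tries):
            row = _draw_row(rng, group, stats, bounds, thresholds, dispersion_scale)
            if clinlabel.assign_group(row, thresholds) == group:
                break
        else:
            raise RuntimeError(
                f"could not sample a consistent {group} row in {max_tries} tries"
            )
        row["group"] = group
        rows.append(row)
    cols = ["group", "sex", "age", "height", "weight", "bmi", "waist", "hip",
            "sbp", "dbp", "glucose", "hba1c", "insulin", "tg", "ct", "hdl",
            "ldl", "vldl", "creatinine", "homa_i", "atherogenic_index",
            "diabetes_dx"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# cohorts

def make_cohort(
    design: Mapping[str, int],
    duration_s: float = 300.0,
    fs: float = 1000.0,
    seed=0,
    profiles: Mapping[str, GroupProfile] | None = None,
    states: Sequence[str] = ("photopic",),
    eyes: Sequence[str] = ("right",),
    species: str = "human",
    with_metadata: bool = True,
) -> list[SyntheticSubject]:
    """Generate a cohort of subjects with consistent metadata and recordings.

    ``design`` maps group label to subject count.  One recording is produced
    per (adaptation state, eye).  Identical (arguments, seed) yields an
    identical cohort.
    """
    for g, cnt in design.items():
        if cnt < 0:
            raise ValueError("counts must be >= 0")
        if g not in TABLE1_STATS:
            raise ValueError(f"unknown group {g!r}")
    if profiles is None:
        profiles = {g: human_group_profile(g) for g in design}
    ss = np.random.SeedSequence(_as_int_seed(seed))
    subjects: list[SyntheticSubject] = []
    # spawn once, in a fixed order over the design
    children = ss.spawn(len(design))
    for (g, cnt), child in zip(design.items(), children):
        meta_ss, *subj_ss = child.spawn(cnt + 1)
        meta = (simulate_metadata(g, cnt, meta_ss) if with_metadata
                else pd.DataFrame(index=range(cnt)))
        for i in range(cnt):
            sid = f"{g}_{i:03d}"
            recs = []
            rec_children = subj_ss[i].spawn(len(states) * len(eyes))
            j = 0
            for state in states:
                for eye in eyes:
                    recs.append(
                        simulate_recording(
                            profiles[g], duration_s, fs, rec_children[j],
                            subject_id=sid, eye=eye, state=state, species=species,
                        )
                    )
                    j += 1
            subjects.append(
                SyntheticSubject(
                    subject_id=sid, group=g,
                    metadata=meta.iloc[i] if with_metadata else pd.Series(dtype=float),
                    recordings=recs,
                )
            )
    return subjects


def _as_int_seed(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1)[0])
    return int(seed)
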