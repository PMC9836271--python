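"""File I/O, pipeline configuration, and the end-to-end driver.

Canonical formats: recordings as two-column CSV (``time_s``, ``voltage_uV``)
with a JSON sidecar holding provenance and the sampling rate; metadata tables
as CSV; reports as JSON embedding the configuration echo, package version,
and seed; configuration as YAML.  EDF recordings can be read when ``mne`` is
importable.

``run_pipeline`` chains simulate/ingest -> preprocess -> spectra -> features
-> classify and a small explanatory block, fully deterministic under
(config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, explain, spectral, synthcohort
from .preprocess import (
    Recording,
    bandlimit_filter,
    normalize_signal,
    reject_artifacts,
    sample_fragments,
)

__all__ = [
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "read_recording_edf",
    "read_metadata",
    "write_metadata",
    "write_report",
    "run_pipeline",
]

log = logging.getLogger("ergosc")


@dataclass
class PipelineConfig:
    """Validated end-to-end pipeline settings (units in field names/comments)."""

    species: str = "human"
    band: tuple[float, float] = spectral.HUMAN_RANGE  # analysis band, Hz
    df: float = 0.05  # spectral resolution, Hz
    dt: float = 0.01  # time resolution, s
    cycles: float = 7.0
    highpass_hz: float = 0.3
    notch_hz: float | None = 50.0
    artifact_threshold_uv: float = 100.0
    artifact_granularity: str = "recording"
    fragment_s: float = 60.0
    norm_mode: str = "unit_integral"
    bands: tuple = spectral.HUMAN_BANDS
    rf_grid: classify.RFGrid = field(default_factory=classify.RFGrid.small)
    cv_folds: int = 5
    train_frac: float = 0.8
    split_unit: str = "fragment"
    seed: int = 0
    # simulation-only settings
    design: dict = field(default_factory=lambda: {"control": 10, "mets": 10})
    duration_s: float = 300.0
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("analysis band must satisfy 0 < fmin < fmax")
        if self.band[1] >= self.fs / 2:
            raise ValueError("band upper edge must lie below Nyquist")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.split_unit not in ("fragment", "subject"):
            raise ValueError("split_unit must be 'fragment' or 'subject'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        if "bands" in raw:
            raw["bands"] = tuple(spectral.Band(*b) for b in raw["bands"])
        if "rf_grid" in raw:
            raw["rf_grid"] = classify.RFGrid(
                **{k: tuple(v) for k, v in raw["rf_grid"].items()}
            )
        return cls(**raw)

    def echo(self) -> dict:
        d = asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        d["rf_grid"] = {k: list(v) for k, v in asdict(self.rf_grid).items()}
        return d


# ---------------------------------------------------------------------------
# recordings

def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    t = np.arange(rec.samples.size) / rec.fs
    pd.DataFrame({"time_s": t, "voltage_uV": rec.samples}).to_csv(path, index=False)
    sidecar = {
        "subject_id": rec.subject_id, "eye": rec.eye, "state": rec.state,
        "fs_hz": rec.fs, "device": rec.device, "species": rec.species,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a CSV + JSON sidecar recording."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata: {sidecar_path}")
    df = pd.read_csv(path)
    for col in ("time_s", "voltage_uV"):
        if col not in df.columns:
            raise ValueError(f"{path}: malformed recording CSV, missing column {col!r}")
    meta = json.loads(sidecar_path.read_text())
    return Recording(
        fs=float(meta["fs_hz"]), samples=df["voltage_uV"].to_numpy(float),
        subject_id=meta.get("subject_id", ""), eye=meta.get("eye", "right"),
        state=meta.get("state", "photopic"), species=meta.get("species", "human"),
        device=meta.get("device", ""),
    )


def read_recording_edf(path: str | Path, channel: int = 0) -> Recording:
    """Read the first (or given) channel of an EDF file via mne."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires mne") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[channel] * 1e6  # volts -> microvolts
    return Recording(fs=float(raw.info["sfreq"]), samples=data,
                     subject_id=Path(path).stem, device="edf")


# ---------------------------------------------------------------------------
# tables and reports

def write_metadata(df: pd.DataFrame, path: str | Path, clinical_names: bool = False) -> Path:
    from .clinlabel import TABLE1_COLUMN_MAP

    out = df.rename(columns=TABLE1_COLUMN_MAP) if clinical_names else df
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    from .clinlabel import TABLE1_COLUMN_MAP

    df = pd.read_csv(path)
    inverse = {v: k for k, v in TABLE1_COLUMN_MAP.items()}
    return df.rename(columns=inverse)


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=1, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# end-to-end pipeline

def _version() -> str:
    from . import __version__

    return __version__


def recording_features(rec: Recording, config: PipelineConfig) -> list[spectral.PowerSpectrum]:
    """Condition one recording and return per-fragment power spectra."""
    rec = bandlimit_filter(rec, config.highpass_hz, config.notch_hz)
    report = reject_artifacts(rec, config.artifact_threshold_uv, config.artifact_granularity)
    if config.artifact_granularity == "recording":
        if not report.kept:
            log.info("recording %s rejected (%d excursions)", rec.subject_id,
                     report.excursion_times_s.size)
            return []
        frags = sample_fragments(normalize_signal(rec), config.fragment_s)
    else:
        frags = []
        for ep in report.kept_epochs:
            r = Recording(fs=ep.fs, samples=ep.samples, subject_id=rec.subject_id,
                          eye=rec.eye, state=rec.state, species=rec.species,
                          device=rec.device)
            frags.extend(sample_fragments(normalize_signal(r), config.fragment_s))
    return [
        spectral.epoch_power_spectrum(
            ep, config.band[0], config.band[1], config.df, config.cycles,
            config.norm_mode,
        )
        for ep in frags
    ]


def profile_feature_table(
    profiles: dict,
    n_fragments: int,
    config: PipelineConfig,
    seed=0,
) -> pd.DataFrame:
    """Feature table with ``n_fragments`` conditioned fragments per profile.

    Each arm is generated as independent recordings of ``config.duration_s``
    seconds, run through the full conditioning chain, and cut into
    ``config.fragment_s`` fragments; used by simulation studies (null
    calibration, effect-recovery power).
    """
    per_rec = int(config.duration_s // config.fragment_s)
    n_rec = -(-n_fragments // per_rec)  # ceil
    ss = np.random.SeedSequence(classify._seed_int(seed))
    arms = ss.spawn(len(profiles))
    spectra, frag_ids, subj_ids, labels = [], [], [], []
    for (label, profile), arm in zip(profiles.items(), arms):
        count = 0
        for i, child in enumerate(arm.spawn(n_rec)):
            rec = synthcohort.simulate_recording(
                profile, config.duration_s, config.fs, child,
                subject_id=f"{label}_{i:03d}", species=config.species,
            )
            for j, spec in enumerate(recording_features(rec, config)):
                if count >= n_fragments:
                    break
                spectra.append(spec)
                frag_ids.append(f"{label}_{i:03d}_{j}")
                subj_ids.append(f"{label}_{i:03d}")
                labels.append(label)
                count += 1
    return classify.build_feature_table(spectra, frag_ids, subj_ids, labels,
                                        bands=config.bands)


def run_pipeline(
    config: PipelineConfig,
    data_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run simulate/ingest -> preprocess -> spectra -> classify -> explain.

    Without ``data_dir`` a synthetic cohort is generated from
    ``config.design``.  Returns (and optionally writes) a report bundle with
    the binary-screening metrics, high-CoV variable list, PCA variance
    fractions, and the configuration echo.
    """
    ss = np.random.SeedSequence(config.seed)
    s_cohort, s_balance, s_split, s_fit = (int(s) for s in ss.generate_state(4))
    if data_dir is None:
        subjects = synthcohort.make_cohort(
            config.design, config.duration_s, config.fs, seed=s_cohort,
            species=config.species,
        )
        recordings = [(s.subject_id, s.group, r) for s in subjects for r in s.recordings]
        metadata = pd.DataFrame([{**s.metadata, "subject_id": s.subject_id}
                                 for s in subjects])
    else:
        data_dir = Path(data_dir)
        metadata = read_metadata(data_dir / "metadata.csv")
        from .clinlabel import assign_group, derive_indices

        groups = {
            row["subject_id"]: assign_group(derive_indices(row))
            for _, row in metadata.iterrows()
        }
        recordings = []
        for csv in sorted(data_dir.glob("*.csv")):
            if csv.name == "metadata.csv":
                continue
            rec = read_recording(csv)
            recordings.append((rec.subject_id, groups[rec.subject_id], rec))

    spectra, frag_ids, subj_ids, labels = [], [], [], []
    n_rejected = 0
    for sid, group, rec in recordings:
        specs = recording_features(rec, config)
        if not specs:
            n_rejected += 1
        for i, spec in enumerate(specs):
            spectra.append(spec)
            frag_ids.append(f"{sid}_{rec.state}_{rec.eye}_{i:02d}")
            subj_ids.append(sid)
            labels.append("control" if group == "control" else "disease")
    log.info("kept %d fragments from %d recordings (%d rejected)",
             len(spectra), len(recordings), n_rejected)
    table = classify.build_feature_table(spectra, frag_ids, subj_ids, labels,
                                         bands=config.bands)
    table = classify.balance_classes(table, seed=s_balance)
    train, test = classify.split_train_test(
        table, config.train_frac, unit=config.split_unit, seed=s_split
    )
    fitted = classify.tune_fit_rf(train, config.rf_grid, config.cv_folds, seed=s_fit)
    report_cls = classify.evaluate(
        fitted, test, positive_class="disease",
        config={"split_unit": config.split_unit, "params": fitted.params},
    )

    feat_cols = classify.feature_columns(table)
    top = explain.select_high_cov(table, k=min(20, len(feat_cols)), variables=feat_cols)
    pca = explain.run_pca(table, top)
    bundle = {
        "version": _version(),
        "seed": config.seed,
        "config": config.echo(),
        "n_fragments": len(table),
        "n_rejected_recordings": n_rejected,
        "classification": report_cls.to_dict(),
        "explain": {
            "high_cov_variables": top,
            "pc_variance_fraction": pca.variance_fraction[:3].tolist(),
        },
    }
    if out_dir is not None:
        write_report(bundle, Path(out_dir) / "report.json")
    return bundle
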