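"""Reading recordings, writing cohorts, serializing model bundles.

The interchange format for raw EEG is either EDF/EDF+ (read through
:mod:`mne`) or a plain CSV matrix: a header line with the sampling rate
and channel labels, then one row per channel.  Model bundles are
directories holding the fitted classifier stack (joblib), a JSON metadata
file with the config echo, feature dimensions and stacking order, and a
version tag checked on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .errors import InputError
from .preprocess import FRONTAL_CHANNELS, EEGRecording

BUNDLE_VERSION = 1


# ---------------------------------------------------------------------------
# raw EEG
# ---------------------------------------------------------------------------

def write_recording_csv(rec: EEGRecording, path) -> None:
    """CSV matrix: header line ``# sampling_rate_hz=... channels=...``,
    then one row of microvolt samples per channel."""
    path = Path(path)
    header = (
        f"# sampling_rate_hz={rec.sampling_rate} "
        f"channels={','.join(rec.channel_labels)} "
        f"patient_id={rec.patient_id}"
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, rec.signal, fmt="%.4f", delimiter=",")


def read_recording_csv(path) -> EEGRecording:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise InputError(f"{path}: missing header line")
        fields = dict(
            part.split("=", 1) for part in header.lstrip("# ").split() if "=" in part
        )
        try:
            fs = float(fields["sampling_rate_hz"])
            channels = tuple(fields["channels"].split(","))
        except (KeyError, ValueError) as exc:
            raise InputError(f"{path}: unreadable header ({exc})") from exc
        try:
            signal = np.loadtxt(fh, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise InputError(f"{path}: truncated or malformed data ({exc})") from exc
    if signal.shape[0] != len(channels):
        raise InputError(
            f"{path}: header names {len(channels)} channels, data has {signal.shape[0]} rows"
        )
    return EEGRecording(signal, fs, channels, fields.get("patient_id", path.stem))


def read_recording_edf(path, channels=FRONTAL_CHANNELS) -> EEGRecording:
    """Read the frontal channels from an EDF/EDF+ file via mne."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise InputError("EDF support requires the optional mne dependency") from exc
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise InputError(f"{path}: unreadable EDF ({exc})") from exc
    missing = [c for c in channels if c not in raw.ch_names]
    if missing:
        raise InputError(f"{path}: missing channels {missing}")
    raw.pick(list(channels))
    signal = raw.get_data() * 1e6  # mne loads volts; recordings are in microvolts
    return EEGRecording(signal, raw.info["sfreq"], tuple(channels), path.stem)


def read_eeg(path, format: str | None = None) -> EEGRecording:
    """Read a recording; the format is inferred from the suffix unless
    given explicitly ("edf" or "csv")."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "edf":
        return read_recording_edf(path)
    if fmt == "csv":
        return read_recording_csv(path)
    raise InputError(f"unsupported format {fmt!r} for {path}")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def write_cohort(patients, outdir) -> None:
    """One CSV recording per patient plus the clinical and ground-truth
    tables."""
    from .simulate import clinical_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for p in patients:
        write_recording_csv(p.recording, outdir / f"{p.patient_id}.csv")
        truth_rows.append(
            {
                "patient_id": p.patient_id,
                "suppression_fraction": p.ground_truth.suppression_fraction,
                "longest_run_s": p.ground_truth.longest_run_s,
                "n_artifact_samples": len(p.ground_truth.artifact_indices),
            }
        )
    clinical_table(patients).to_csv(outdir / "clinical.csv")
    pd.DataFrame(truth_rows).set_index("patient_id").to_csv(outdir / "ground_truth.csv")


def read_clinical_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    table = pd.read_csv(path)
    if "patient_id" not in table.columns:
        raise InputError(f"{path}: clinical table needs a patient_id column")
    return table.set_index("patient_id")


# ---------------------------------------------------------------------------
# model bundles
# ---------------------------------------------------------------------------

def save_bundle(results, path) -> None:
    """Serialize fitted results (or a GroupedModelSet) to a directory."""
    from .model import DeliriumRiskResults

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(results, DeliriumRiskResults):
        payload = {"kind": "single", "results": _strip(results)}
        cfg = results.config
    else:  # GroupedModelSet
        payload = {
            "kind": "grouped",
            "groups": {g: _strip(r) for g, r in results.groups.items()},
            "all_model": _strip(results.all_model),
            "min_group_size": results.min_group_size,
        }
        cfg = results.all_model.config
    meta = {
        "bundle_version": BUNDLE_VERSION,
        "kind": payload["kind"],
        "config": cfg.to_dict(),
        "n_cov_rows": 4 * len(cfg.bands) + 1,
        "stacking_order": "channel-major within band, bands low to high, timeline last",
    }
    joblib.dump(payload, path / "models.joblib")
    (path / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _strip(results):
    # the embedded model holds the full training features; the bundle
    # only needs the fitted state
    import copy

    out = copy.copy(results)
    out.model = None
    return out


def load_bundle(path):
    """Load a saved bundle; predictions round-trip exactly."""
    path = Path(path)
    meta_path = path / "metadata.json"
    models_path = path / "models.joblib"
    for p, name in [(meta_path, "metadata.json"), (models_path, "models.joblib")]:
        if not p.exists():
            raise InputError(f"bundle at {path} is missing {name}")
    meta = json.loads(meta_path.read_text())
    if meta.get("bundle_version") != BUNDLE_VERSION:
        raise InputError(
            f"bundle version {meta.get('bundle_version')} is incompatible "
            f"with this package (expected {BUNDLE_VERSION})"
        )
    payload = joblib.load(models_path)
    if payload["kind"] == "single":
        results = payload["results"]
        if results.ens_cov.reference is None:
            raise InputError("bundle is missing the covariance reference point")
        return results
    from .evaluate import GroupedModelSet

    return GroupedModelSet(
        payload["groups"], payload["all_model"], payload["min_group_size"]
    )
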