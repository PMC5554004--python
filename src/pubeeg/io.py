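"""File I/O: BrainVision reading, flat binary matrix + JSON header, trial
tables as TSV, and array containers for grids.

The native on-disk format for recordings is a raw float32 channel-major
matrix (``<prefix>.dat``) beside a JSON header (``<prefix>.json``) describing
rate, channel names, montage and sample count.  BrainVision triplets
(.vhdr/.vmrk/.eeg) are read through mne when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EEGRecording

__all__ = [
    "write_recording",
    "read_recording",
    "read_brainvision",
    "write_trials",
    "read_trials",
    "save_grids",
    "load_grids",
]

TRIAL_COLUMNS = ["trial", "noise_onset_s", "speech_onset_s", "probe_onset_s",
                 "probe_duration_s", "rt_ms", "correct", "word_id"]


def write_recording(eeg: EEGRecording, prefix) -> None:
    """Write a recording as float32 binary + JSON header."""
    prefix = Path(prefix)
    header = {
        "rate": eeg.rate,
        "n_channels": eeg.n_channels,
        "n_samples": eeg.n_samples,
        "channel_names": list(eeg.channel_names),
        "montage": None if eeg.montage is None else eeg.montage.tolist(),
        "reference": eeg.reference,
        "dtype": "float32",
        "order": "channels_major",
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))
    eeg.data.astype(np.float32).tofile(prefix.with_suffix(".dat"))


def read_recording(prefix) -> EEGRecording:
    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    data = np.fromfile(prefix.with_suffix(".dat"), dtype=header["dtype"])
    data = data.reshape(header["n_channels"], header["n_samples"]).astype(float)
    montage = header.get("montage")
    return EEGRecording(data=data, rate=header["rate"],
                        channel_names=header["channel_names"],
                        montage=None if montage is None else np.asarray(montage),
                        reference=header.get("reference", "as-recorded"))


def read_brainvision(vhdr_path) -> EEGRecording:
    """Read a BrainVision .vhdr/.vmrk/.eeg triplet (requires mne)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data=data, rate=float(raw.info["sfreq"]),
                        channel_names=list(raw.ch_names))


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "correct" in df.columns:
        df["correct"] = df["correct"].astype("boolean")
    return df


def save_grids(path, **arrays) -> None:
    """Save named arrays (PUB grids, t-maps, phases) as an .npz container."""
    np.savez_compressed(path, **arrays)


def load_grids(path) -> dict:
    with np.load(path, allow_pickle=False) as z:
        return {k: z[k] for k in z.files}
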