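"""File formats: montage text files, the epoch interchange directory,
evoked/template CSVs, standard EEG readers, and YAML configs.

The interchange format is one directory per EpochSet:

* ``montage.txt`` — whitespace-delimited, one electrode per row:
  ``label x y z``; ``#`` starts a comment.
* ``timeaxis.json`` — ``{"sfreq": ..., "n_tf": ..., "t0_index": ...}``.
* ``metadata.csv`` — one row per trial (subject, condition, phoneme,
  item, rt_ms, accepted).
* ``data.csv`` (default) or ``data.npy`` — the trials x electrodes x TF
  matrix.  The CSV stores one row per (trial, electrode) with the trial
  index, electrode label, then the TF columns, in montage order, using
  17 significant digits so a CSV round trip is bit-exact.  The ``.npy``
  layout is a little-endian float64 C-order array.

CSV dialect everywhere: comma-separated, '.' decimal, UTF-8, LF line
endings, headers mandatory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .topography import EpochSet, Evoked, Montage, TimeAxis

__all__ = [
    "FormatError",
    "read_montage",
    "write_montage",
    "write_interchange",
    "read_interchange",
    "write_evoked_csv",
    "read_evoked_csv",
    "write_templates_csv",
    "read_templates_csv",
    "read_raw_mne",
    "load_config",
    "save_config",
]


class FormatError(ValueError):
    """An on-disk artifact does not match its declared dimensions."""


# ---------------------------------------------------------------------------
# Montage files
# ---------------------------------------------------------------------------


def read_montage(path) -> Montage:
    labels, rows = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(
                f"{path}:{lineno}: expected 'label x y z', got {line!r}"
            )
        labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad coordinate") from exc
    return Montage(labels=labels, positions=np.asarray(rows))


def write_montage(path, montage: Montage) -> None:
    lines = ["# label x y z"]
    for lab, (x, y, z) in zip(montage.labels, montage.positions):
        lines.append(f"{lab} {x:.17g} {y:.17g} {z:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Epoch interchange directory
# ---------------------------------------------------------------------------


def write_interchange(directory, epochs: EpochSet, fmt: str = "csv") -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_montage(d / "montage.txt", epochs.montage)
    (d / "timeaxis.json").write_text(
        json.dumps(
            {
                "sfreq": epochs.time.sfreq,
                "n_tf": epochs.time.n_tf,
                "t0_index": epochs.time.t0_index,
            }
        )
        + "\n"
    )
    epochs.metadata.to_csv(d / "metadata.csv", index=False, lineterminator="\n")
    n_trials, n_ch, n_tf = epochs.data.shape
    if fmt == "npy":
        np.save(d / "data.npy", np.ascontiguousarray(epochs.data, dtype="<f8"))
    elif fmt == "csv":
        header = "trial,electrode," + ",".join(f"tf{t}" for t in range(n_tf))
        with open(d / "data.csv", "w", newline="\n") as fh:
            fh.write(header + "\n")
            for i in range(n_trials):
                for c in range(n_ch):
                    vals = ",".join(f"{v:.17g}" for v in epochs.data[i, c])
                    fh.write(f"{i},{epochs.montage.labels[c]},{vals}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return d


def read_interchange(directory) -> EpochSet:
    d = Path(directory)
    if not d.is_dir():
        raise FileNotFoundError(f"interchange directory not found: {d}")
    montage = read_montage(d / "montage.txt")
    ta = json.loads((d / "timeaxis.json").read_text())
    time = TimeAxis(sfreq=ta["sfreq"], n_tf=ta["n_tf"], t0_index=ta["t0_index"])
    metadata = pd.read_csv(d / "metadata.csv")
    n_trials, n_ch, n_tf = len(metadata), montage.n_channels, time.n_tf

    if (d / "data.npy").exists():
        data = np.load(d / "data.npy")
        if data.shape != (n_trials, n_ch, n_tf):
            raise FormatError(
                f"data.npy shape {data.shape} != (trials={n_trials}, "
                f"electrodes={n_ch}, tf={n_tf})"
            )
    else:
        df = pd.read_csv(d / "data.csv", float_precision="round_trip")
        if len(df.columns) != n_tf + 2:
            raise FormatError(
                f"data.csv has {len(df.columns) - 2} TF columns, "
                f"timeaxis declares {n_tf} time frames"
            )
        if len(df) != n_trials * n_ch:
            raise FormatError(
                f"data.csv has {len(df)} rows, expected trials x electrodes "
                f"= {n_trials} x {n_ch}"
            )
        data = df.iloc[:, 2:].to_numpy(dtype=float).reshape(n_trials, n_ch, n_tf)
        file_labels = df["electrode"].iloc[:n_ch].tolist()
        if file_labels != list(montage.labels):
            raise FormatError("data.csv electrode order differs from montage")
    return EpochSet(data=data, montage=montage, time=time, metadata=metadata)


# ---------------------------------------------------------------------------
# Evoked / template CSVs
# ---------------------------------------------------------------------------


def write_evoked_csv(path, evoked: Evoked) -> None:
    """Rows = time frames (first column the TF index), columns = electrodes
    in montage order."""
    df = pd.DataFrame(
        evoked.data.T, columns=list(evoked.montage.labels)
    )
    df.insert(0, "tf", np.arange(evoked.time.n_tf))
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_evoked_csv(path, montage: Montage, time: TimeAxis, **kw) -> Evoked:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns[1:])
    if cols != list(montage.labels):
        raise FormatError("evoked CSV electrode columns differ from montage")
    if len(df) != time.n_tf:
        raise FormatError(
            f"evoked CSV has {len(df)} frames, time axis declares {time.n_tf}"
        )
    return Evoked(
        data=df.iloc[:, 1:].to_numpy(float).T,
        montage=montage,
        time=time,
        n_trials=kw.pop("n_trials", 1),
        **kw,
    )


def write_templates_csv(path, templates: np.ndarray, montage: Montage, letters) -> None:
    """One row per electrode (first column the label), one column per map."""
    df = pd.DataFrame(
        np.asarray(templates).T, columns=list(letters)
    )
    df.insert(0, "electrode", list(montage.labels))
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def read_templates_csv(path, montage: Montage) -> tuple[np.ndarray, tuple]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df["electrode"].tolist() != list(montage.labels):
        raise FormatError("template CSV electrode order differs from montage")
    letters = tuple(df.columns[1:])
    return df.iloc[:, 1:].to_numpy(float).T, letters


# ---------------------------------------------------------------------------
# Standard EEG formats (continuous data)
# ---------------------------------------------------------------------------


def read_raw_mne(path) -> tuple[np.ndarray, float, list[str]]:
    """Read continuous BrainVision (.vhdr) or EDF (.edf) data.

    Returns (data in microvolts, sfreq, channel names).  The reader is a
    thin wrapper over MNE; montage coordinates come from a separate
    montage file, not from the recording.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise FormatError(f"unsupported raw format: {path.suffix}")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    out = yaml.safe_load(path.read_text())
    return out or {}


def save_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
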