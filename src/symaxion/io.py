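"""Dataset input/output.

Two interchange formats are supported:

* the array container: ``<prefix>.npy`` holding the trials x channels x
  samples float array plus a ``<prefix>.json`` sidecar with labels, class
  names, sampling rate and channel names;
* EDF recordings (one continuous signal per channel) with a JSON or CSV label
  sidecar giving one class id per 1-s epoch.  Reading uses mne; a minimal
  16-bit EDF writer is included for interoperability testing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .features import EpochSet
from .montage import ElectrodeLayout


def save_epochs(epochs: EpochSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write the array container; returns (data_path, sidecar_path)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    data_path = prefix.with_suffix(".npy")
    meta_path = prefix.with_suffix(".json")
    np.save(data_path, epochs.data)
    meta = {
        "sampling_rate": epochs.sampling_rate,
        "labels": epochs.labels.tolist(),
        "class_names": list(epochs.class_names),
        "channel_names": list(epochs.channel_names) if epochs.channel_names else None,
    }
    meta_path.write_text(json.dumps(meta))
    return data_path, meta_path


def load_epochs(prefix: str | Path) -> EpochSet:
    """Read an array container written by :func:`save_epochs`."""
    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return EpochSet(
        data=data,
        sampling_rate=meta["sampling_rate"],
        labels=np.asarray(meta["labels"], dtype=int),
        class_names=tuple(meta["class_names"]),
        channel_names=tuple(meta["channel_names"]) if meta.get("channel_names") else None,
    )


def read_edf(
    edf_path: str | Path,
    labels_path: str | Path,
    layout: ElectrodeLayout,
    epoch_length: float = 1.0,
) -> EpochSet:
    """Read a continuous EDF recording and segment it into labelled epochs.

    Channel labels in the file must cover the montage (matching is
    case-insensitive); channels are reordered to the montage order.  The
    label sidecar is JSON with keys ``labels`` (one class id per consecutive
    epoch) and ``class_names``.
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    upper = {name.upper(): name for name in raw.ch_names}
    missing = [n for n in layout.names if n.upper() not in upper]
    if missing:
        raise ValueError(f"EDF is missing montage channels: {missing[:5]}...")
    raw.pick([upper[n.upper()] for n in layout.names])
    raw.reorder_channels([upper[n.upper()] for n in layout.names])
    sfreq = float(raw.info["sfreq"])
    sig = raw.get_data() * 1e6  # mne returns volts; the pipeline works in microvolts
    n_samples = int(round(sfreq * epoch_length))
    meta = json.loads(Path(labels_path).read_text())
    labels = np.asarray(meta["labels"], dtype=int)
    n_epochs = min(len(labels), sig.shape[1] // n_samples)
    data = sig[:, : n_epochs * n_samples].reshape(len(layout.names), n_epochs, n_samples)
    return EpochSet(
        data=np.moveaxis(data, 0, 1),
        sampling_rate=sfreq,
        labels=labels[:n_epochs],
        class_names=tuple(meta["class_names"]),
        channel_names=layout.names,
    )


def write_edf(epochs: EpochSet, edf_path: str | Path, labels_path: str | Path | None = None) -> None:
    """Write epochs as one continuous 16-bit EDF recording (1-s data records).

    Epochs are concatenated in order; physical units are microvolts.  A JSON
    label sidecar is written when ``labels_path`` is given.
    """
    if epochs.channel_names is None:
        raise ValueError("channel names are required to write EDF")
    n_epochs, n_ch, n_samples = epochs.data.shape
    sig = np.moveaxis(epochs.data, 1, 0).reshape(n_ch, n_epochs * n_samples)
    record_samples = int(round(epochs.sampling_rate))  # 1-s records
    n_records = sig.shape[1] // record_samples
    sig = sig[:, : n_records * record_samples]

    pmin = np.floor(sig.min(axis=1))
    pmax = np.ceil(sig.max(axis=1))
    pmax = np.where(pmax <= pmin, pmin + 1, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((sig - pmin[:, None]) * scale[:, None]) + dmin, dmin, dmax).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),  # version
            pad("X X X X", 80),  # patient id (anonymous)
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + n_ch)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, seconds
            pad(str(n_ch), 4),
        ]
    )
    fields = [
        b"".join(pad(name, 16) for name in epochs.channel_names),
        b"".join(pad("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(pad("uV", 8) for _ in range(n_ch)),
        b"".join(pad(f"{v:g}", 8) for v in pmin),
        b"".join(pad(f"{v:g}", 8) for v in pmax),
        b"".join(pad(str(dmin), 8) for _ in range(n_ch)),
        b"".join(pad(str(dmax), 8) for _ in range(n_ch)),
        b"".join(pad("", 80) for _ in range(n_ch)),
        b"".join(pad(str(record_samples), 8) for _ in range(n_ch)),
        b"".join(pad("", 32) for _ in range(n_ch)),
    ]
    with open(edf_path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for rec in range(n_records):
            chunk = digital[:, rec * record_samples : (rec + 1) * record_samples]
            fh.write(chunk.tobytes())

    if labels_path is not None:
        Path(labels_path).write_text(
            json.dumps({"labels": epochs.labels.tolist(), "class_names": list(epochs.class_names)})
        )
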