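"""Readers and writers for recordings, adjacency matrices and tables.

Two interchange formats are supported for multichannel recordings:

* **EDF** (European Data Format): the field's standard container for
  biosignals. Written here with 16-bit quantisation scaled to each
  channel's physical range; readable by any EDF tool (``mne`` included).
* **A float-exact binary container**: a ``<stem>.npy`` array of shape
  (channels, samples) in C order, float64 little-endian, plus a
  ``<stem>.json`` sidecar holding subject id, sampling rate, channel
  labels and reference. Round-trips are bit-exact, which EDF's integer
  quantisation cannot offer.

Adjacency (PLI) matrices use the same npy+json scheme, or a delimited
text form with a header row of channel labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

_EDF_VERSION = "0"


def _ascii_field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, sampling_rate: float, channel_labels,
              subject_id: str = "X", physical_dim: str = "uV") -> None:
    """Write a (channels, samples) array as a 16-bit EDF file.

    One data record per second; samples beyond the last whole second are
    dropped (EDF records have fixed integer duration). Each channel is
    scaled to its own physical min/max over the full digital range, so
    the quantisation step is ``(max - min) / 65535``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels, samples)")
    fs = int(round(sampling_rate))
    if abs(fs - sampling_rate) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise ValueError("one label per channel required")
    n_rec = n_samp // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    data = data[:, : n_rec * fs]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    header = b"".join(
        [
            _ascii_field(_EDF_VERSION, 8),
            _ascii_field(subject_id, 80),
            _ascii_field("recording", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(str(256 * (1 + n_ch)), 8),
            _ascii_field("", 44),
            _ascii_field(str(n_rec), 8),
            _ascii_field("1", 8),
            _ascii_field(str(n_ch), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_ascii_field(lab, 16) for lab in channel_labels),
            b"".join(_ascii_field("EEG", 80) for _ in range(n_ch)),
            b"".join(_ascii_field(physical_dim, 8) for _ in range(n_ch)),
            b"".join(_ascii_field(f"{v:.6g}", 8) for v in pmin),
            b"".join(_ascii_field(f"{v:.6g}", 8) for v in pmax),
            b"".join(_ascii_field(str(dmin), 8) for _ in range(n_ch)),
            b"".join(_ascii_field(str(dmax), 8) for _ in range(n_ch)),
            b"".join(_ascii_field("", 80) for _ in range(n_ch)),
            b"".join(_ascii_field(str(fs), 8) for _ in range(n_ch)),
            b"".join(_ascii_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        # record-major, channel-contiguous within each record
        for rec in range(n_rec):
            block = digital[:, rec * fs : (rec + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path):
    """Read an EDF file, returning (data uV, sampling_rate, labels, subject).

    Minimal reader for files produced by :func:`write_edf` and other
    single-rate continuous EDF recordings.
    """
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        subject = hdr[8:88].decode("ascii").strip()
        n_rec = int(hdr[236:244])
        rec_dur = float(hdr[244:252])
        n_ch = int(hdr[252:256])
        sig = fh.read(256 * n_ch)

        def fields(offset, width):
            base = offset * n_ch
            return [
                sig[base + k * width : base + (k + 1) * width].decode("ascii").strip()
                for k in range(n_ch)
            ]

        labels = fields(0, 16)
        pmin = np.array([float(v) for v in fields(16 + 80 + 8, 8)], float)
        pmax = np.array([float(v) for v in fields(16 + 80 + 8 + 8, 8)], float)
        dmin = np.array([float(v) for v in fields(16 + 80 + 8 + 16, 8)], float)
        dmax = np.array([float(v) for v in fields(16 + 80 + 8 + 24, 8)], float)
        nsamp = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(nsamp)) != 1:
            raise ValueError("mixed per-channel rates are not supported")
        spr = nsamp[0]
        raw = np.frombuffer(fh.read(2 * spr * n_ch * n_rec), dtype="<i2")
    raw = raw.reshape(n_rec, n_ch, spr).transpose(1, 0, 2).reshape(n_ch, -1)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (raw - dmin[:, None]) * scale[:, None] + pmin[:, None]
    fs = spr / rec_dur
    return data, fs, labels, subject


def write_array_container(stem, data: np.ndarray, metadata: dict) -> None:
    """Write ``<stem>.npy`` (float64, C order) plus ``<stem>.json`` sidecar."""
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), np.ascontiguousarray(data, dtype=np.float64))
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(metadata, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_array_container(stem):
    """Read the npy+json pair written by :func:`write_array_container`."""
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npy"))
    with open(stem.with_suffix(".json")) as fh:
        metadata = json.load(fh)
    return data, metadata


def write_matrix_text(path, matrix: np.ndarray, labels) -> None:
    """Delimited text adjacency: header of N labels, then N rows of N values."""
    matrix = np.asarray(matrix, float)
    with open(path, "w") as fh:
        fh.write("\t".join(str(lab) for lab in labels) + "\n")
        for row in matrix:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix_text(path):
    with open(path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
        matrix = np.loadtxt(fh, delimiter="\t")
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match header label count")
    return matrix, labels
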