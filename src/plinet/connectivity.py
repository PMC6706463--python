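"""Instantaneous phase and phase-lag-index (PLI) connectivity.

The PLI between two narrowband signals is the magnitude of the
time-averaged sign of their wrapped instantaneous-phase difference:

    PLI = | < sign(wrap(phi_a(t) - phi_b(t))) >_t |

It is 0 when the phase difference has no consistent side (including the
exactly-zero-lag case, since sign(0) = 0) and 1 when one signal
consistently leads the other. Because strictly zero-lag synchronisation
— the signature of volume conduction, where one source projects
instantaneously to several electrodes — contributes sign(0) = 0, PLI
discards it by construction.

Estimation here is per epoch: the sign average is taken over time within
each epoch, its magnitude is the epoch's PLI, and the subject-level
value is the mean of the per-epoch PLIs over the M epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .montage import REGION_BLOCK_ORDER, Montage
from .preprocessing import EpochSet
from . import io as _io


@dataclass(frozen=True)
class PhaseTensor:
    """Instantaneous phase in (-pi, pi], shaped like the source EpochSet.

    Channels whose signal was constant (zero variance in some epoch)
    have undefined phase; their indices are listed in ``bad_channels``
    and every PLI involving them is reported as missing downstream.
    """

    subject_id: str
    sampling_rate: float
    channel_labels: tuple
    data: np.ndarray
    band: tuple | None
    bad_channels: tuple = ()

    def __post_init__(self):
        data = np.asarray(self.data, float)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError("phase tensor must be (epochs, channels, samples)")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class PLIMatrix:
    """Symmetric channels-by-channels PLI adjacency with zero diagonal.

    Entries lie in [0, 1]; entries involving flagged (constant) channels
    are NaN and tracked in ``missing_channels``.
    """

    subject_id: str
    channel_labels: tuple
    values: np.ndarray
    n_epochs: int
    band: tuple | None = None
    missing_channels: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("PLI matrix must be square")
        if v.shape[0] != len(self.channel_labels):
            raise ValueError("label count must match matrix size")
        valid = np.isfinite(v)
        if not np.allclose(v[valid], np.swapaxes(v, 0, 1)[valid]):
            raise ValueError("PLI matrix must be symmetric")
        if np.any(np.diagonal(v) != 0):
            raise ValueError("PLI diagonal must be exactly zero")
        if np.any((v[valid] < 0) | (v[valid] > 1)):
            raise ValueError("PLI entries must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def to_text(self, path) -> None:
        _io.write_matrix_text(path, self.values, self.channel_labels)

    def to_container(self, stem) -> None:
        _io.write_array_container(
            stem,
            self.values,
            {
                "subject_id": self.subject_id,
                "channel_labels": list(self.channel_labels),
                "n_epochs": self.n_epochs,
                "band": list(self.band) if self.band else None,
                "missing_channels": list(self.missing_channels),
                "kind": "pli_matrix",
            },
        )

    @classmethod
    def from_container(cls, stem) -> "PLIMatrix":
        values, meta = _io.read_array_container(stem)
        return cls(
            subject_id=meta["subject_id"],
            channel_labels=tuple(meta["channel_labels"]),
            values=values,
            n_epochs=meta["n_epochs"],
            band=tuple(meta["band"]) if meta.get("band") else None,
            missing_channels=tuple(meta.get("missing_channels", ())),
        )


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    w = np.mod(x, 2.0 * np.pi)  # [0, 2pi)
    return np.where(w > np.pi, w - 2.0 * np.pi, w)


def _sign_of_wrapped(diff: np.ndarray) -> np.ndarray:
    """sign(wrap(diff)) with wrap onto (-pi, pi] and sign(0) = 0.

    Computed directly from diff mod 2*pi: values in (0, pi] are positive
    lags, values in (pi, 2*pi) negative, exact multiples of 2*pi are 0.
    """
    w = np.mod(diff, 2.0 * np.pi)
    return np.where(w == 0.0, 0.0, np.where(w <= np.pi, 1.0, -1.0))


def instantaneous_phase(epochset: EpochSet) -> PhaseTensor:
    """Phase of the analytic (Hilbert) signal, per epoch/channel/sample.

    Requires a band-limited EpochSet (the band must have been recorded
    by isolate_band): instantaneous phase is only meaningful for
    narrowband signals.
    """
    if epochset.band is None:
        raise ValueError(
            "epochs must be band-limited before phase extraction; "
            "run isolate_band first"
        )
    data = epochset.data
    variances = data.var(axis=2)  # (epochs, channels)
    bad = tuple(int(c) for c in np.where((variances == 0).any(axis=0))[0])
    if bad:
        warnings.warn(
            f"channels {bad} are constant in at least one epoch; "
            "their phase is undefined and downstream PLI will be missing"
        )
    analytic = hilbert(data, axis=2)
    phase = np.angle(analytic)
    # np.angle returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] contract
    phase = np.where(phase == -np.pi, np.pi, phase)
    return PhaseTensor(
        subject_id=epochset.subject_id,
        sampling_rate=epochset.sampling_rate,
        channel_labels=epochset.channel_labels,
        data=phase,
        band=epochset.band,
        bad_channels=bad,
    )


def pli_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLI between two per-epoch phase series of shape (epochs, samples).

    Within each epoch the sign of the wrapped phase difference is
    averaged over time and its magnitude taken; the returned value is
    the mean of those per-epoch magnitudes.
    """
    a = np.atleast_2d(np.asarray(phase_a, float))
    b = np.atleast_2d(np.asarray(phase_b, float))
    if a.shape != b.shape:
        raise ValueError(f"phase series shapes differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty phase series")
    if a.shape[1] < 2:
        raise ValueError("need at least 2 samples per epoch")
    s = _sign_of_wrapped(a - b)
    return float(np.abs(s.mean(axis=1)).mean())


def pli_matrix(phases: PhaseTensor) -> PLIMatrix:
    """All-pairs PLI adjacency from a phase tensor.

    Flagged (constant) channels propagate as NaN rows/columns, reported
    in ``missing_channels`` — never as 0, which is a meaningful PLI.
    """
    n_epochs, n_ch, _ = phases.data.shape
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    values = np.zeros((n_ch, n_ch))
    ph = phases.data
    for i in range(n_ch - 1):
        s = _sign_of_wrapped(ph[:, i, None, :] - ph[:, i + 1 :, :])
        values[i, i + 1 :] = np.abs(s.mean(axis=2)).mean(axis=0)
    values = values + values.T
    if phases.bad_channels:
        bad = list(phases.bad_channels)
        values[bad, :] = np.nan
        values[:, bad] = np.nan
    np.fill_diagonal(values, 0.0)
    return PLIMatrix(
        subject_id=phases.subject_id,
        channel_labels=phases.channel_labels,
        values=values,
        n_epochs=n_epochs,
        band=phases.band,
        missing_channels=tuple(
            phases.channel_labels[c] for c in phases.bad_channels
        ),
    )


def mean_global_pli(matrix: PLIMatrix) -> float:
    """Mean of the strictly-upper-triangle PLI entries (global PLI).

    Averaging the off-diagonal entries rather than the full matrix
    avoids deflating the value by the N zero diagonal cells; group
    comparisons are invariant to that choice of convention.
    """
    iu = np.triu_indices(matrix.n_channels, k=1)
    vals = matrix.values[iu]
    return float(np.nanmean(vals))


def region_block_view(matrix: PLIMatrix, montage: Montage) -> PLIMatrix:
    """Reorder channels into regional blocks (O, F, T_L, T_R, P).

    Channel labels are matched to montage electrode ids; within each
    region the original channel order is preserved. Idempotent, and all
    permutation-invariant summaries (e.g. global PLI) are unchanged.
    """
    label_to_idx = {lab: k for k, lab in enumerate(matrix.channel_labels)}
    montage_labels = {f"E{eid}" for eid in montage.ids}
    uncovered = sorted(set(matrix.channel_labels) - montage_labels)
    if uncovered:
        raise ValueError(
            f"montage does not cover channel(s): {', '.join(uncovered)}"
        )
    order = []
    for region in REGION_BLOCK_ORDER:
        for eid in montage.electrodes_in_region(region):
            lab = f"E{eid}"
            if lab in label_to_idx:
                order.append(label_to_idx[lab])
    order = np.asarray(order)
    return PLIMatrix(
        subject_id=matrix.subject_id,
        channel_labels=tuple(matrix.channel_labels[k] for k in order),
        values=matrix.values[np.ix_(order, order)],
        n_epochs=matrix.n_epochs,
        band=matrix.band,
        missing_channels=matrix.missing_channels,
    )
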