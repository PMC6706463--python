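"""Synthetic phase-coupled EEG cohorts.

The generator produces multichannel alpha-band recordings whose pairwise
phase coupling is under experimental control, so that the whole analysis
chain — PLI estimation, graph metrics, group statistics — can be
exercised with known ground truth.

Each channel is a noisy oscillator near the alpha centre frequency whose
phase obeys a degree-normalised Kuramoto update

    dphi_i/dt = omega_i + (K/k_i) * sum_j A_ij sin(phi_j - phi_i + delta_ij)

where k_i is the number of coupling partners of channel i: normalising
by k_i rather than the channel count makes the per-pair coupling a
given gain K produces independent of montage size and topology density,
so the same K is directly comparable between a 32-channel test cohort
and a 128-channel one.

The pairwise lag delta is *fixed and non-zero* (antisymmetric across
each pair: delta_ji = -delta_ij), so coupled pairs lock at a consistent
non-zero phase offset — the regime PLI is designed to detect. Zero lag
is reserved for the volume-conduction confound: an optional common
source added instantaneously (zero-lag) to every channel, which PLI
must, by construction, not register as connectivity.

The output signal per channel is an amplitude-modulated cosine of the
oscillator phase plus 1/f background noise. Clinical covariates
(MCCB-like, GAF-like) are linear-Gaussian in the subject's coupling
gain with a negative slope, emulating cohorts where stronger coupling
accompanies poorer functioning scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import Montage, default_montage
from .preprocessing import Recording

GROUPS = ("HC", "UHR", "FES")

_DEFAULT_GROUP_SIZES = {"HC": 15, "UHR": 15, "FES": 15}
_DEFAULT_COUPLING = {"HC": 0.5, "UHR": 3.0, "FES": 2.0}
_DEFAULT_COVARIATES = {
    "MCCB": {"intercept": 46.0, "slope": -3.0, "sd": 3.0},
    "GAF": {"intercept": 90.0, "slope": -10.0, "sd": 5.0},
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic cohort.

    group_sizes : subjects per group (HC, UHR, FES), each >= 2.
    n_channels, sampling_rate, duration : recording geometry
        (defaults 128 channels, 1000 Hz, 180 s).
    alpha_center, alpha_jitter : oscillator frequency in Hz; each
        channel's natural frequency is drawn N(center, jitter^2).
    coupling_strength : per-group Kuramoto gain K_g (dimensionless);
        a subject's own K is drawn N(K_g, coupling_spread^2), floored
        at 0.
    coupling_lag : fixed pairwise phase offset delta in (0, pi) radians.
    phase_noise : intrinsic phase diffusion of each oscillator in
        rad/sqrt(s). Real alpha rhythm is not a pure tone: its ~1 Hz
        spectral linewidth corresponds to Brownian phase noise, and
        without it two *uncoupled* oscillators with nearly equal
        frequencies would hold a fixed phase-difference sign for whole
        epochs, inflating null PLI. Default 1.7 rad/sqrt(s) gives a
        Lorentzian linewidth of about 0.9 Hz.
    coupling_topology : "regional" couples all within-region pairs of
        the schematic montage plus a sparse fraction
        (cross_region_density) of cross-region pairs; "all" couples
        every pair (used for few-channel setups).
    noise_sd : RMS of the 1/f background relative to the oscillation RMS.
    mixing_gain : zero-lag common-source leak coefficient (volume-
        conduction confound); 0 disables it.
    env_depth : relative depth of the slow amplitude modulation.
    phase_init : "random" (uniform initial phases) or "zero".
    covariate_model : per-scale {intercept, slope, sd} generating the
        clinical score from the subject's coupling K.
    integration_dt : time step (s) of the Euler-Maruyama phase
        integration. Phase velocities are a few tens of rad/s, so a
        4 ms step keeps the per-step phase advance small (~0.25 rad);
        phases are linearly interpolated onto the sample grid.
    seed : master seed; identical spec + seed reproduces the cohort
        exactly.
    """

    group_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_GROUP_SIZES))
    n_channels: int = 128
    sampling_rate: float = 1000.0
    duration: float = 180.0
    alpha_center: float = 10.0
    alpha_jitter: float = 0.1
    coupling_strength: dict = field(default_factory=lambda: dict(_DEFAULT_COUPLING))
    coupling_spread: float = 0.3
    coupling_lag: float = math.pi / 4
    phase_noise: float = 1.7
    coupling_topology: str = "regional"
    cross_region_density: float = 0.02
    noise_sd: float = 0.5
    mixing_gain: float = 0.0
    env_depth: float = 0.2
    phase_init: str = "random"
    covariate_model: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_COVARIATES.items()
    })
    integration_dt: float = 0.004
    seed: int = 0

    def __post_init__(self):
        for name in ("sampling_rate", "duration", "alpha_center", "alpha_jitter",
                     "coupling_lag", "cross_region_density", "noise_sd",
                     "mixing_gain", "env_depth", "coupling_spread",
                     "phase_noise"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v}")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.sampling_rate <= 2 * (self.alpha_center + self.alpha_jitter):
            raise ValueError(
                "sampling_rate must exceed twice the highest oscillator "
                "frequency (alpha_center + alpha_jitter)"
            )
        for g, k in self.coupling_strength.items():
            if not np.isfinite(k) or k < 0:
                raise ValueError(f"coupling_strength[{g}] must be finite and >= 0")
        if not (0 < self.coupling_lag < math.pi):
            raise ValueError(
                "coupling_lag must lie in (0, pi): zero lag is reserved for "
                "the volume-conduction confound"
            )
        if self.noise_sd < 0 or self.mixing_gain < 0 or self.phase_noise < 0:
            raise ValueError(
                "noise_sd, mixing_gain and phase_noise must be non-negative"
            )
        if not (0 < self.integration_dt <= 0.02):
            raise ValueError("integration_dt must lie in (0, 0.02] s")
        if self.phase_init not in ("random", "zero"):
            raise ValueError("phase_init must be 'random' or 'zero'")
        if self.coupling_topology not in ("regional", "all"):
            raise ValueError("coupling_topology must be 'regional' or 'all'")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def coupling_structure(spec: SyntheticCohortSpec):
    """Binary coupling adjacency A and antisymmetric lag matrix delta.

    Deterministic given the spec (topology randomness uses spec.seed),
    so every subject of a cohort shares one coupling structure.
    """
    n = spec.n_channels
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(0xA,))
    )
    A = np.zeros((n, n))
    if spec.coupling_topology == "regional" and n >= 5:
        montage = default_montage(n)
        regions = np.asarray(montage.regions)
        same = regions[:, None] == regions[None, :]
        A[same] = 1.0
        cross = (~same) & (rng.random((n, n)) < spec.cross_region_density)
        cross = np.triu(cross, 1)
        A[cross | cross.T] = 1.0
    else:
        A[:] = 1.0
    np.fill_diagonal(A, 0.0)
    delta = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    delta[iu] = spec.coupling_lag
    delta = delta - delta.T
    return A, delta


def _one_over_f_noise(rng: np.random.Generator, n_channels: int,
                      n_samples: int, sampling_rate: float) -> np.ndarray:
    """Unit-RMS 1/f-power noise by spectral shaping of white noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** -0.5  # amplitude ~ f^-1/2 => power ~ 1/f
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return shaped / rms


def _integrate_phases(omega: np.ndarray, phi0: np.ndarray, A: np.ndarray,
                      delta: np.ndarray, coupling: float, phase_noise: float,
                      dt: float, n_samples: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Euler-Maruyama integration of the noisy lagged Kuramoto dynamics.

    dphi_i = [omega_i + (K/k_i) sum_j A_ij sin(phi_j - phi_i + delta_ij)] dt
             + phase_noise dW_i

    The coupling term is evaluated as the imaginary part of
    conj(z_i) * (A e^{i delta} z)_i with z = e^{i phi}, one complex
    matrix-vector product per step; the degree normalisation 1/k_i is
    folded into the effective adjacency.
    """
    n = len(omega)
    if phase_noise > 0:
        increments = phase_noise * math.sqrt(dt) * rng.standard_normal(
            (n, n_samples - 1)
        )
    else:
        increments = None
    if coupling > 0 and A.any():
        phases = np.empty((n, n_samples))
        phases[:, 0] = phi0
        degrees = A.sum(axis=1)
        degrees[degrees == 0] = 1.0
        aeff = (A * np.exp(1j * delta)) * (coupling / degrees)[:, None]
        phi = phi0.copy()
        for t in range(1, n_samples):
            z = np.exp(1j * phi)
            drive = np.imag(np.conj(z) * (aeff @ z))
            phi = phi + dt * (omega + drive)
            if increments is not None:
                phi = phi + increments[:, t - 1]
            phases[:, t] = phi
    else:
        steps = np.empty((n, n_samples))
        steps[:, 0] = 0.0
        steps[:, 1:] = omega[:, None] * dt
        if increments is not None:
            steps[:, 1:] += increments
        phases = phi0[:, None] + np.cumsum(steps, axis=1)
    return phases


def simulate_subject(spec: SyntheticCohortSpec, subject_coupling: float,
                     seed, subject_id: str = "S001",
                     return_phases: bool = False):
    """Simulate one subject's recording.

    subject_coupling is the Kuramoto gain K for this subject; seed may
    be an int or a numpy SeedSequence. When return_phases is true the
    ground-truth oscillator phase trajectories (channels x samples) are
    returned alongside the Recording.
    """
    if not np.isfinite(subject_coupling) or subject_coupling < 0:
        raise ValueError("subject_coupling must be finite and >= 0")
    rng = np.random.default_rng(seed)
    n, t = spec.n_channels, spec.n_samples
    dt = 1.0 / spec.sampling_rate

    A, delta = coupling_structure(spec)
    omega = 2 * np.pi * (
        spec.alpha_center + spec.alpha_jitter * rng.standard_normal(n)
    )
    if spec.phase_init == "zero":
        phi0 = np.zeros(n)
    else:
        phi0 = rng.uniform(-np.pi, np.pi, size=n)

    # integrate on a coarser grid, then interpolate phase to the sample grid
    m = max(1, int(round(spec.integration_dt * spec.sampling_rate)))
    dt_i = m * dt
    n_coarse = (t - 1) // m + 2
    coarse = _integrate_phases(omega, phi0, A, delta, subject_coupling,
                               spec.phase_noise, dt_i, n_coarse, rng)
    if m == 1:
        phases = coarse[:, :t]
    else:
        q = np.arange(t) / m
        base = np.minimum(q.astype(int), n_coarse - 2)
        frac = q - base
        phases = coarse[:, base] * (1 - frac) + coarse[:, base + 1] * frac

    if spec.env_depth > 0:
        f_env = rng.uniform(0.05, 0.2, size=n)
        ph_env = rng.uniform(0, 2 * np.pi, size=n)
        tt = dt * np.arange(t)
        env = 1.0 + spec.env_depth * np.sin(
            2 * np.pi * f_env[:, None] * tt[None, :] + ph_env[:, None]
        )
    else:
        env = np.ones((n, 1))
    signal = env * np.cos(phases)

    osc_rms = signal.std(axis=1, keepdims=True)
    osc_rms[osc_rms == 0] = 1.0
    if spec.noise_sd > 0:
        noise = _one_over_f_noise(rng, n, t, spec.sampling_rate)
        signal = signal + spec.noise_sd * osc_rms * noise
    if spec.mixing_gain > 0:
        src_phase = (
            rng.uniform(-np.pi, np.pi)
            + 2 * np.pi * spec.alpha_center * dt * np.arange(t)
        )
        source = np.cos(src_phase) + 0.5 * _one_over_f_noise(
            rng, 1, t, spec.sampling_rate
        )[0]
        signal = signal + spec.mixing_gain * osc_rms * source[None, :]

    rec = Recording(
        subject_id=subject_id,
        sampling_rate=spec.sampling_rate,
        channel_labels=tuple(f"E{i}" for i in range(1, n + 1)),
        data=signal * 10.0,  # microvolt-like scale
    )
    if return_phases:
        return rec, phases
    return rec


def simulate_cohort(spec: SyntheticCohortSpec):
    """Simulate a full cohort: (list of Recording, cohort DataFrame).

    Subject couplings are drawn per group around K_g; clinical
    covariates follow the linear-Gaussian covariate model (negative
    slope by default: higher coupling, lower score). The cohort table
    rows match the recordings one-to-one by subject id.
    """
    for g, size in spec.group_sizes.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}; expected {GROUPS}")
        if size < 2:
            raise ValueError(f"group {g} must have at least 2 subjects")
    cohort_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(0xC,))
    )
    recordings, rows = [], []
    idx = 0
    for g in GROUPS:
        size = spec.group_sizes.get(g, 0)
        kg = spec.coupling_strength.get(g, 0.0)
        for _ in range(size):
            idx += 1
            sid = f"{g}{idx:03d}"
            k = max(0.0, kg + spec.coupling_spread * cohort_rng.standard_normal())
            rec = simulate_subject(
                spec, k,
                seed=np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, idx)),
                subject_id=sid,
            )
            recordings.append(rec)
            row = {
                "subject_id": sid,
                "group": g,
                "coupling": k,
                "sex": "M" if cohort_rng.random() < 0.55 else "F",
                "age": float(np.round(cohort_rng.normal(24.5, 5.0), 1)),
                "education": float(np.round(cohort_rng.normal(13.0, 3.3), 1)),
                "IQ": float(np.round(cohort_rng.normal(105.0, 13.0), 1)),
                "CDSST": float(np.round(abs(cohort_rng.normal(1.0, 1.2)), 2)),
            }
            for scale, model in spec.covariate_model.items():
                row[scale] = float(
                    model["intercept"]
                    + model["slope"] * k
                    + model["sd"] * cohort_rng.standard_normal()
                )
            if g == "FES":
                row["PANSS_total"] = float(np.round(cohort_rng.normal(84.0, 13.0), 1))
            else:
                row["SIPS_total"] = float(
                    np.round(abs(cohort_rng.normal(15.0 if g == "UHR" else 1.5,
                                                   5.0 if g == "UHR" else 1.5)), 1)
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    return recordings, table


def write_cohort(out_dir, recordings, table: pd.DataFrame,
                 montage: Montage | None = None, edf: bool = False) -> None:
    """Write a cohort to disk: per-subject containers, cohort CSV, montage CSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        rec.to_container(out / rec.subject_id)
        if edf:
            rec.to_edf(out / f"{rec.subject_id}.edf")
    table.to_csv(out / "cohort.csv", index=False)
    if montage is None and recordings:
        montage = default_montage(recordings[0].n_channels)
    if montage is not None:
        montage.to_csv(out / "montage.csv")
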