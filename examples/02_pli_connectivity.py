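"""From a raw recording to a PLI adjacency matrix.

The recording is segmented into 3-s epochs, the alpha band (8-13 Hz) is
isolated per epoch with a zero-phase filter and a 75 ms edge trim, the
instantaneous phase comes from the Hilbert transform, and the phase lag
index is computed per channel pair: the magnitude of the time-averaged
sign of the wrapped phase difference, averaged over epochs.

The demonstration plants one strongly coupled channel pair (fixed
quarter-cycle lag) and a zero-lag common source leaking into every
channel: PLI detects the lagged pair and ignores the common source.
"""

import numpy as np

from plinet import (
    SyntheticCohortSpec,
    instantaneous_phase,
    isolate_band,
    mean_global_pli,
    pli_matrix,
    segment,
    simulate_subject,
)

spec = SyntheticCohortSpec(
    group_sizes={"HC": 2, "UHR": 2, "FES": 2},
    n_channels=2,
    duration=33.0,
    coupling_topology="all",
    coupling_lag=np.pi / 2,
    mixing_gain=0.4,  # zero-lag common source into both channels
    seed=7,
)
recording = simulate_subject(spec, subject_coupling=8.0, seed=7)

epochs = segment(recording, epoch_length=3.0, n_epochs=10)
alpha = isolate_band(epochs, 8.0, 13.0, trim=0.075)
print(f"epochs: {alpha.data.shape} (epochs x channels x samples; "
      f"3 s minus 2 x 75 ms at 1000 Hz = {alpha.data.shape[2]})")

phases = instantaneous_phase(alpha)
matrix = pli_matrix(phases)
print(f"PLI of the coupled pair: {matrix.values[0, 1]:.3f} "
      "(near 1: consistent quarter-cycle lag)")
print(f"global PLI (upper-triangle mean): {mean_global_pli(matrix):.3f}")
print()
print("The zero-lag common source never shows up as connectivity: the")
print("wrapped phase difference it induces is symmetric around zero, so")
print("the sign average cancels; only genuinely lagged coupling survives.")
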