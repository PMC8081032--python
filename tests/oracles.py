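"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: plain Python loops,
``math`` scalar arithmetic and ``np.interp`` only, so they can serve as an
independent check of the vectorized/numba implementations.
"""

import math

import numpy as np


def predict_echo_peak_sample(elem_x, delays, sx, sz, c, fs, wavelet):
    """Predicted |RF| peak sample index on each receive channel for one
    scatterer whose transmit arrivals are aligned (e.g. on-axis scatterer
    with a symmetric zero-delay aperture).

    Time of flight: transmit arrival (same for all elements by construction)
    plus the return path to each receiver, plus the wavelet's own peak.
    Returns an (n_channels, n_candidates) array — one candidate per tied
    |wavelet| maximum, since subsample interpolation can land the echo's
    argmax on any of them.
    """
    t_tx = delays[0] + math.hypot(elem_x[0] - sx, sz) / c
    aw = np.abs(wavelet)
    # ties up to float rounding (antisymmetric bursts peak twice)
    k_peaks = np.flatnonzero(aw >= aw.max() * (1.0 - 1e-9))
    out = []
    for xj in elem_x:
        t = t_tx + math.hypot(xj - sx, sz) / c
        out.append([t * fs + k for k in k_peaks])
    return np.array(out)


def naive_das_focused(rf_data, t0, fs, elem_x, tx_delays, z_grid, c, f_number,
                      peak_time=0.0):
    """Triple-loop delay-and-sum with dynamic Hanning subaperture.

    One image line per element; receive delay law
    tau = tau_F(x_c) + (z + sqrt(z^2 + (x - x_c)^2)) / c, sampled with
    linear interpolation (np.interp).
    """
    n_el = len(elem_x)
    t_axis = t0 + np.arange(rf_data.shape[0]) / fs
    out = np.zeros((len(z_grid), n_el))
    for ci in range(n_el):
        xc = elem_x[ci]
        for zi, z in enumerate(z_grid):
            half = z / (2.0 * f_number)
            acc = 0.0
            for e in range(n_el):
                u = (elem_x[e] - xc) / half
                if abs(u) > 1.0:
                    continue
                w = 0.5 + 0.5 * math.cos(math.pi * u)
                tau = tx_delays[ci] + (z + math.hypot(z, elem_x[e] - xc)) / c
                acc += w * float(np.interp(tau + peak_time, t_axis, rf_data[:, e]))
            out[zi, ci] = acc
    return out
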