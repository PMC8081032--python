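"""Numba inner loops for RF echo superposition.

The forward model is a double sum over transmit elements e and scatterers k,
received on every element j:

    data[t, j] = sum_k A_k sum_e g_tx(e,k) g_rx(k,j)
                 * w(t - delays[e] - (d_ek + d_kj)/c)

It is evaluated exactly in two stages: for each scatterer the transmit-field
waveform p_k(t) = sum_e g_tx w(t - delays[e] - d_ek/c) is accumulated on a
local time window, then p_k is scattered onto every receive channel at its
round-trip delay.  Subsample delays use linear interpolation in both stages.
"""

import math

import numpy as np
from numba import njit


@njit(cache=False)
def superpose_echoes(
    data,  # (n_t, n_el) float64, modified in place
    fs,  # float
    elem_x,  # (n_el,) float64
    delays,  # (n_el,) float64 transmit delays
    sx,  # (n_sc,) scatterer x
    sz,  # (n_sc,) scatterer z
    amp,  # (n_sc,) reflectivities
    wav,  # (Lw,) two-way wavelet samples
    inv_c,  # float, 1/c
    spreading,  # bool: 1/r per path
    directivity,  # bool: cos(theta) hard-baffle factor per path
):
    """Accumulate all echoes into ``data``; returns the number of wavelet
    samples clipped by the end of the record window."""
    n_t, n_el = data.shape
    Lw = wav.shape[0]
    n_sc = sx.shape[0]
    clipped = 0
    ttx = np.empty(n_el)
    gtx = np.empty(n_el)
    for k in range(n_sc):
        zk = sz[k]
        # stage 1: transmit-field waveform at scatterer k
        tmin = 1e300
        tmax = -1e300
        for e in range(n_el):
            dx = sx[k] - elem_x[e]
            d = math.sqrt(dx * dx + zk * zk)
            t = delays[e] + d * inv_c
            g = 1.0
            if spreading:
                g /= d
            if directivity:
                g *= zk / d
            ttx[e] = t
            gtx[e] = g
            if t < tmin:
                tmin = t
            if t > tmax:
                tmax = t
        npad = int(math.ceil((tmax - tmin) * fs)) + Lw + 2
        p = np.zeros(npad)
        for e in range(n_el):
            off = (ttx[e] - tmin) * fs
            i0 = int(off)
            fr = off - i0
            for m in range(Lw):
                v = gtx[e] * wav[m]
                p[i0 + m] += v * (1.0 - fr)
                p[i0 + m + 1] += v * fr
        # stage 2: scatter onto every receive channel
        for j in range(n_el):
            dx = sx[k] - elem_x[j]
            d = math.sqrt(dx * dx + zk * zk)
            g = amp[k]
            if spreading:
                g /= d
            if directivity:
                g *= zk / d
            off = (tmin + d * inv_c) * fs
            i0 = int(off)
            fr = off - i0
            for m in range(npad):
                i = i0 + m
                if i >= n_t - 1:
                    clipped += npad - m
                    break
                if i < 0:
                    continue
                v = g * p[m]
                data[i, j] += v * (1.0 - fr)
                data[i + 1, j] += v * fr
    return clipped
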