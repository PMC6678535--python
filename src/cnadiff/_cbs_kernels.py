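"""Numba kernels for the circular-binary-segmentation arc scan.

The max-arc statistic over a segment of length n compares the mean inside an
arc (i, j] against the mean of its complement, scaled by the segment's trimmed
SD.  For a fixed arc width k the statistic is a monotone function of the
windowed sum S[i+k] - S[i], so the maximum over i reduces to tracking the
running max and min of that sliding difference — three cheap operations per
(k, i) pair instead of a full t computation, which is what makes full
permutation testing tractable at 180K probes.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def scan_ge(S, n, sd, min_w, wstarts, wlen, thresh):
    """Arc-scan maximum, exact only with respect to the comparison `max >= thresh`.

    Uses the centered-cumsum form of the statistic,
    stat(i, j) = |z[j] - z[i]| * sqrt(n / (k (n - k))) / sd with z[i] = S[i] - i*T/n,
    so the window's z-range yields an O(1) upper bound per width k; widths whose
    bound falls below ``thresh`` cannot host an arc with stat >= thresh and are
    skipped.  The return value is therefore a lower bound on the true maximum
    that is exact whenever it is >= thresh, which is all the permutation test
    ever compares.  Early-exits as soon as an arc reaches ``thresh``.
    """
    T = S[n]
    mu = T / n
    best = 0.0
    for w in range(wstarts.shape[0]):
        s = wstarts[w]
        e = s + wlen
        if e > n:
            e = n
        L = e - s
        kmax = L
        if kmax > n - min_w:
            kmax = n - min_w
        zmax = -1e300
        zmin = 1e300
        for i in range(s, e + 1):
            z = S[i] - mu * i
            if z > zmax:
                zmax = z
            if z < zmin:
                zmin = z
        rng_z = zmax - zmin
        for k in range(min_w, kmax + 1):
            c = np.sqrt(n / (k * (n - k))) / sd
            if rng_z * c * (1.0 + 1e-12) < thresh:
                continue
            dmax = -1e300
            dmin = 1e300
            for i in range(s, e - k + 1):
                d = S[i + k] - S[i]
                if d > dmax:
                    dmax = d
                if d < dmin:
                    dmin = d
            v1 = dmax - mu * k
            if v1 < 0.0:
                v1 = -v1
            v2 = dmin - mu * k
            if v2 < 0.0:
                v2 = -v2
            v = v1 if v1 > v2 else v2
            v *= c
            if v > best:
                best = v
                if best >= thresh:
                    return best
    return best


@njit(cache=True)
def scan_argmax(S, n, sd, min_w, wstarts, wlen):
    """Best arc (statistic, i, j); ties broken by smallest i, then smallest j."""
    T = S[n]
    best = -1.0
    bi = -1
    bj = -1
    for w in range(wstarts.shape[0]):
        s = wstarts[w]
        e = s + wlen
        if e > n:
            e = n
        L = e - s
        kmax = L
        if kmax > n - min_w:
            kmax = n - min_w
        for k in range(min_w, kmax + 1):
            ak = 1.0 / k + 1.0 / (n - k)
            bk = T / (n - k)
            c = 1.0 / (sd * np.sqrt(ak))
            for i in range(s, e - k + 1):
                d = S[i + k] - S[i]
                v = ak * d - bk
                if v < 0.0:
                    v = -v
                v *= c
                if v > best or (v == best and (i < bi or (i == bi and i + k < bj))):
                    best = v
                    bi = i
                    bj = i + k
    return best, bi, bj
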