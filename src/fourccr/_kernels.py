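"""Fixed-step integration kernels (numba-jitted) for the 4CCr equations.

The grid is built per profile segment so that no step straddles a breakpoint
of the piecewise-constant (TL, V) input.  Within a segment the rate
coefficients are constant and the only nonlinearity is the controller's
min().  Two steppers are provided: classical RK4 (the main integrator) and
explicit Euler (the independent first-order oracle).

Status codes: 0 = ok, 1 = instability (a compartment left
[-1e-6, 1 + 1e-6] before clipping).
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_UNSTABLE = 1

_CLIP_EPS = 1e-6
_RENORM_TOL = 1e-12


@njit(cache=True)
def _rates(TL, V, FC0, FP0, RC0, RP0, r, k, rest_mult_at_rest):
    decay = np.exp(-k * V)
    FP = FP0 * (1.0 - decay)
    FC = FC0 * decay
    RP = RP0
    if rest_mult_at_rest:
        RC = r * RC0 if TL == 0.0 else RC0
    else:
        RC = RC0 if TL == 0.0 else r * RC0
    return FP, FC, RP, RC


@njit(cache=True)
def _deriv(MA, MR, MFP, MFC, TL, L, FP, FC, RP, RC):
    c = TL - MA
    if MR < c:
        c = MR
    C = L * c
    dMA = -FP * MA - FC * MA + C
    dMR = RP * MFP + RC * MFC - C
    dMFP = -RP * MFP + FP * MA
    dMFC = -RC * MFC + FC * MA
    return dMA, dMR, dMFP, dMFC


@njit(cache=True)
def integrate_profile(
    breaks, tls, vs, seg_counts,
    FC0, FP0, RC0, RP0, r, k, L, rest_mult_at_rest,
    state0, order,
):
    """Integrate over all segments; returns (t, states, tl, v, status, i_bad)."""
    n_pts = 1
    for j in range(seg_counts.shape[0]):
        n_pts += seg_counts[j]
    t_out = np.empty(n_pts)
    s_out = np.empty((n_pts, 4))
    tl_out = np.empty(n_pts)
    v_out = np.empty(n_pts)

    MA, MR, MFP, MFC = state0[0], state0[1], state0[2], state0[3]
    t_out[0] = 0.0
    s_out[0, 0] = MA
    s_out[0, 1] = MR
    s_out[0, 2] = MFP
    s_out[0, 3] = MFC
    tl_out[0] = tls[0]
    v_out[0] = vs[0]

    pos = 1
    for j in range(seg_counts.shape[0]):
        t0 = breaks[j]
        t1 = breaks[j + 1]
        n = seg_counts[j]
        h = (t1 - t0) / n
        TL = tls[j]
        V = vs[j]
        FP, FC, RP, RC = _rates(TL, V, FC0, FP0, RC0, RP0, r, k, rest_mult_at_rest)
        for i in range(n):
            if order == 1:
                d1 = _deriv(MA, MR, MFP, MFC, TL, L, FP, FC, RP, RC)
                MA += h * d1[0]
                MR += h * d1[1]
                MFP += h * d1[2]
                MFC += h * d1[3]
            else:
                d1 = _deriv(MA, MR, MFP, MFC, TL, L, FP, FC, RP, RC)
                d2 = _deriv(MA + 0.5 * h * d1[0], MR + 0.5 * h * d1[1],
                            MFP + 0.5 * h * d1[2], MFC + 0.5 * h * d1[3],
                            TL, L, FP, FC, RP, RC)
                d3 = _deriv(MA + 0.5 * h * d2[0], MR + 0.5 * h * d2[1],
                            MFP + 0.5 * h * d2[2], MFC + 0.5 * h * d2[3],
                            TL, L, FP, FC, RP, RC)
                d4 = _deriv(MA + h * d3[0], MR + h * d3[1],
                            MFP + h * d3[2], MFC + h * d3[3],
                            TL, L, FP, FC, RP, RC)
                MA += h / 6.0 * (d1[0] + 2.0 * d2[0] + 2.0 * d3[0] + d4[0])
                MR += h / 6.0 * (d1[1] + 2.0 * d2[1] + 2.0 * d3[1] + d4[1])
                MFP += h / 6.0 * (d1[2] + 2.0 * d2[2] + 2.0 * d3[2] + d4[2])
                MFC += h / 6.0 * (d1[3] + 2.0 * d2[3] + 2.0 * d3[3] + d4[3])

            # instability check before any clipping
            if (MA < -_CLIP_EPS or MA > 1.0 + _CLIP_EPS
                    or MR < -_CLIP_EPS or MR > 1.0 + _CLIP_EPS
                    or MFP < -_CLIP_EPS or MFP > 1.0 + _CLIP_EPS
                    or MFC < -_CLIP_EPS or MFC > 1.0 + _CLIP_EPS):
                return t_out, s_out, tl_out, v_out, STATUS_UNSTABLE, pos

            if MA < 0.0:
                MA = 0.0
            elif MA > 1.0:
                MA = 1.0
            if MR < 0.0:
                MR = 0.0
            elif MR > 1.0:
                MR = 1.0
            if MFP < 0.0:
                MFP = 0.0
            elif MFP > 1.0:
                MFP = 1.0
            if MFC < 0.0:
                MFC = 0.0
            elif MFC > 1.0:
                MFC = 1.0
            total = MA + MR + MFP + MFC
            if np.abs(total - 1.0) > _RENORM_TOL:
                MA /= total
                MR /= total
                MFP /= total
                MFC /= total

            t_out[pos] = t0 + (i + 1) * h if i + 1 < n else t1
            s_out[pos, 0] = MA
            s_out[pos, 1] = MR
            s_out[pos, 2] = MFP
            s_out[pos, 3] = MFC
            tl_out[pos] = TL
            v_out[pos] = V
            pos += 1

    return t_out, s_out, tl_out, v_out, STATUS_OK, -1


@njit(cache=True)
def final_capacity(
    breaks, tls, vs, seg_counts,
    FC0, FP0, RC0, RP0, r, k, L, rest_mult_at_rest,
    sample_times,
):
    """Residual capacity MA+MR at given sample times, RK4, no trajectory storage.

    Used by the fitting loop; returns (capacities, status).  Sample times must
    be sorted and are matched to the nearest grid point (grid resolution is
    the segment step, <= dt).
    """
    caps = np.empty(sample_times.shape[0])
    n_samp = sample_times.shape[0]
    si = 0
    MA, MR, MFP, MFC = 0.0, 1.0, 0.0, 0.0
    t = 0.0
    # samples at or before t=0
    while si < n_samp and sample_times[si] <= 1e-12:
        caps[si] = MA + MR
        si += 1
    for j in range(seg_counts.shape[0]):
        t0 = breaks[j]
        t1 = breaks[j + 1]
        n = seg_counts[j]
        h = (t1 - t0) / n
        TL = tls[j]
        V = vs[j]
        FP, FC, RP, RC = _rates(TL, V, FC0, FP0, RC0, RP0, r, k, rest_mult_at_rest)
        for i in range(n):
            d1 = _deriv(MA, MR, MFP, MFC, TL, L, FP, FC, RP, RC)
            d2 = _deriv(MA + 0.5 * h * d1[0], MR + 0.5 * h * d1[1],
                        MFP + 0.5 * h * d1[2], MFC + 0.5 * h * d1[3],
                        TL, L, FP, FC, RP, RC)
            d3 = _deriv(MA + 0.5 * h * d2[0], MR + 0.5 * h * d2[1],
                        MFP + 0.5 * h * d2[2], MFC + 0.5 * h * d2[3],
                        TL, L, FP, FC, RP, RC)
            d4 = _deriv(MA + h * d3[0], MR + h * d3[1],
                        MFP + h * d3[2], MFC + h * d3[3],
                        TL, L, FP, FC, RP, RC)
            MA += h / 6.0 * (d1[0] + 2.0 * d2[0] + 2.0 * d3[0] + d4[0])
            MR += h / 6.0 * (d1[1] + 2.0 * d2[1] + 2.0 * d3[1] + d4[1])
            MFP += h / 6.0 * (d1[2] + 2.0 * d2[2] + 2.0 * d3[2] + d4[2])
            MFC += h / 6.0 * (d1[3] + 2.0 * d2[3] + 2.0 * d3[3] + d4[3])
            if (MA < -_CLIP_EPS or MA > 1.0 + _CLIP_EPS
                    or MR < -_CLIP_EPS or MR > 1.0 + _CLIP_EPS
                    or MFP < -_CLIP_EPS or MFP > 1.0 + _CLIP_EPS
                    or MFC < -_CLIP_EPS or MFC > 1.0 + _CLIP_EPS):
                return caps, STATUS_UNSTABLE
            if MA < 0.0:
                MA = 0.0
            elif MA > 1.0:
                MA = 1.0
            if MR < 0.0:
                MR = 0.0
            elif MR > 1.0:
                MR = 1.0
            if MFP < 0.0:
                MFP = 0.0
            elif MFP > 1.0:
                MFP = 1.0
            if MFC < 0.0:
                MFC = 0.0
            elif MFC > 1.0:
                MFC = 1.0
            total = MA + MR + MFP + MFC
            if np.abs(total - 1.0) > _RENORM_TOL:
                MA /= total
                MR /= total
                MFP /= total
                MFC /= total
            t = t0 + (i + 1) * h if i + 1 < n else t1
            while si < n_samp and sample_times[si] <= t + 1e-12:
                caps[si] = MA + MR
                si += 1
    while si < n_samp:
        caps[si] = MA + MR
        si += 1
    return caps, STATUS_OK
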