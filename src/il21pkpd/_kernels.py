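"""Compiled fixed-step RK4 kernel for the coupled PK+PD system.

State vector layout (length n_pk + 7):

* ``y[0:n_pk]``        PK compartment amounts (µg)
* ``y[n_pk]``          cumulative degraded drug (µg) — mass-balance tally
* ``y[n_pk+1:n_pk+7]`` PD states: N, C, pN, pC, Mem, T

The kernel hardcodes the default saturable rate form ``w*x/(1+alpha*x)``;
pluggable alternative forms go through the pure-Python reference path in
:mod:`il21pkpd.pk` / :mod:`il21pkpd.pd`, against which this kernel is
cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _rhs(y, out, n_pk, tsrc, tdst, tw, talpha, didx, dd, dbeta,
         plasma_i, inv_vs, pdp, pd_on):
    for i in range(y.shape[0]):
        out[i] = 0.0
    for k in range(tsrc.shape[0]):
        x = y[tsrc[k]]
        if x < 0.0:
            x = 0.0
        flow = tw[k] * x / (1.0 + talpha[k] * x)
        out[tsrc[k]] -= flow
        out[tdst[k]] += flow
    for k in range(didx.shape[0]):
        x = y[didx[k]]
        if x < 0.0:
            x = 0.0
        loss = dd[k] * x / (1.0 + dbeta[k] * x)
        out[didx[k]] -= loss
        out[n_pk] += loss
    if pd_on:
        u = y[plasma_i] * inv_vs
        if u < 0.0:
            u = 0.0
        N = y[n_pk + 1]
        C = y[n_pk + 2]
        pN = y[n_pk + 3]
        pC = y[n_pk + 4]
        M = y[n_pk + 5]
        T = y[n_pk + 6]
        out[n_pk + 1] = pdp[0] - pdp[1] * N - pdp[2] * (u / (pdp[3] + u)) * N
        out[n_pk + 2] = pdp[9] + pdp[7] * M * C * (1.0 - C / pdp[8]) - pdp[10] * C
        out[n_pk + 3] = pdp[14] * (pdp[11] + pdp[12] * u / (pdp[13] + u) - pN)
        out[n_pk + 4] = pdp[18] * (pdp[15] + pdp[16] * u / (pdp[17] + u) - pC)
        out[n_pk + 5] = pdp[4] * u / (pdp[5] + u) - pdp[6] * M
        out[n_pk + 6] = (pdp[21] * T * (1.0 - T / pdp[22])
                         - (pdp[19] * N * pN + pdp[20] * C * pC) * T)


@njit(cache=True)
def integrate_segment(y, dt, n_steps, out_states, out_start,
                      n_pk, tsrc, tdst, tw, talpha, didx, dd, dbeta,
                      plasma_i, inv_vs, pdp, pd_on):
    """Advance ``y`` in place by ``n_steps`` RK4 steps, saving every step.

    ``out_states[out_start + k]`` receives the state after step ``k+1``.
    """
    n = y.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    yt = np.empty(n)
    for step in range(n_steps):
        _rhs(y, k1, n_pk, tsrc, tdst, tw, talpha, didx, dd, dbeta,
             plasma_i, inv_vs, pdp, pd_on)
        for i in range(n):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        _rhs(yt, k2, n_pk, tsrc, tdst, tw, talpha, didx, dd, dbeta,
             plasma_i, inv_vs, pdp, pd_on)
        for i in range(n):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        _rhs(yt, k3, n_pk, tsrc, tdst, tw, talpha, didx, dd, dbeta,
             plasma_i, inv_vs, pdp, pd_on)
        for i in range(n):
            yt[i] = y[i] + dt * k3[i]
        _rhs(yt, k4, n_pk, tsrc, tdst, tw, talpha, didx, dd, dbeta,
             plasma_i, inv_vs, pdp, pd_on)
        for i in range(n):
            y[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        for i in range(n):
            out_states[out_start + step, i] = y[i]
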