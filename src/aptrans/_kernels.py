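"""Numba kernels for the ventricular action-potential model.

All of the model arithmetic lives here in scalar/array form so that the
public API (``aptrans.apmodel``) and the paced integrator share a single
source of truth.  Conventions:

* voltage in mV, time in ms, currents in A/F, outward currents positive;
* gate vector order: m, h, mL, hL, d, f, a, i, xr, xs, dT, fT;
* current vector order: Na, NaL, CaL, CaT, to, Kr, Ks, KL, NaCa, NaK,
  pCa, bCl, bCa;
* ``consts`` vector: E_Na, E_K, E_Ca, E_Cl, RT/F, Ca_i, Ca_o, q_ncx,
  f_nak_sat, sigma_nak, f_pca.
"""

import numpy as np
from numba import njit

N_GATES = 12
N_CURRENTS = 13

# gate indices
M, H, ML, HL, D, F, A, I, XR, XS, DT, FT = range(N_GATES)
# current indices
INA, INAL, ICAL, ICAT, ITO, IKR, IKS, IKL, INACA, INAK, IPCA, IBCL, IBCA = range(
    N_CURRENTS
)
# consts indices
CE_NA, CE_K, CE_CA, CE_CL, CVT, CCAI, CCAO, CQNCX, CFNAK, CSIGMA, CFPCA = range(11)

# ---------------------------------------------------------------------------
# Kinetic constants.  The T-type gates follow the printed closed forms with
# midpoints -26.3 mV (activation) and -61.7 mV (inactivation); the remaining
# rate constants are this package's calibrated stand-in kinetics (see
# docs/methods.md).
# ---------------------------------------------------------------------------

# I_CaL permeability scale (dimensionless, applied to the GHK flux factor)
K_CAL = 6.0
# I_NaCa driving normalisation (dimensionless)
K_NCX = 200.0
# GHK extracellular calcium activity coefficient
GAMMA_CAO = 0.341


@njit(cache=True)
def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def ttype_d(v):
    """T-type activation: (d_inf, tau_d [ms]) at voltage v [mV]."""
    d_inf = 1.0 / (1.0 + np.exp(-(v + 26.3) / 6.0))
    tau_d = 1.0 / (
        1.068 * np.exp((v + 26.3) / 30.0) + 1.068 * np.exp(-(v + 26.3) / 30.0)
    )
    return d_inf, tau_d


@njit(cache=True)
def ttype_f(v):
    """T-type inactivation: (f_inf, tau_f [ms]) at voltage v [mV]."""
    f_inf = 1.0 / (1.0 + np.exp((v + 61.7) / 5.6))
    tau_f = 1.0 / (
        0.0153 * np.exp(-(v + 61.7) / 83.3) + 0.015 * np.exp((v + 61.7) / 15.38)
    )
    return f_inf, tau_f


@njit(cache=True)
def gate_steady_tau(v):
    """Steady states and time constants of all twelve gates at voltage v."""
    inf = np.empty(N_GATES)
    tau = np.empty(N_GATES)

    # fast sodium activation / inactivation
    inf[M] = _sig((v + 40.0) / 6.0)
    tau[M] = 0.05 + 0.35 * np.exp(-(((v + 45.0) / 15.0) ** 2))
    inf[H] = _sig(-(v + 71.0) / 6.0)
    tau[H] = 0.3 + 9.0 / (1.0 + np.exp((v + 55.0) / 8.0))

    # late sodium
    inf[ML] = _sig((v + 42.0) / 6.0)
    tau[ML] = 0.05 + 0.35 * np.exp(-(((v + 45.0) / 15.0) ** 2))
    inf[HL] = _sig(-(v + 80.0) / 7.0)
    tau[HL] = 200.0

    # L-type calcium
    inf[D] = _sig((v + 9.0) / 6.0)
    tau[D] = 0.5 + 1.8 * np.exp(-(((v + 15.0) / 20.0) ** 2))
    inf[F] = _sig(-(v + 33.0) / 4.5)
    tau[F] = 19.3 + 89.0 * np.exp(-(((v - 15.0) / 30.0) ** 2))

    # transient outward
    inf[A] = _sig((v - 10.0) / 13.0)
    tau[A] = 1.5 + 3.5 * np.exp(-(((v + 10.0) / 30.0) ** 2))
    inf[I] = _sig(-(v + 45.0) / 5.0)
    tau[I] = 4.0 + 20.0 * np.exp(-(((v + 50.0) / 20.0) ** 2))

    # rapid delayed rectifier activation
    inf[XR] = _sig((v + 20.0) / 8.0)
    tau[XR] = 18.0 + 417.0 * np.exp(-(((v + 0.0) / 20.0) ** 2))

    # slow delayed rectifier activation
    inf[XS] = _sig((v - 2.0) / 14.0)
    tau[XS] = 300.0 + 700.0 * np.exp(-(((v - 10.0) / 40.0) ** 2))

    # T-type calcium (printed closed forms)
    inf[DT], tau[DT] = ttype_d(v)
    inf[FT], tau[FT] = ttype_f(v)

    return inf, tau


@njit(cache=True)
def ghk_ca(v, vt, ca_i, ca_o):
    """GHK-style flux factor for calcium (mV * mM; negative = inward)."""
    u = 2.0 * v / vt
    if abs(u) < 1e-6:
        # series limit of v*(ca_i*e^u - gamma*ca_o)/(e^u - 1) as u -> 0
        return 0.5 * vt * (ca_i - GAMMA_CAO * ca_o)
    eu = np.exp(u)
    return v * (ca_i * eu - GAMMA_CAO * ca_o) / (eu - 1.0)


@njit(cache=True)
def currents(v, gates, g, blocks, consts):
    """All thirteen membrane currents (A/F, outward positive)."""
    e_na = consts[CE_NA]
    e_k = consts[CE_K]
    e_ca = consts[CE_CA]
    e_cl = consts[CE_CL]
    vt = consts[CVT]

    out = np.empty(N_CURRENTS)

    out[INA] = blocks[INA] * g[INA] * gates[M] ** 3 * gates[H] * (v - e_na)
    out[INAL] = blocks[INAL] * g[INAL] * gates[ML] * gates[HL] * (v - e_na)
    out[ICAL] = (
        blocks[ICAL]
        * g[ICAL]
        * K_CAL
        * gates[D]
        * gates[F]
        * ghk_ca(v, vt, consts[CCAI], consts[CCAO])
    )
    out[ICAT] = blocks[ICAT] * g[ICAT] * gates[DT] * gates[FT] * (v - e_ca)
    out[ITO] = blocks[ITO] * g[ITO] * gates[A] * gates[I] * (v - e_k)

    r_kr = _sig(-(v + 15.0) / 24.0)  # instantaneous inward rectification
    out[IKR] = blocks[IKR] * g[IKR] * gates[XR] * r_kr * (v - e_k)
    out[IKS] = blocks[IKS] * g[IKS] * gates[XS] ** 2 * (v - e_k)

    kl_inf = _sig(-(v - e_k - 0.0) / 10.0)  # instantaneous inward rectifier
    out[IKL] = blocks[IKL] * g[IKL] * kl_inf * (v - e_k)

    x = v / vt
    em = np.exp(-0.65 * x)
    out[INACA] = (
        blocks[INACA]
        * g[INACA]
        * (np.exp(0.35 * x) * consts[CQNCX] - em)
        / (K_NCX * (1.0 + 0.27 * em))
    )
    f_nak = 1.0 / (
        1.0 + 0.1245 * np.exp(-0.1 * x) + 0.0365 * consts[CSIGMA] * np.exp(-x)
    )
    out[INAK] = blocks[INAK] * g[INAK] * f_nak * consts[CFNAK]
    out[IPCA] = blocks[IPCA] * g[IPCA] * consts[CFPCA]

    out[IBCL] = blocks[IBCL] * g[IBCL] * (v - e_cl)
    out[IBCA] = blocks[IBCA] * g[IBCA] * (v - e_ca)

    return out


@njit(cache=True)
def dv_dt(v, gates, g, blocks, consts, stim):
    cur = currents(v, gates, g, blocks, consts)
    s = 0.0
    for k in range(N_CURRENTS):
        s += cur[k]
    return -s + stim


@njit(cache=True)
def pace(
    v0,
    gates0,
    g,
    blocks,
    consts,
    period,
    stim_duration,
    stim_amplitude,
    n_beats,
    record_beat,
    dt_min,
    dt_max,
    dv_max,
):
    """Integrate ``n_beats`` paced cycles with an adaptive Rush-Larsen/Heun
    scheme.

    Gates are advanced with the exact exponential (Rush-Larsen) update, which
    keeps them in [0, 1] for any step size; the voltage uses Heun's method
    with the step chosen so that a single step changes v by at most
    ``dv_max`` mV (and never exceeds ``dt_max`` ms, tightened to 0.05 ms in
    the first 20 ms of each beat to resolve the upstroke).

    Records every accepted step of beats ``record_beat`` and
    ``record_beat - 1`` (0-based).  Returns
    (status, tp, vp, n_prev, tr, vr, n_rec, v_end, gates_end) where status is
    0 on success and 1 if the state became non-finite.
    """
    max_steps = int(period / dt_min) + 4096
    tp = np.empty(max_steps)
    vp = np.empty(max_steps)
    tr = np.empty(max_steps)
    vr = np.empty(max_steps)
    n_prev = 0
    n_rec = 0

    v = v0
    gates = gates0.copy()
    status = 0

    for beat in range(n_beats):
        rec_this = beat == record_beat
        rec_prev = beat == record_beat - 1
        if rec_this:
            n_rec = 0
        if rec_prev:
            n_prev = 0
        t = 0.0
        if rec_this:
            tr[0] = 0.0
            vr[0] = v
            n_rec = 1
        if rec_prev:
            tp[0] = 0.0
            vp[0] = v
            n_prev = 1
        while t < period:
            stim = stim_amplitude if t < stim_duration else 0.0
            k1 = dv_dt(v, gates, g, blocks, consts, stim)

            cap = 0.05 if t < 20.0 else dt_max
            dt = dv_max / (abs(k1) + 1e-12)
            if dt > cap:
                dt = cap
            if dt < dt_min:
                dt = dt_min
            # do not step across the stimulus edge or the beat boundary
            if t < stim_duration and t + dt > stim_duration:
                dt = stim_duration - t
            if t + dt > period:
                dt = period - t

            inf, tau = gate_steady_tau(v)
            new_gates = np.empty(N_GATES)
            for j in range(N_GATES):
                new_gates[j] = inf[j] + (gates[j] - inf[j]) * np.exp(-dt / tau[j])

            stim2 = stim_amplitude if (t + dt) < stim_duration else 0.0
            v_pred = v + dt * k1
            k2 = dv_dt(v_pred, new_gates, g, blocks, consts, stim2)
            v_new = v + 0.5 * dt * (k1 + k2)

            if not np.isfinite(v_new):
                status = 1
                return status, tp, vp, n_prev, tr, vr, n_rec, v, gates

            v = v_new
            gates = new_gates
            t += dt

            if rec_this and n_rec < max_steps:
                tr[n_rec] = t
                vr[n_rec] = v
                n_rec += 1
            if rec_prev and n_prev < max_steps:
                tp[n_prev] = t
                vp[n_prev] = v
                n_prev += 1

    return status, tp, vp, n_prev, tr, vr, n_rec, v, gates
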