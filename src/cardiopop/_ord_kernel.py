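"""Numba kernels for the O'Hara-Rudy (ORd) human ventricular endocardial model.

The 41-state endocardial formulation (O'Hara, Virag, Varro & Rudy 2011) is
transcribed here with seven scalable maximal conductances/fluxes:

    index 0: s_Kr   -> G_Kr   (rapid delayed rectifier K+)
    index 1: s_Ks   -> G_Ks   (slow delayed rectifier K+)
    index 2: s_K1   -> G_K1   (inward rectifier K+)
    index 3: s_to   -> G_to   (transient outward K+)
    index 4: s_CaL  -> P_Ca   (L-type Ca2+ channel permeability)
    index 5: s_NaCa -> G_ncx  (Na+/Ca2+ exchanger)
    index 6: s_up   -> J_up   (net SR uptake flux variable, uptake - leak)

Everything in this module is nopython-compiled; the public API lives in
:mod:`cardiopop.ord`.  Units follow the model's native conventions: time ms,
voltage mV, concentrations mM, currents uA/uF (C_m = 1 uF/cm^2).
"""

import numpy as np
from numba import njit

N_STATES = 41

# State vector layout (indices into y)
IV, INAI, INASS, IKI, IKSS, ICAI, ICASS, ICANSR, ICAJSR = range(9)
IM, IHF, IHS, IJ, IHSP, IJP, IML, IHL, IHLP = range(9, 18)
IA, IIF, IIS, IAP, IIFP, IISP = range(18, 24)
ID, IFF, IFS, IFCAF, IFCAS, IJCA, INCA, IFFP, IFCAFP = range(24, 33)
IXRF, IXRS, IXS1, IXS2, IXK1 = range(33, 38)
IJRELNP, IJRELP, ICAMKT = range(38, 41)

# Gate states updated by exact exponential (Rush-Larsen) integration
GATE_LO, GATE_HI = 9, 40  # indices 9..39 inclusive

# Current/flux output layout
C_INA, C_INAL, C_ITO, C_ICAL, C_ICANA, C_ICAK, C_IKR, C_IKS, C_IK1 = range(9)
C_INACA_I, C_INACA_SS, C_INAK, C_INAB, C_ICAB, C_IKB, C_IPCA = range(9, 16)
C_JREL, C_JUP, C_JLEAK, C_JTR, C_JDIFF, C_CAMKA = range(16, 22)
N_CURRENTS = 22

# Physical constants and cell geometry (endocardial)
_R = 8314.0
_T = 310.0
_F = 96485.0
_L = 0.01
_RAD = 0.0011
_VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
_AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
_ACAP = 2.0 * _AGEO
_VMYO = 0.68 * _VCELL
_VNSR = 0.0552 * _VCELL
_VJSR = 0.0048 * _VCELL
_VSS = 0.02 * _VCELL

_NAO = 140.0
_CAO = 1.8
_KO = 5.4


@njit(cache=True, fastmath=True, error_model="numpy")
def derivs(y, sc, istim, gss, gtau, dy, cur):
    """Full right-hand side of the ORd endocardial model.

    Fills ``gss``/``gtau`` with the steady state and time constant of every
    exponentially-relaxing gate (indices 9..39), ``dy`` with the complete time
    derivative of all 41 states, and ``cur`` with membrane currents and
    intracellular fluxes.  ``sc`` is the 7-vector of conductance scalings in
    the order (Kr, Ks, K1, to, CaL, NaCa, up); ``istim`` in uA/uF.
    """
    v = y[IV]
    nai = y[INAI]
    nass = y[INASS]
    ki = y[IKI]
    kss = y[IKSS]
    cai = y[ICAI]
    cass = y[ICASS]
    cansr = y[ICANSR]
    cajsr = y[ICAJSR]

    # --- CaMKII activity ----------------------------------------------------
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - y[ICAMKT]) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + y[ICAMKT]
    dy[ICAMKT] = aCaMK * CaMKb * (CaMKb + y[ICAMKT]) - bCaMK * y[ICAMKT]

    # --- reversal potentials ------------------------------------------------
    rtf = _R * _T / _F
    ENa = rtf * np.log(_NAO / nai)
    EK = rtf * np.log(_KO / ki)
    PKNa = 0.01833
    EKs = rtf * np.log((_KO + PKNa * _NAO) / (ki + PKNa * nai))
    vfrt = v / rtf
    vffrt = v * _F / rtf

    # --- fast Na+ current ---------------------------------------------------
    mss = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                + 8.552 * np.exp(-(v + 77.42) / 5.955))
    gss[IM] = mss
    gtau[IM] = tm

    hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285)
                 + 6.149 * np.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * np.exp((v + 5.730) / 56.66))
    gss[IHF] = hss
    gtau[IHF] = thf
    gss[IHS] = hss
    gtau[IHS] = ths
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    h = Ahf * y[IHF] + Ahs * y[IHS]

    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * np.exp((v + 0.9941) / 38.45))
    gss[IJ] = jss
    gtau[IJ] = tj

    hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
    gss[IHSP] = hssp
    gtau[IHSP] = 3.0 * ths
    hp = Ahf * y[IHF] + Ahs * y[IHSP]
    gss[IJP] = jss
    gtau[IJP] = 1.46 * tj

    GNa = 75.0
    fINap = 1.0 / (1.0 + KmCaMK / CaMKa)
    m3 = y[IM] * y[IM] * y[IM]
    INa = GNa * (v - ENa) * m3 * ((1.0 - fINap) * h * y[IJ]
                                  + fINap * hp * y[IJP])

    # --- late Na+ current ---------------------------------------------------
    mLss = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    gss[IML] = mLss
    gtau[IML] = tm
    hLss = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
    thL = 200.0
    gss[IHL] = hLss
    gtau[IHL] = thL
    hLssp = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
    gss[IHLP] = hLssp
    gtau[IHLP] = 3.0 * thL
    GNaL = 0.0075
    fINaLp = fINap
    INaL = GNaL * (v - ENa) * y[IML] * ((1.0 - fINaLp) * y[IHL]
                                        + fINaLp * y[IHLP])

    # --- transient outward K+ current --------------------------------------
    ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    gss[IA] = ass
    gtau[IA] = ta
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    # delta_epi = 1 for the endocardial cell type
    tiF = 4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * np.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * np.exp((v + 114.1) / 8.079))
    gss[IIF] = iss
    gtau[IIF] = tiF
    gss[IIS] = iss
    gtau[IIS] = tiS
    AiF = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_to_gate = AiF * y[IIF] + AiS * y[IIS]
    assp = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
    gss[IAP] = assp
    gtau[IAP] = ta
    dti_develop = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89)
                                    + np.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    gss[IIFP] = iss
    gtau[IIFP] = dti_develop * dti_recover * tiF
    gss[IISP] = iss
    gtau[IISP] = dti_develop * dti_recover * tiS
    ip = AiF * y[IIFP] + AiS * y[IISP]
    Gto = 0.02 * sc[3]
    fItop = fINap
    Ito = Gto * (v - EK) * ((1.0 - fItop) * y[IA] * i_to_gate
                            + fItop * y[IAP] * ip)

    # --- L-type Ca2+ current ------------------------------------------------
    dss = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    gss[ID] = dss
    gtau[ID] = td
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * np.exp((v + 5.0) / 6.0))
    gss[IFF] = fss
    gtau[IFF] = tff
    gss[IFS] = fss
    gtau[IFS] = tfs
    Aff = 0.6
    Afs = 1.0 - Aff
    f = Aff * y[IFF] + Afs * y[IFS]
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0)
                           + 0.00012 * np.exp(v / 7.0))
    gss[IFCAF] = fcass
    gtau[IFCAF] = tfcaf
    gss[IFCAS] = fcass
    gtau[IFCAS] = tfcas
    Afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    fca = Afcaf * y[IFCAF] + Afcas * y[IFCAS]
    gss[IJCA] = fcass
    gtau[IJCA] = 75.0
    gss[IFFP] = fss
    gtau[IFFP] = 2.5 * tff
    fp = Aff * y[IFFP] + Afs * y[IFS]
    gss[IFCAFP] = fcass
    gtau[IFCAFP] = 2.5 * tfcaf
    fcap = Afcaf * y[IFCAFP] + Afcas * y[IFCAS]

    Kmn = 0.002
    k2n = 1000.0
    km2n = y[IJCA] * 1.0
    if km2n < 1.0e-8:
        km2n = 1.0e-8
    tmp = 1.0 + Kmn / cass
    anca = 1.0 / (k2n / km2n + tmp * tmp * tmp * tmp)
    gss[INCA] = anca * k2n / km2n
    gtau[INCA] = 1.0 / km2n

    x2 = 2.0 * vfrt
    if x2 > 1.0e-7 or x2 < -1.0e-7:
        PhiCaL = 4.0 * vffrt * (cass * np.exp(x2) - 0.341 * _CAO) / (np.exp(x2) - 1.0)
    else:
        PhiCaL = 2.0 * _F * (cass - 0.341 * _CAO)
    if vfrt > 1.0e-7 or vfrt < -1.0e-7:
        ev = np.exp(vfrt)
        PhiCaNa = vffrt * (0.75 * nass * ev - 0.75 * _NAO) / (ev - 1.0)
        PhiCaK = vffrt * (0.75 * kss * ev - 0.75 * _KO) / (ev - 1.0)
    else:
        PhiCaNa = _F * 0.75 * (nass - _NAO)
        PhiCaK = _F * 0.75 * (kss - _KO)
    PCa = 0.0001 * sc[4]
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    fICaLp = fINap
    nca = y[INCA]
    d_gate = y[ID]
    jca = y[IJCA]
    ICaL = ((1.0 - fICaLp) * PCa * PhiCaL * d_gate
            * (f * (1.0 - nca) + jca * fca * nca)
            + fICaLp * PCap * PhiCaL * d_gate
            * (fp * (1.0 - nca) + jca * fcap * nca))
    ICaNa = ((1.0 - fICaLp) * PCaNa * PhiCaNa * d_gate
             * (f * (1.0 - nca) + jca * fca * nca)
             + fICaLp * PCaNap * PhiCaNa * d_gate
             * (fp * (1.0 - nca) + jca * fcap * nca))
    ICaK = ((1.0 - fICaLp) * PCaK * PhiCaK * d_gate
            * (f * (1.0 - nca) + jca * fca * nca)
            + fICaLp * PCaKp * PhiCaK * d_gate
            * (fp * (1.0 - nca) + jca * fcap * nca))

    # --- rapid delayed rectifier K+ current --------------------------------
    xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
    gss[IXRF] = xrss
    gtau[IXRF] = txrf
    gss[IXRS] = xrss
    gtau[IXRS] = txrs
    Axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * y[IXRF] + Axrs * y[IXRS]
    rkr = (1.0 / (1.0 + np.exp((v + 55.0) / 75.0))
           / (1.0 + np.exp((v - 10.0) / 30.0)))
    GKr = 0.046 * sc[0]
    IKr = GKr * np.sqrt(_KO / 5.4) * xr * rkr * (v - EK)

    # --- slow delayed rectifier K+ current ---------------------------------
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                          + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    gss[IXS1] = xs1ss
    gtau[IXS1] = txs1
    txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                  + 0.0193 * np.exp(-(v + 66.54) / 31.0))
    gss[IXS2] = xs1ss
    gtau[IXS2] = txs2
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034 * sc[1]
    IKs = GKs * KsCa * y[IXS1] * y[IXS2] * (v - EKs)

    # --- inward rectifier K+ current ---------------------------------------
    xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * _KO + 144.59)
                                / (1.5692 * _KO + 3.8115)))
    txk1 = 122.2 / (np.exp(-(v + 127.2) / 20.36) + np.exp((v + 236.8) / 69.33))
    gss[IXK1] = xk1ss
    gtau[IXK1] = txk1
    rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * _KO) / 9.493))
    GK1 = 0.1908 * sc[2]
    IK1 = GK1 * np.sqrt(_KO) * rk1 * y[IXK1] * (v - EK)

    # --- Na+/Ca2+ exchanger -------------------------------------------------
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = np.exp(qca * vfrt)
    hna = np.exp(qna * vfrt)
    # myoplasmic component
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = (nai * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + _NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = _NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + _NAO / kna1 * (1.0 + _NAO / kna2)
    h11 = _NAO * _NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * _CAO * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2_ = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    stot = x1 + x2_ + x3 + x4
    E1 = x1 / stot
    E2 = x2_ / stot
    E3 = x3 / stot
    E4 = x4 / stot
    KmCaAct = 150.0e-6
    allo = 1.0 / (1.0 + (KmCaAct / cai) * (KmCaAct / cai))
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    Gncx = 0.0008 * sc[5]
    INaCa_i = 0.8 * Gncx * allo * (JncxNa + 2.0 * JncxCa)
    # subspace component
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = (nass * hna) / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2_ = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    stot = x1 + x2_ + x3 + x4
    E1 = x1 / stot
    E2 = x2_ / stot
    E3 = x3 / stot
    E4 = x4 / stot
    allo_ss = 1.0 / (1.0 + (KmCaAct / cass) * (KmCaAct / cass))
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo_ss * (JncxNa + 2.0 * JncxCa)

    # --- Na+/K+ ATPase ------------------------------------------------------
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3p_ = 1899.0
    k3m = 79300.0
    k4p_ = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * np.exp(delta * vfrt / 3.0)
    Knao = Knao0 * np.exp((1.0 - delta) * vfrt / 3.0)
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    rnai = nai / Knai
    rnao = _NAO / Knao
    rki = ki / Kki
    rko = _KO / Kko
    d_i = (1.0 + rnai) ** 3 + (1.0 + rki) ** 2 - 1.0
    d_o = (1.0 + rnao) ** 3 + (1.0 + rko) ** 2 - 1.0
    a1 = k1p * rnai ** 3 / d_i
    b1 = k1m * MgADP
    a2 = k2p
    b2 = k2m * rnao ** 3 / d_o
    a3 = k3p_ * rko ** 2 / d_o
    b3 = k3m * P * H / (1.0 + MgATP / Kmgatp)
    a4 = k4p_ * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
    b4 = k4m * rki ** 2 / d_i
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2_ = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    stot = x1 + x2_ + x3 + x4
    E1 = x1 / stot
    E2 = x2_ / stot
    E3 = x3 / stot
    E4 = x4 / stot
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0
    INaK = Pnak * (JnakNa + JnakK)

    # --- background and pump currents --------------------------------------
    xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    GKb = 0.003
    IKb = GKb * xkb * (v - EK)
    if vfrt > 1.0e-7 or vfrt < -1.0e-7:
        ev = np.exp(vfrt)
        INab = 3.75e-10 * vffrt * (nai * ev - _NAO) / (ev - 1.0)
    else:
        INab = 3.75e-10 * _F * (nai - _NAO)
    if x2 > 1.0e-7 or x2 < -1.0e-7:
        ICab = 2.5e-8 * 4.0 * vffrt * (cai * np.exp(x2) - 0.341 * _CAO) / (np.exp(x2) - 1.0)
    else:
        ICab = 2.5e-8 * 2.0 * _F * (cai - 0.341 * _CAO)
    GpCa = 0.0005
    IpCa = GpCa * cai / (0.0005 + cai)

    # --- SR fluxes ----------------------------------------------------------
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    gss[IJRELNP] = Jrel_inf
    gtau[IJRELNP] = tau_rel
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    gss[IJRELP] = Jrel_infp
    gtau[IJRELP] = tau_relp
    fJrelp = fINap
    Jrel = (1.0 - fJrelp) * y[IJRELNP] + fJrelp * y[IJRELP]

    Jupnp = 0.004375 * cai / (cai + 0.00092)
    Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    fJupp = fINap
    Jleak = 0.0039375 * cansr / 15.0
    Jup = sc[6] * ((1.0 - fJupp) * Jupnp + fJupp * Jupp - Jleak)

    Jtr = (cansr - cajsr) / 100.0
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # --- concentration and voltage derivatives ------------------------------
    cmdnmax = 0.05
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    dy[INAI] = (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab)
                * _ACAP / (_F * _VMYO) + JdiffNa * _VSS / _VMYO)
    dy[INASS] = -(ICaNa + 3.0 * INaCa_ss) * _ACAP / (_F * _VSS) - JdiffNa
    dy[IKI] = (-(Ito + IKr + IKs + IK1 + IKb + istim - 2.0 * INaK)
               * _ACAP / (_F * _VMYO) + JdiffK * _VSS / _VMYO)
    dy[IKSS] = -ICaK * _ACAP / (_F * _VSS) - JdiffK
    tcmdn = kmcmdn + cai
    ttrpn = kmtrpn + cai
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (tcmdn * tcmdn)
                  + trpnmax * kmtrpn / (ttrpn * ttrpn))
    dy[ICAI] = Bcai * (-(IpCa + ICab - 2.0 * INaCa_i) * _ACAP / (2.0 * _F * _VMYO)
                       - Jup * _VNSR / _VMYO + Jdiff * _VSS / _VMYO)
    tbsr = KmBSR + cass
    tbsl = KmBSL + cass
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (tbsr * tbsr)
                   + BSLmax * KmBSL / (tbsl * tbsl))
    dy[ICASS] = Bcass * (-(ICaL - 2.0 * INaCa_ss) * _ACAP / (2.0 * _F * _VSS)
                         + Jrel * _VJSR / _VSS - Jdiff)
    dy[ICANSR] = Jup - Jtr * _VJSR / _VNSR
    tcsqn = kmcsqn + cajsr
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (tcsqn * tcsqn))
    dy[ICAJSR] = Bcajsr * (Jtr - Jrel)
    dy[IV] = -(INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
               + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + istim)

    # gate derivatives in relaxation form (used by generic ODE solvers)
    for g in range(GATE_LO, GATE_HI):
        dy[g] = (gss[g] - y[g]) / gtau[g]

    cur[C_INA] = INa
    cur[C_INAL] = INaL
    cur[C_ITO] = Ito
    cur[C_ICAL] = ICaL
    cur[C_ICANA] = ICaNa
    cur[C_ICAK] = ICaK
    cur[C_IKR] = IKr
    cur[C_IKS] = IKs
    cur[C_IK1] = IK1
    cur[C_INACA_I] = INaCa_i
    cur[C_INACA_SS] = INaCa_ss
    cur[C_INAK] = INaK
    cur[C_INAB] = INab
    cur[C_ICAB] = ICab
    cur[C_IKB] = IKb
    cur[C_IPCA] = IpCa
    cur[C_JREL] = Jrel
    cur[C_JUP] = Jup
    cur[C_JLEAK] = Jleak
    cur[C_JTR] = Jtr
    cur[C_JDIFF] = Jdiff
    cur[C_CAMKA] = CaMKa


@njit(cache=True, fastmath=True, error_model="numpy")
def pace(y, bcl, sc, stim_amp, stim_dur, dt_max, dv_max, dt_min,
         rec_v, rec_ca, record):
    """Integrate one pace of length ``bcl`` ms in place.

    Adaptive-step hybrid scheme: gates relax exactly along their exponential
    (Rush-Larsen), concentrations/voltage advance by forward Euler with the
    step limited so |dV| <= dv_max per step and subspace/JSR calcium changes
    by at most 2% per step.  When ``record`` is true, Vm and Cai are sampled
    on the 1 ms output grid (``rec_v[k]`` is the state at t = k ms).
    Returns 0 on success, 1 if the state went non-finite.
    """
    gss = np.empty(N_STATES)
    gtau = np.empty(N_STATES)
    dy = np.empty(N_STATES)
    gss2 = np.empty(N_STATES)
    gtau2 = np.empty(N_STATES)
    dy2 = np.empty(N_STATES)
    yp = np.empty(N_STATES)
    cur = np.empty(N_CURRENTS)
    t = 0.0
    k = 0
    if record:
        rec_v[0] = y[IV]
        rec_ca[0] = y[ICAI]
        k = 1
    nrec = rec_v.shape[0]
    while t < bcl - 1.0e-9:
        istim = stim_amp if t < stim_dur - 1.0e-9 else 0.0
        derivs(y, sc, istim, gss, gtau, dy, cur)
        dt = dt_max
        advdt = abs(dy[IV])
        if advdt * dt > dv_max:
            dt = dv_max / advdt
        acass = abs(dy[ICASS])
        if acass * dt > 0.04 * y[ICASS]:
            dt = 0.04 * y[ICASS] / acass
        acajsr = abs(dy[ICAJSR])
        if acajsr * dt > 0.04 * y[ICAJSR]:
            dt = 0.04 * y[ICAJSR] / acajsr
        if dt < dt_min:
            dt = dt_min
        # never step across the stimulus end, a recording point, or pace end
        bound = bcl
        if t < stim_dur - 1.0e-9 and stim_dur < bound:
            bound = stim_dur
        if record and k < nrec and float(k) < bound:
            bound = float(k)
        if t + dt > bound:
            dt = bound - t
        # predictor (forward Euler / Rush-Larsen)
        for g in range(GATE_LO, GATE_HI):
            yp[g] = gss[g] + (y[g] - gss[g]) * np.exp(-dt / gtau[g])
        yp[IV] = y[IV] + dt * dy[IV]
        for s in range(INAI, ICAJSR + 1):
            yp[s] = y[s] + dt * dy[s]
        yp[ICAMKT] = y[ICAMKT] + dt * dy[ICAMKT]
        # corrector (Heun for non-gates; trapezoidal gate coefficients)
        derivs(yp, sc, istim, gss2, gtau2, dy2, cur)
        for g in range(GATE_LO, GATE_HI):
            ssm = 0.5 * (gss[g] + gss2[g])
            taum = 0.5 * (gtau[g] + gtau2[g])
            y[g] = ssm + (y[g] - ssm) * np.exp(-dt / taum)
        y[IV] += 0.5 * dt * (dy[IV] + dy2[IV])
        for s in range(INAI, ICAJSR + 1):
            y[s] += 0.5 * dt * (dy[s] + dy2[s])
        y[ICAMKT] += 0.5 * dt * (dy[ICAMKT] + dy2[ICAMKT])
        t += dt
        if record and k < nrec and t >= float(k) - 1.0e-9:
            rec_v[k] = y[IV]
            rec_ca[k] = y[ICAI]
            k += 1
    if not np.isfinite(y[IV]):
        return 1
    return 0


@njit(cache=True, fastmath=True, error_model="numpy")
def paced_run(y, bcl, n_paces, sc, stim_amp, stim_dur, dt_max, dv_max, dt_min,
              n_record):
    """Pace ``n_paces`` beats at ``bcl`` (integer ms), recording the last
    ``n_record`` paces on a 1 ms grid.  Returns (vm, cai, status)."""
    nb = int(bcl)
    vm = np.empty(n_record * nb)
    cai = np.empty(n_record * nb)
    dummy = np.empty(1)
    status = 0
    for p in range(n_paces):
        rec = p >= n_paces - n_record
        if rec:
            off = (p - (n_paces - n_record)) * nb
            status = pace(y, float(nb), sc, stim_amp, stim_dur,
                          dt_max, dv_max, dt_min,
                          vm[off:off + nb], cai[off:off + nb], True)
        else:
            status = pace(y, float(nb), sc, stim_amp, stim_dur,
                          dt_max, dv_max, dt_min, dummy, dummy, False)
        if status != 0:
            return vm, cai, status
    return vm, cai, status
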