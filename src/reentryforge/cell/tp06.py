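"""Ten Tusscher–Panfilov (2006) human ventricular ionic model (epicardial
variant) with ischemic modifications.

State vector layout (19 variables, model-native units: mV, ms, mM,
dimensionless gates):

====  =========  ============================================
idx   name       meaning
====  =========  ============================================
0     V          membrane voltage, mV
1-3   m, h, j    fast Na+ current gates
4-5   xr1, xr2   rapid delayed rectifier gates
6     xs         slow delayed rectifier gate
7-8   r, s       transient outward gates
9-11  d, f, f2   L-type Ca2+ current gates
12    fcass      Ca2+-dependent ICaL inactivation gate
13    Rq         SR release adaptation variable
14    Cai        cytosolic free Ca2+, mM
15    CaSR       sarcoplasmic-reticulum Ca2+, mM
16    CaSS       subspace Ca2+, mM
17    Nai        intracellular Na+, mM
18    Ki         intracellular K+, mM
====  =========  ============================================

Ischemic remodeling knobs (all per cell):

* ``ina_scale`` / ``ical_scale`` multiply the fast Na+ and L-type Ca2+
  conductances (border zone 0.8, core 0.7);
* ``K_o`` elevates extracellular potassium (7.5 -> 10 mM across layers),
  entering every K+ Nernst potential and the K_o-dependent conductance
  factors;
* an ATP-sensitive K+ current
  ``I_KATP = g_KATP * f_ATP * (K_o/5.4)**0.24 * (V - E_K)``
  (Ferrero-type formulation) is added, with ``f_ATP`` the open-channel
  fraction. ``G_KATP_REF`` was calibrated once so that f_ATP = 0.0049 at
  normal K_o shortens the healthy epicardial APD90 by roughly 15-20%.

A steep-restitution parameter preset (maximum S1S2 restitution slope near
1.8) modifies G_Kr, G_Ks, G_pCa and G_pK following the published
restitution-variant settings of the model; a multiplier on the ICaL f-gate
time constant is exposed as an additional knob.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = ["CellParams", "STATE_NAMES", "N_STATE", "initial_state",
           "cell_derivatives", "step_cells", "G_KATP_REF"]

STATE_NAMES = ("V", "m", "h", "j", "xr1", "xr2", "xs", "r", "s",
               "d", "f", "f2", "fcass", "Rq", "Cai", "CaSR", "CaSS",
               "Nai", "Ki")
N_STATE = 19
N_GATES = 12  # indices 1..12 updated by Rush-Larsen

# Physical constants
_R = 8314.472      # mJ/(mol K)
_T = 310.0         # K
_F = 96485.3415    # C/mol
_RTONF = _R * _T / _F

# KATP reference conductance (nS/pF scale of the model), calibrated so
# f_ATP = 0.0049 shortens healthy APD90 by ~15-20% at K_o = 5.4 mM.
G_KATP_REF = 1.5


@dataclass
class CellParams:
    """Ionic parameter set, healthy by default (epicardial).

    ``g_kr``, ``g_ks``, ``g_pca``, ``g_pk`` and ``tau_f_mult`` are the
    restitution-variant knobs; the remaining fields are the ischemic
    remodeling knobs."""

    K_o: float = 5.4            # mM
    ina_scale: float = 1.0
    ical_scale: float = 1.0
    f_ATP: float = 0.0
    g_katp_max: float = G_KATP_REF
    g_kr: float = 0.153
    g_ks: float = 0.392
    g_pca: float = 0.1238
    g_pk: float = 0.0146
    tau_f_mult: float = 1.0
    restitution_variant: str = "baseline"

    def __post_init__(self):
        if not (0 < self.ina_scale <= 1 and 0 < self.ical_scale <= 1):
            raise ValueError("current scales must be in (0, 1]")
        if not (0 <= self.f_ATP <= 1):
            raise ValueError(f"f_ATP must be in [0, 1], got {self.f_ATP}")
        if not (4.0 <= self.K_o <= 12.0):
            raise ValueError(f"K_o must be in [4, 12] mM, got {self.K_o}")

    @classmethod
    def healthy(cls) -> "CellParams":
        return cls()

    @classmethod
    def steep_restitution(cls) -> "CellParams":
        """Parameter preset with maximum APD restitution slope near 1.8."""
        return cls(g_kr=0.172, g_ks=0.441, g_pca=0.8666, g_pk=0.00219,
                   restitution_variant="steep")

    def with_ischemia(self, K_o: float, ina_scale: float, ical_scale: float,
                      f_ATP: float) -> "CellParams":
        return replace(self, K_o=K_o, ina_scale=ina_scale,
                       ical_scale=ical_scale, f_ATP=f_ATP)

    def as_tissue_arrays(self, n: int):
        """Broadcast the per-cell knobs into arrays of length n."""
        return (np.full(n, self.K_o), np.full(n, self.ina_scale),
                np.full(n, self.ical_scale), np.full(n, self.f_ATP))

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh,
                           sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CellParams":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def initial_state() -> np.ndarray:
    """Published resting initial conditions of the epicardial variant."""
    y = np.zeros(N_STATE)
    y[0] = -86.2       # V
    y[1] = 0.0         # m
    y[2] = 0.75        # h
    y[3] = 0.75        # j
    y[4] = 0.0         # xr1
    y[5] = 1.0         # xr2
    y[6] = 0.0         # xs
    y[7] = 0.0         # r
    y[8] = 1.0         # s
    y[9] = 0.0         # d
    y[10] = 1.0        # f
    y[11] = 1.0        # f2
    y[12] = 1.0        # fcass
    y[13] = 1.0        # Rq
    y[14] = 0.00007    # Cai
    y[15] = 1.3        # CaSR
    y[16] = 0.00007    # CaSS
    y[17] = 7.67       # Nai
    y[18] = 138.3      # Ki
    return y


@njit(cache=False, fastmath=False)
def _core(y, Ko, ina_scale, ical_scale, fatp, gkatp,
          gkr, gks, gpca, gpk, taufm, istim, inf, tau, dot):
    """Fill gate (inf, tau) pairs and non-gate time derivatives.

    ``inf``/``tau`` have length 12 (gates, state indices 1..12); ``dot``
    has length 7 for (V, Rq, Cai, CaSR, CaSS, Nai, Ki). Returns the total
    ionic current (pA/pF) for diagnostics."""
    V = y[0]
    m = y[1]; h = y[2]; j = y[3]
    xr1 = y[4]; xr2 = y[5]; xs = y[6]
    r = y[7]; s = y[8]
    d = y[9]; f = y[10]; f2 = y[11]; fcass = y[12]
    Rq = y[13]
    Cai = y[14]; CaSR = y[15]; CaSS = y[16]
    Nai = y[17]; Ki = y[18]

    # Fixed model constants (epicardial)
    Nao = 140.0; Cao = 2.0
    Gna = 14.838; Gcal = 0.0000398; Gto = 0.294; GK1 = 5.405
    pKNa = 0.03
    knak = 2.724; KmK = 1.0; KmNa = 40.0
    knaca = 1000.0; KmNai = 87.5; KmCa = 1.38; ksat = 0.1; gam = 0.35
    GbNa = 0.00029; GbCa = 0.000592
    KpCa = 0.0005
    Vmaxup = 0.006375; Kup = 0.00025
    Vrel = 0.102; k1p = 0.15; k2p = 0.045; k3 = 0.060; k4 = 0.005
    EC = 1.5; maxsr = 2.5; minsr = 1.0
    Vleak = 0.00036; Vxfer = 0.0038
    Bufc = 0.2; Kbufc = 0.001
    Bufsr = 10.0; Kbufsr = 0.3
    Bufss = 0.4; Kbufss = 0.00025
    Vc = 0.016404; Vsr = 0.001094; Vss = 0.00005468
    Cm = 0.185

    Ek = _RTONF * np.log(Ko / Ki)
    Ena = _RTONF * np.log(Nao / Nai)
    Eks = _RTONF * np.log((Ko + pKNa * Nao) / (Ki + pKNa * Nai))
    Eca = 0.5 * _RTONF * np.log(Cao / Cai)

    # --- currents ------------------------------------------------------
    INa = ina_scale * Gna * m ** 3 * h * j * (V - Ena)

    vf = (V - 15.0) * _F / (_R * _T)
    if abs(vf) < 1e-7:
        # L'Hopital limit of the GHK-type driving term
        ICaL = ical_scale * Gcal * d * f * f2 * fcass * 2.0 * _F * (
            0.25 * CaSS - Cao) * (1.0 + vf)
    else:
        ICaL = (ical_scale * Gcal * d * f * f2 * fcass * 4.0 * (V - 15.0)
                * _F * _F / (_R * _T)
                * (0.25 * CaSS * np.exp(2.0 * vf) - Cao)
                / (np.exp(2.0 * vf) - 1.0))

    Ito = Gto * r * s * (V - Ek)
    sqko = np.sqrt(Ko / 5.4)
    IKr = gkr * sqko * xr1 * xr2 * (V - Ek)
    IKs = gks * xs * xs * (V - Eks)

    Ak1 = 0.1 / (1.0 + np.exp(0.06 * (V - Ek - 200.0)))
    Bk1 = ((3.0 * np.exp(0.0002 * (V - Ek + 100.0))
            + np.exp(0.1 * (V - Ek - 10.0)))
           / (1.0 + np.exp(-0.5 * (V - Ek))))
    IK1 = GK1 * sqko * Ak1 / (Ak1 + Bk1) * (V - Ek)

    vfrt = V * _F / (_R * _T)
    INaCa = (knaca
             * (np.exp(gam * vfrt) * Nai ** 3 * Cao
                - np.exp((gam - 1.0) * vfrt) * Nao ** 3 * Cai * 2.5)
             / ((KmNai ** 3 + Nao ** 3) * (KmCa + Cao)
                * (1.0 + ksat * np.exp((gam - 1.0) * vfrt))))
    INaK = (knak * Ko / (Ko + KmK) * Nai / (Nai + KmNa)
            / (1.0 + 0.1245 * np.exp(-0.1 * vfrt)
               + 0.0353 * np.exp(-vfrt)))
    IpCa = gpca * Cai / (KpCa + Cai)
    IpK = gpk * (V - Ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    IbNa = GbNa * (V - Ena)
    IbCa = GbCa * (V - Eca)

    # ATP-sensitive K+ current (ischemia)
    IKatp = gkatp * fatp * (Ko / 5.4) ** 0.24 * (V - Ek)

    Iion = (IK1 + Ito + IKr + IKs + ICaL + INaK + INa + IbNa + INaCa
            + IbCa + IpK + IpCa + IKatp)

    # --- gate kinetics -------------------------------------------------
    # m
    inf[0] = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    bm = (0.1 / (1.0 + np.exp((V + 35.0) / 5.0))
          + 0.10 / (1.0 + np.exp((V - 50.0) / 200.0)))
    tau[0] = am * bm
    # h
    inf[1] = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V < -40.0:
        ah = 0.057 * np.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.3485 * V)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    tau[1] = 1.0 / (ah + bh)
    # j
    inf[2] = inf[1]
    if V < -40.0:
        aj = ((-2.5428e4 * np.exp(0.2444 * V)
               - 6.948e-6 * np.exp(-0.04391 * V)) * (V + 37.78)
              / (1.0 + np.exp(0.311 * (V + 79.23))))
        bj = (0.02424 * np.exp(-0.01052 * V)
              / (1.0 + np.exp(-0.1378 * (V + 40.14))))
    else:
        aj = 0.0
        bj = (0.6 * np.exp(0.057 * V)
              / (1.0 + np.exp(-0.1 * (V + 32.0))))
    tau[2] = 1.0 / (aj + bj)
    # xr1
    inf[3] = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tau[3] = axr1 * bxr1
    # xr2
    inf[4] = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau[4] = axr2 * bxr2
    # xs
    inf[5] = 1.0 / (1.0 + np.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    tau[5] = axs * bxs + 80.0
    # r
    inf[6] = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau[6] = 9.5 * np.exp(-(V + 40.0) ** 2 / 1800.0) + 0.8
    # s (epicardial)
    inf[7] = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
    tau[7] = (85.0 * np.exp(-(V + 45.0) ** 2 / 320.0)
              + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0)) + 3.0)
    # d
    inf[8] = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tau[8] = ad * bd + gd
    # f (restitution variant scales tau_f)
    inf[9] = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau[9] = taufm * (1102.5 * np.exp(-(V + 27.0) ** 2 / 225.0)
                      + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
                      + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0)) + 20.0)
    # f2
    inf[10] = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau[10] = (562.0 * np.exp(-(V + 27.0) ** 2 / 240.0)
               + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
               + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0)))
    # fcass
    inf[11] = 0.6 / (1.0 + (CaSS / 0.05) ** 2) + 0.4
    tau[11] = 80.0 / (1.0 + (CaSS / 0.05) ** 2) + 2.0

    # --- calcium dynamics ---------------------------------------------
    kCaSR = maxsr - (maxsr - minsr) / (1.0 + (EC / CaSR) ** 2)
    k1 = k1p / kCaSR
    k2 = k2p * kCaSR
    O = k1 * CaSS ** 2 * Rq / (k3 + k1 * CaSS ** 2)
    Irel = Vrel * O * (CaSR - CaSS)
    Ileak = Vleak * (CaSR - Cai)
    Iup = Vmaxup / (1.0 + Kup ** 2 / Cai ** 2)
    Ixfer = Vxfer * (CaSS - Cai)

    bufc = 1.0 / (1.0 + Bufc * Kbufc / (Cai + Kbufc) ** 2)
    bufsr = 1.0 / (1.0 + Bufsr * Kbufsr / (CaSR + Kbufsr) ** 2)
    bufss = 1.0 / (1.0 + Bufss * Kbufss / (CaSS + Kbufss) ** 2)

    dot[0] = -(Iion + istim)                                   # V
    dot[1] = k4 * (1.0 - Rq) - k2 * CaSS * Rq                  # Rq
    dot[2] = bufc * ((Ileak - Iup) * Vsr / Vc + Ixfer
                     - (IbCa + IpCa - 2.0 * INaCa)
                     * Cm / (2.0 * Vc * _F))                   # Cai
    dot[3] = bufsr * (Iup - Irel - Ileak)                      # CaSR
    dot[4] = bufss * (-ICaL * Cm / (2.0 * Vss * _F)
                      + Irel * Vsr / Vss - Ixfer * Vc / Vss)   # CaSS
    dot[5] = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa) * Cm / (Vc * _F)
    dot[6] = -(istim + IK1 + Ito + IKr + IKs + IKatp - 2.0 * INaK
               + IpK) * Cm / (Vc * _F)                         # Ki
    return Iion


@njit(cache=False)
def _step_kernel(states, n_sub, dt, Ko, ina, ical, fatp, gkatp,
                 gkr, gks, gpca, gpk, taufm, istim):
    """Advance all cells by n_sub Rush-Larsen/Euler steps of dt, in place."""
    n = states.shape[0]
    inf = np.empty(12)
    tau = np.empty(12)
    dot = np.empty(7)
    other_idx = np.array([0, 13, 14, 15, 16, 17, 18])
    for c in range(n):
        y = states[c]
        for _ in range(n_sub):
            _core(y, Ko[c], ina[c], ical[c], fatp[c], gkatp,
                  gkr, gks, gpca, gpk, taufm, istim[c], inf, tau, dot)
            for g in range(12):
                v = inf[g] + (y[1 + g] - inf[g]) * np.exp(-dt / tau[g])
                if v < 0.0:
                    v = 0.0
                elif v > 1.0:
                    v = 1.0
                y[1 + g] = v
            for k in range(7):
                y[other_idx[k]] += dt * dot[k]
    return states


def cell_derivatives(state: np.ndarray, params: CellParams,
                     I_stim: float = 0.0) -> np.ndarray:
    """Full time derivative of the 19-variable state (forward form).

    Gate derivatives are ``(x_inf - x) / tau_x``; concentrations and
    voltage use the current-balance equations. ``I_stim`` is in pA/pF
    (negative = depolarizing)."""
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATE,) or not np.all(np.isfinite(y)):
        raise ValueError("state must be a finite vector of length "
                         f"{N_STATE}")
    inf = np.empty(12)
    tau = np.empty(12)
    dot = np.empty(7)
    _core(y, params.K_o, params.ina_scale, params.ical_scale,
          params.f_ATP, params.g_katp_max, params.g_kr, params.g_ks,
          params.g_pca, params.g_pk, params.tau_f_mult, I_stim,
          inf, tau, dot)
    dy = np.empty(N_STATE)
    dy[1:13] = (inf - y[1:13]) / tau
    dy[[0, 13, 14, 15, 16, 17, 18]] = dot
    return dy


def step_cells(states: np.ndarray, dt: float, params: CellParams,
               Ko=None, ina=None, ical=None, fatp=None,
               istim=None, n_sub: int = 1) -> np.ndarray:
    """Advance an (n_cells, 19) state array in place.

    Per-cell ischemia arrays default to the uniform values in ``params``;
    gates use Rush-Larsen updates, voltage and concentrations forward
    Euler. Raises on numerical blow-up (|V| > 200 mV)."""
    n = states.shape[0]
    if Ko is None:
        Ko, ina, ical, fatp = params.as_tissue_arrays(n)
    if istim is None:
        istim = np.zeros(n)
    _step_kernel(states, n_sub, dt, Ko, ina, ical, fatp,
                 params.g_katp_max, params.g_kr, params.g_ks,
                 params.g_pca, params.g_pk, params.tau_f_mult, istim)
    vmax = np.abs(states[:, 0]).max()
    if not np.isfinite(vmax) or vmax > 200.0:
        raise FloatingPointError(
            f"numerical blow-up: max |V| = {vmax:.1f} mV")
    return states


def nernst_potassium(K_o: float, K_i: float) -> float:
    """Potassium Nernst potential (mV) at 37 C."""
    return _RTONF * np.log(K_o / K_i)
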