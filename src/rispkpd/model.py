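"""Deterministic core of the PBPK-PD model: state layout, dose expansion,
ODE right-hand side and state-derived observables.

State vector (length 18), all drug amounts in nmol per kg body weight,
bound-receptor states in nM:

====  ==========  =================================================
idx   name        meaning
====  ==========  =================================================
0     A_dep_R     SC depot, risperidone
1     A_c_R       plasma central, risperidone
2     A_p_R       plasma peripheral, risperidone
3     A_bv_R      brain vascular, risperidone
4     A_ev_R      brain extra-vascular (residual), risperidone
5     A_st_R      striatum free, risperidone
6     A_cx_R      frontal-cortex free, risperidone
7-13  ..._P       the same seven states for paliperidone
14    B_st_R      D2-bound risperidone concentration (nM)
15    B_st_P      D2-bound paliperidone concentration (nM)
16    B_cx_R      5-HT2A-bound risperidone concentration (nM)
17    B_cx_P      5-HT2A-bound paliperidone concentration (nM)
====  ==========  =================================================

Only unbound drug crosses the blood-brain barrier and binds: the vascular
side contributes fu_plasma * C_bv, parenchymal sides fu_brain * C. Plasma <->
brain-vascular exchange at cerebral blood flow operates on total
concentrations. Active efflux moves unbound drug from the extra-vascular
compartment back to the vascular compartment, linearly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .params import ModelParameters

__all__ = [
    "DoseEvent",
    "InputSchedule",
    "N_STATES",
    "STATE_NAMES",
    "dose_to_inputs",
    "combine_schedules",
    "ode_rhs",
    "pack_params",
    "receptor_occupancy_from_state",
    "brain_concentration",
    "unit_convert",
]

N_STATES = 18

STATE_NAMES = (
    "A_dep_R", "A_c_R", "A_p_R", "A_bv_R", "A_ev_R", "A_st_R", "A_cx_R",
    "A_dep_P", "A_c_P", "A_p_P", "A_bv_P", "A_ev_P", "A_st_P", "A_cx_P",
    "B_st_R", "B_st_P", "B_cx_R", "B_cx_P",
)

IDX = {name: i for i, name in enumerate(STATE_NAMES)}

ROUTES = ("IV", "IP", "SC")
DRUGS = ("RIS", "PALI")


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: drug, route, dose (mg/kg) and time (h)."""

    drug: str
    route: str
    amount: float
    time: float = 0.0

    def validate(self, allow_any_route: bool = False) -> "DoseEvent":
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.drug == "PALI" and self.route != "SC" and not allow_any_route:
            raise ValueError(
                f"unsupported combination (PALI, {self.route}): paliperidone "
                "was only dosed subcutaneously; pass allow_any_route=True to "
                "override")
        return self


@dataclass
class InputSchedule:
    """Expanded dose inputs: instantaneous boluses and zero-order windows.

    ``boluses``: list of (time, state index, amount nmol/kg).
    ``zero_order``: list of (t_start, t_end, state index, rate nmol/kg/h).
    """

    boluses: list
    zero_order: list

    def breakpoints(self) -> np.ndarray:
        ts = [b[0] for b in self.boluses]
        for t0, t1, _, _ in self.zero_order:
            ts.extend((t0, t1))
        return np.unique(np.asarray(ts, dtype=float))

    def rates_at(self, t: float) -> np.ndarray:
        """Constant external input-rate vector valid just after time t."""
        r = np.zeros(N_STATES)
        for t0, t1, idx, rate in self.zero_order:
            if t0 <= t < t1:
                r[idx] += rate
        return r

    def bolus_at(self, t: float) -> np.ndarray:
        dy = np.zeros(N_STATES)
        for tb, idx, amt in self.boluses:
            if tb == t:
                dy[idx] += amt
        return dy


def dose_to_inputs(event: DoseEvent, params: ModelParameters,
                   allow_any_route: bool = False) -> InputSchedule:
    """Expand one dose event into bolus additions and zero-order windows.

    IV: full molar dose as a central bolus. IP: central bolus of the
    bioavailable dose, with fraction Fr_FPM of an IP risperidone dose
    appearing as a paliperidone central bolus (first-pass metabolism,
    mole-conserving). SC: zero-order input into the drug's depot at rate
    F_SC * molar dose / DR_SC over [time, time + DR_SC]; the depot drains
    first-order via Ka_SC inside the ODE right-hand side.
    """
    event.validate(allow_any_route=allow_any_route)
    pl = params.plasma
    molar = event.amount * 1e6 / params.mw(event.drug)  # nmol/kg
    d = "R" if event.drug == "RIS" else "P"
    boluses: list = []
    zero_order: list = []
    if event.route == "IV":
        boluses.append((event.time, IDX[f"A_c_{d}"], molar))
    elif event.route == "IP":
        if event.drug == "RIS":
            boluses.append(
                (event.time, IDX["A_c_R"], pl.F_IP * (1.0 - pl.Fr_FPM) * molar))
            boluses.append(
                (event.time, IDX["A_c_P"], pl.F_IP * pl.Fr_FPM * molar))
        else:
            boluses.append((event.time, IDX["A_c_P"], pl.F_IP * molar))
    else:  # SC
        dr = pl.DR_SC_R if d == "R" else pl.DR_SC_P
        rate = pl.F_SC * molar / dr
        zero_order.append((event.time, event.time + dr, IDX[f"A_dep_{d}"], rate))
    return InputSchedule(boluses=boluses, zero_order=zero_order)


def combine_schedules(schedules: Iterable[InputSchedule]) -> InputSchedule:
    boluses: list = []
    zero_order: list = []
    for s in schedules:
        boluses.extend(s.boluses)
        zero_order.extend(s.zero_order)
    return InputSchedule(boluses=boluses, zero_order=zero_order)


# ---------------------------------------------------------------------------
# ODE right-hand side
# ---------------------------------------------------------------------------

def pack_params(params: ModelParameters) -> np.ndarray:
    """Flatten the constants the RHS needs into a float64 vector."""
    ph, pl, br = params.physiological, params.plasma, params.brain
    return np.array([
        pl.V_c_R, pl.V_p_R, pl.V_c_P, pl.V_p_P,
        pl.CL_R, pl.CL_met, pl.CL_P, pl.Q_R, pl.Q_P,
        pl.Ka_SC_R, pl.Ka_SC_P,
        ph.V_bv, ph.V_ev, ph.V_st, ph.V_cx,
        ph.CL_bv, ph.CL_exch,
        br.CL_bev, br.CL_eff_R, br.CL_eff_P,
        ph.fu_plasma_R, ph.fu_brain_R, ph.fu_plasma_P, ph.fu_brain_P,
        br.kon_D2, br.koff_D2, br.Bmax_D2,
        br.kon_5HT2A, br.koff_5HT2A, br.Bmax_5HT2A,
    ], dtype=np.float64)


@njit(cache=True)
def _rhs(t, y, p, r):  # pragma: no cover - exercised via ode_rhs/simulate
    dy = r.copy()
    Vc_R, Vp_R, Vc_P, Vp_P = p[0], p[1], p[2], p[3]
    CL_R, CL_met, CL_P, Q_R, Q_P = p[4], p[5], p[6], p[7], p[8]
    Ka_R, Ka_P = p[9], p[10]
    V_bv, V_ev, V_st, V_cx = p[11], p[12], p[13], p[14]
    CL_bv, CL_exch = p[15], p[16]
    CL_bev, CL_eff_R, CL_eff_P = p[17], p[18], p[19]
    fup_R, fub_R, fup_P, fub_P = p[20], p[21], p[22], p[23]
    kon_D2, koff_D2, Bmax_D2 = p[24], p[25], p[26]
    kon_5, koff_5, Bmax_5 = p[27], p[28], p[29]

    free_D2 = Bmax_D2 - y[14] - y[15]
    free_5 = Bmax_5 - y[16] - y[17]

    for k in range(2):
        o = 7 * k
        if k == 0:
            Vc, Vp, Q, Ka = Vc_R, Vp_R, Q_R, Ka_R
            fup, fub, CL_eff = fup_R, fub_R, CL_eff_R
        else:
            Vc, Vp, Q, Ka = Vc_P, Vp_P, Q_P, Ka_P
            fup, fub, CL_eff = fup_P, fub_P, CL_eff_P

        C_c = y[o + 1] / Vc
        C_p = y[o + 2] / Vp
        C_bv = y[o + 3] / V_bv
        C_ev = y[o + 4] / V_ev
        C_st = y[o + 5] / V_st
        C_cx = y[o + 6] / V_cx
        Cu_bv = fup * C_bv
        Cu_ev = fub * C_ev
        Cu_st = fub * C_st
        Cu_cx = fub * C_cx

        # depot
        dy[o + 0] += -Ka * y[o + 0]
        # central
        dy[o + 1] += (Ka * y[o + 0]
                      - Q * (C_c - C_p)
                      - CL_bv * (C_c - C_bv))
        if k == 0:
            dy[o + 1] += -(CL_R + CL_met) * C_c
        else:
            dy[o + 1] += -CL_P * C_c + CL_met * (y[1] / Vc_R)
        # peripheral
        dy[o + 2] += Q * (C_c - C_p)
        # brain vascular
        dy[o + 3] += (CL_bv * (C_c - C_bv)
                      - CL_bev * (Cu_bv - Cu_ev)
                      + CL_eff * Cu_ev)
        # brain extra-vascular
        dy[o + 4] += (CL_bev * (Cu_bv - Cu_ev)
                      - CL_eff * Cu_ev
                      - CL_exch * (Cu_ev - Cu_st)
                      - CL_exch * (Cu_ev - Cu_cx))
        # striatum free + D2 binding
        bind_st = kon_D2 * Cu_st * free_D2 - koff_D2 * y[14 + k]
        dy[o + 5] += CL_exch * (Cu_ev - Cu_st) - V_st * bind_st
        dy[14 + k] = bind_st
        # cortex free + 5-HT2A binding
        bind_cx = kon_5 * Cu_cx * free_5 - koff_5 * y[16 + k]
        dy[o + 6] += CL_exch * (Cu_ev - Cu_cx) - V_cx * bind_cx
        dy[16 + k] = bind_cx
    return dy


def ode_rhs(t: float, y: np.ndarray, params: ModelParameters,
            schedule: InputSchedule | None = None) -> np.ndarray:
    """State derivative at time ``t``.

    ``schedule`` supplies any zero-order inputs active at ``t``; bolus
    additions are discontinuities handled by the integrator driver, not here.
    Raises if the state has drifted meaningfully negative (integration
    instability signal).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state passed to ode_rhs")
    scale = max(1.0, float(np.max(np.abs(y))))
    if np.min(y) < -1e-6 * scale:
        raise FloatingPointError(
            f"state component negative beyond tolerance at t={t}")
    r = schedule.rates_at(t) if schedule is not None else np.zeros(N_STATES)
    return _rhs(t, y, pack_params(params), r)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def receptor_occupancy_from_state(
        y: np.ndarray, params: ModelParameters) -> tuple:
    """Total (RIS + PALI) D2 and 5-HT2A receptor occupancy in percent.

    Measured occupancy is the sum over both drugs because they compete for
    the same receptor pool. A receptor with Bmax = 0 reports 0% occupancy.
    Accepts a single state vector or an (n, 18) trajectory.
    """
    y = np.asarray(y, dtype=float)
    br = params.brain
    b_d2 = y[..., 14] + y[..., 15]
    b_5 = y[..., 16] + y[..., 17]
    ro_d2 = 100.0 * b_d2 / br.Bmax_D2 if br.Bmax_D2 > 0 else np.zeros_like(b_d2)
    ro_5 = 100.0 * b_5 / br.Bmax_5HT2A if br.Bmax_5HT2A > 0 else np.zeros_like(b_5)
    return ro_d2, ro_5


REGIONS = ("total", "excl_striatum", "excl_cortex", "striatum", "cortex")


def brain_concentration(y: np.ndarray, params: ModelParameters,
                        region: str = "total", drug: str = "RIS") -> np.ndarray:
    """Homogenate brain concentration (nM) for a dissection variant.

    ``excl_striatum`` / ``excl_cortex`` mimic removing the region assayed for
    receptor occupancy before homogenizing the rest of the brain; ``striatum``
    and ``cortex`` are the regional concentrations themselves (free + bound).
    Bound receptor states (nM) enter the numerator as V * B amounts.
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    y = np.asarray(y, dtype=float)
    ph = params.physiological
    o = 0 if drug == "RIS" else 7
    kb = 0 if drug == "RIS" else 1
    A_bv, A_ev = y[..., o + 3], y[..., o + 4]
    A_st, A_cx = y[..., o + 5], y[..., o + 6]
    B_st, B_cx = y[..., 14 + kb], y[..., 16 + kb]
    if region == "striatum":
        return A_st / ph.V_st + B_st
    if region == "cortex":
        return A_cx / ph.V_cx + B_cx
    num = A_bv + A_ev
    den = ph.V_bv + ph.V_ev
    if region in ("total", "excl_cortex"):
        num = num + A_st + ph.V_st * B_st
        den += ph.V_st
    if region in ("total", "excl_striatum"):
        num = num + A_cx + ph.V_cx * B_cx
        den += ph.V_cx
    return num / den


def unit_convert(value, from_unit: str, to_unit: str, mw: float):
    """Exact molar unit conversion via molecular weight (g/mol).

    Supported pairs: mg/kg <-> nmol/kg and nM <-> ng/mL (either direction).
    """
    value = np.asarray(value, dtype=float)
    key = (from_unit, to_unit)
    if key == ("mg/kg", "nmol/kg"):
        out = value * 1e6 / mw
    elif key == ("nmol/kg", "mg/kg"):
        out = value * mw / 1e6
    elif key == ("nM", "ng/mL"):
        out = value * mw / 1000.0
    elif key == ("ng/mL", "nM"):
        out = value * 1000.0 / mw
    elif from_unit == to_unit and from_unit in ("mg/kg", "nmol/kg", "nM", "ng/mL"):
        out = value
    else:
        raise ValueError(f"unsupported unit conversion {from_unit!r} -> {to_unit!r}")
    return out if out.ndim else float(out)
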