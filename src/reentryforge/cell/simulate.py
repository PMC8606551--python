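"""Single-cell pacing, action-potential measurement, and S1S2 restitution.

Conventions: stimulus current is -52 pA/pF for 1 ms (about 2x diastolic
threshold); action-potential duration is measured from the maximum-upstroke
time to the point of 90% (or other level) repolarization toward the
pre-stimulus diastolic voltage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tp06 import CellParams, initial_state, step_cells

__all__ = ["APTrace", "simulate_cell", "apd", "apds", "restitution_slope",
           "RestitutionCurve"]

STIM_AMPLITUDE = -52.0  # pA/pF
STIM_DURATION = 1.0     # ms


@dataclass
class APTrace:
    """Sampled voltage trace with the stimulus schedule that produced it."""

    time: np.ndarray        # ms, strictly increasing
    V: np.ndarray           # mV
    stim_times: np.ndarray  # ms (onsets)
    steady_state: bool = False
    final_state: np.ndarray = None

    def __post_init__(self):
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trace time must be strictly increasing")

    def to_csv(self, path) -> None:
        """Write the trace as `t_ms,V_mV` rows."""
        import pandas as pd
        pd.DataFrame({"t_ms": self.time, "V_mV": self.V}).to_csv(
            path, index=False)


def _run_schedule(state, params, stim_times, t_end, dt, sample_every):
    """Integrate one cell through a stimulus schedule, sampling V."""
    n_steps = int(round(t_end / dt))
    stride = max(int(round(sample_every / dt)), 1)
    stim_steps = [(int(round(t / dt)),
                   int(round((t + STIM_DURATION) / dt)))
                  for t in stim_times]
    times = [0.0]
    volts = [state[0, 0]]
    istim = np.zeros(1)
    step = 0
    events = sorted({0, n_steps}
                    | {a for a, _ in stim_steps} | {b for _, b in stim_steps})
    while step < n_steps:
        nxt = min([e for e in events if e > step] + [n_steps])
        on = any(a <= step < b for a, b in stim_steps)
        istim[0] = STIM_AMPLITUDE if on else 0.0
        while step < nxt:
            n_sub = min(stride - (step % stride) or stride, nxt - step)
            step_cells(state, dt, params, istim=istim, n_sub=n_sub)
            step += n_sub
            if step % stride == 0 or step == n_steps:
                times.append(step * dt)
                volts.append(state[0, 0])
    return np.asarray(times), np.asarray(volts)


def simulate_cell(params: CellParams, cl: float = 1000.0, n_beats: int = 5,
                  dt: float = 0.02, sample_every: float = 0.1,
                  state: np.ndarray | None = None,
                  pre_time: float = 50.0) -> APTrace:
    """Pace a single cell at cycle length ``cl`` for ``n_beats`` beats.

    The cell rests for ``pre_time`` ms before the first stimulus so the
    pre-stimulus diastolic voltage is observable. The trace's
    ``steady_state`` flag is set when the last two beats' APD90 differ by
    less than 1 ms; ``final_state`` stores the end-of-run state vector.
    """
    if dt > 0.05:
        raise ValueError(f"dt must be <= 0.05 ms for Rush-Larsen, got {dt}")
    if state is None:
        state = initial_state()[None, :].copy()
    else:
        state = np.array(state, dtype=float).reshape(1, -1)
    stim_times = pre_time + cl * np.arange(n_beats)
    t_end = pre_time + cl * n_beats
    t, V = _run_schedule(state, params, stim_times, t_end, dt, sample_every)
    trace = APTrace(time=t, V=V, stim_times=stim_times,
                    final_state=state[0].copy())
    if n_beats >= 2:
        try:
            a = apds(trace)
            if len(a) >= 2 and abs(a[-1] - a[-2]) < 1.0:
                trace.steady_state = True
        except ValueError:
            pass
    return trace


def apds(trace: APTrace, repolarization_level: float = 90.0) -> np.ndarray:
    """APD per stimulated beat, in ms.

    For each stimulus: diastolic V is the voltage at stimulus onset, the
    upstroke is the maximum dV/dt after the stimulus, and the AP ends when
    V first repolarizes ``repolarization_level`` percent of the way from
    peak back toward diastolic. Beats without an AP (peak < -20 mV above
    diastole, or never crossing 0 mV upstroke amplitude) are skipped.
    """
    t, V = trace.time, trace.V
    frac = repolarization_level / 100.0
    out = []
    onsets = list(trace.stim_times) + [t[-1] + 1.0]
    for k in range(len(trace.stim_times)):
        lo = np.searchsorted(t, onsets[k])
        hi = np.searchsorted(t, onsets[k + 1])
        if hi - lo < 3:
            continue
        v_dia = V[max(lo - 1, 0)]
        seg_t, seg_v = t[lo:hi], V[lo:hi]
        v_peak = seg_v.max()
        if v_peak - v_dia < 40.0:   # no regenerative upstroke
            continue
        dv = np.diff(seg_v) / np.diff(seg_t)
        i_up = int(np.argmax(dv))
        t_up = seg_t[i_up]
        v_thr = v_peak - frac * (v_peak - v_dia)
        i_peak = int(np.argmax(seg_v))
        below = np.flatnonzero(seg_v[i_peak:] <= v_thr)
        if below.size == 0:
            continue
        i_rep = i_peak + below[0]
        # linear interpolation of the crossing time
        if i_rep > 0 and seg_v[i_rep - 1] > v_thr:
            t0, t1 = seg_t[i_rep - 1], seg_t[i_rep]
            v0, v1 = seg_v[i_rep - 1], seg_v[i_rep]
            t_rep = t0 + (v_thr - v0) / (v1 - v0) * (t1 - t0)
        else:
            t_rep = seg_t[i_rep]
        out.append(t_rep - t_up)
    if not out:
        raise ValueError("no action potential detected in trace")
    return np.asarray(out)


def apd(trace: APTrace, repolarization_level: float = 90.0) -> float:
    """APD of the last stimulated action potential (ms)."""
    return float(apds(trace, repolarization_level)[-1])


@dataclass
class RestitutionCurve:
    di: np.ndarray        # diastolic interval, ms
    apd: np.ndarray       # APD90 of the S2 beat, ms
    max_slope: float


def restitution_slope(params: CellParams, s1_cl: float = 1000.0,
                      di_grid=None, dt: float = 0.02,
                      n_s1: int = 20) -> RestitutionCurve:
    """S1S2 restitution: maximum finite-difference slope d(APD)/d(DI).

    The cell is paced to approximate steady state at ``s1_cl``; from the
    saved end-of-drive state a single S2 is delivered after each diastolic
    interval in ``di_grid`` and its APD90 measured. Grid order does not
    affect the result (each S2 restarts from the same stored state).
    """
    if di_grid is None:
        di_grid = np.array([400.0, 300.0, 200.0, 150.0, 100.0, 80.0, 60.0,
                            50.0, 40.0, 30.0, 25.0, 20.0, 15.0, 10.0, 5.0])
    di_grid = np.asarray(di_grid, dtype=float)

    # Drive for n_s1 - 1 beats; the saved state is due for its next S1
    # exactly at the end of the run.
    drive = simulate_cell(params, cl=s1_cl, n_beats=n_s1 - 1, dt=dt,
                          pre_time=10.0)
    base_state = drive.final_state

    # Reference run: final S1 alone, to locate its upstroke and APD90.
    state = base_state[None, :].copy()
    t, V = _run_schedule(state, params, [0.0], 600.0, dt, 0.1)
    ref = APTrace(time=t, V=V, stim_times=np.array([0.0]))
    apd_s1 = apds(ref)[-1]
    dv = np.diff(ref.V) / np.diff(ref.time)
    t_up = ref.time[int(np.argmax(dv))]
    t_rep = t_up + apd_s1

    di_out, apd_out = [], []
    for di in di_grid:
        t_s2 = t_rep + di
        state = base_state[None, :].copy()
        t, V = _run_schedule(state, params, [0.0, t_s2], t_s2 + 600.0,
                             dt, 0.1)
        tr = APTrace(time=t, V=V, stim_times=np.array([0.0, t_s2]))
        # Full capture requires a regenerative overshoot, not a graded
        # local response.
        if V[np.searchsorted(t, t_s2):].max() <= 0.0:
            continue
        a2 = apds(tr)
        if a2.size < 2:   # S2 failed to capture
            continue
        di_out.append(di)
        apd_out.append(a2[-1])
    if not apd_out:
        raise ValueError("S2 failed to elicit an action potential at "
                         "every diastolic interval")
    di_arr = np.asarray(di_out)
    apd_arr = np.asarray(apd_out)
    order = np.argsort(di_arr)
    di_arr, apd_arr = di_arr[order], apd_arr[order]
    if di_arr.size < 2:
        raise ValueError("need at least two captured S2 beats for a slope")
    slopes = np.diff(apd_arr) / np.diff(di_arr)
    return RestitutionCurve(di=di_arr, apd=apd_arr,
                            max_slope=float(slopes.max()))
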