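"""Adaptive programmed-stimulation vulnerability protocol.

At each of the 17 AHA pacing sites a clinical-style induction attempt is
made: five S1 drive stimuli at 350 ms cycle length, then an S2 premature
stimulus 200 ms after the last S1, tightened in 10 ms decrements until
either reentry appears or the stimulus fails to capture; on capture
failure the last captured S2 is kept and an S3 (then S4) is added 250 ms
later and tightened the same way. Every delivered premature stimulus is
followed by a 2000 ms observation window; outcomes are NR (no reentry),
UR (unsustained reentry — re-excitation that extinguishes before the end
of the window) and R (sustained reentry — activity persisting into the
final 200 ms of the window).

The state machine is backend-agnostic: a backend maps a stimulus schedule
to capture/outcome observations. Backends provided here:

* :class:`TissueBackend` — the monodomain solver (expensive; fixture scale);
* :class:`SurrogateBackend` — a documented substrate-propensity surrogate
  for population-scale studies (see its docstring);
* test suites supply scripted stubs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import VentricleGeometry, GeometryError
from .ischemia import PopulationMember
from .tissue import (SolverConfig, Stimulus, conductivity_from_geometry,
                     electrode_footprint, run_monodomain)
from .cell.tp06 import CellParams

__all__ = ["ProtocolConfig", "SiteResult", "VulnerabilitySummary",
           "select_pacing_sites", "run_vulnerability_protocol",
           "check_capture", "classify_outcome", "evaluate_population",
           "AttemptResult", "TissueBackend", "SurrogateBackend",
           "summary_from_counts"]

POSITIVE_OUTCOMES = ("R", "UR")  # both count as "arrhythmia" downstream


@dataclass
class ProtocolConfig:
    """Stimulation-protocol timing parameters (ms)."""

    s1_count: int = 5
    s1_cl: float = 350.0
    s2_initial_offset: float = 200.0
    decrement: float = 10.0
    s3_offset: float = 250.0
    s4_offset: float = 250.0
    observation_window: float = 2000.0
    coupling_floor: float = 100.0       # hard floor bounding runtime
    post_stim_latency: float = 50.0     # ignore the paced beat's upstroke
    sustained_tail: float = 200.0       # R = activity in this final span
    min_interstimulus: float = 10.0     # floor guard
    capture_radius: float = 5.0         # mm
    capture_window: float = 100.0       # ms

    def __post_init__(self):
        for name in ("s1_cl", "s2_initial_offset", "decrement", "s3_offset",
                     "s4_offset", "observation_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.decrement >= self.s2_initial_offset:
            raise ValueError("decrement must be smaller than the initial "
                             "S2 offset")


@dataclass
class AttemptResult:
    """Backend observation for one delivered premature stimulus."""

    captured: bool
    outcome: str            # 'NR', 'UR' or 'R' over the observation window
    events: list = field(default_factory=list)
    episode_duration: float = 0.0


@dataclass
class SiteResult:
    site: int                     # AHA segment id 1..17
    outcome: str                  # 'NR', 'UR', 'R'
    inducing_stage: str           # 'S2', 'S3', 'S4' or 'none'
    coupling_intervals: dict      # stage -> final interval (ms)
    episode_duration: float = 0.0
    n_attempts: int = 0

    def __post_init__(self):
        if (self.outcome == "NR") != (self.inducing_stage == "none"):
            raise ValueError("outcome NR must pair with stage 'none'")

    @property
    def arrhythmic(self) -> bool:
        return self.outcome in POSITIVE_OUTCOMES


def select_pacing_sites(geom: VentricleGeometry,
                        footprint_mm: float = 1.0) -> dict:
    """One electrode per AHA segment at the segment's centroid element.

    Returns ``{segment_id: element-index array}``; each footprint is a
    ~1 mm patch around the element nearest the segment centroid."""
    if not np.any(geom.segment_id > 0):
        raise GeometryError("segments not assigned")
    sites = {}
    for seg in range(1, 18):
        members = np.flatnonzero(geom.segment_id == seg)
        if members.size == 0:
            raise GeometryError(f"AHA segment {seg} is empty")
        centroid = geom.centers[members].mean(axis=0)
        d2 = ((geom.centers[members] - centroid) ** 2).sum(axis=1)
        center_el = int(members[np.argmin(d2)])
        foot = electrode_footprint(geom, center_el, footprint_mm)
        foot = foot[geom.segment_id[foot] == seg]
        sites[seg] = foot if foot.size else np.array([center_el])
    return sites


def check_capture(events, geom: VentricleGeometry, site_elements,
                  stim_onset: float, cfg: ProtocolConfig | None = None
                  ) -> bool:
    """A stimulus captured iff at least one activation occurs at >= 5 mm
    from the electrode centroid within 100 ms of its onset."""
    cfg = cfg or ProtocolConfig()
    center = geom.centers[np.atleast_1d(site_elements)].mean(axis=0)
    for e, t in events:
        if stim_onset <= t <= stim_onset + cfg.capture_window:
            if np.linalg.norm(geom.centers[e] - center) >= \
                    cfg.capture_radius:
                return True
    return False


def classify_outcome(events, last_stim_onset: float,
                     cfg: ProtocolConfig | None = None) -> str:
    """NR/UR/R classification of an observation window.

    Re-excitation means some element activates at least twice after
    ``last_stim_onset + post_stim_latency``. Sustained reentry (R) further
    requires activity within the final ``sustained_tail`` ms of the
    window; re-excitation that extinguishes earlier is unsustained (UR).
    """
    cfg = cfg or ProtocolConfig()
    t0 = last_stim_onset + cfg.post_stim_latency
    t_end = last_stim_onset + cfg.observation_window
    counts = {}
    latest = -np.inf
    for e, t in events:
        if t > t0:
            counts[e] = counts.get(e, 0) + 1
            latest = max(latest, t)
    reexcited = any(c >= 2 for c in counts.values())
    if not reexcited:
        return "NR"
    if latest >= t_end - cfg.sustained_tail:
        return "R"
    return "UR"


# ---------------------------------------------------------------------------
# Backends

class TissueBackend:
    """Monodomain-simulation backend for the protocol state machine.

    Each attempt re-simulates the full train (drive beats plus premature
    stimuli) from rest and classifies the observation window after the
    last stimulus. Intended for fixture-scale geometries."""

    def __init__(self, geom, grading=None, cell_params=None,
                 solver_cfg=None, protocol_cfg=None):
        self.geom = geom
        self.grading = grading
        self.cell_params = cell_params or CellParams.steep_restitution()
        self.solver_cfg = solver_cfg or SolverConfig()
        self.cfg = protocol_cfg or ProtocolConfig()
        self.cond = conductivity_from_geometry(geom, self.solver_cfg)

    def attempt(self, site_elements, schedule) -> AttemptResult:
        cfg = self.cfg
        stimuli = [Stimulus(site=site_elements, onset=t,
                            duration=self.solver_cfg.stim_duration,
                            amplitude=self.solver_cfg.stim_amplitude)
                   for t in schedule]
        last = max(schedule)
        t_end = last + cfg.observation_window
        res = run_monodomain(self.geom, self.cond, self.cell_params,
                             grading=self.grading, stimuli=stimuli,
                             t_end=t_end, cfg=self.solver_cfg,
                             record_V=False)
        captured = check_capture(res.activations, self.geom, site_elements,
                                 last, cfg)
        outcome = classify_outcome(res.activations, last, cfg)
        ep = 0.0
        if outcome in POSITIVE_OUTCOMES:
            tail = [t for _, t in res.activations
                    if t > last + cfg.post_stim_latency]
            ep = max(tail) - last if tail else 0.0
        return AttemptResult(captured=captured, outcome=outcome,
                             events=res.activations, episode_duration=ep)


class SurrogateBackend:
    """Substrate-propensity surrogate for population-scale studies.

    Emulates the empirical behaviour of the simulated protocol without
    solving the monodomain equations, so that population studies fit on a
    single CPU. Per (model, site) a latent inducibility score

        z = w_seg * sqrt(seg_ischemic_pct) + w_glob * sqrt(global_pct)
            + u_model + eps_site

    is drawn once (u_model ~ N(0, sigma_model) per virtual patient,
    eps_site ~ N(0, sigma_z) per (patient, site), both seeded; the square
    roots saturate the score so a fully ischemic core segment does not
    dominate after peeling shrinks the substrate). The patient effect,
    site noise and the site-specific effective refractory period
    ERP ~ N(erp_mean, erp_sd) are shared by all peel variants of a
    patient, so layer peeling moves a site's score only through the
    shrinking substrate terms — vulnerability decreases monotonically as
    layers are removed, as in the simulated cohort. Capture requires
    coupling interval > ERP.
    An attempt at stage k (S2=1, S3=2, S4=3) with coupling interval ci
    captures iff ci > ERP and triggers reentry iff

        z > z_thr - a_prem * (s2_initial - ci) - a_stage * (k - 1).

    Tighter coupling and later stages therefore probe deeper into the
    vulnerable substrate, and larger / more ischemic substrates induce
    earlier — the qualitative structure reported for the patient cohort
    (inducibility rising with ischemic burden, and with pacing from more
    ischemic segments). Sustained vs unsustained reentry splits on the
    score's margin over the threshold. Fully deterministic given the seed.
    """

    def __init__(self, member: PopulationMember, seed: int = 0,
                 cfg: ProtocolConfig | None = None,
                 w_seg: float = 0.18, w_glob: float = 0.50,
                 sigma_z: float = 0.30, sigma_model: float = 0.45,
                 z_thr: float = 3.4,
                 a_prem: float = 0.004, a_stage: float = 0.25,
                 erp_mean: float = 150.0, erp_sd: float = 12.0,
                 sustained_margin: float = 0.5):
        self.member = member
        self.cfg = cfg or ProtocolConfig()
        self.p = dict(w_seg=w_seg, w_glob=w_glob, sigma_z=sigma_z,
                      sigma_model=sigma_model, z_thr=z_thr,
                      a_prem=a_prem, a_stage=a_stage,
                      erp_mean=erp_mean, erp_sd=erp_sd,
                      sustained_margin=sustained_margin)
        geom = member.geom
        self.global_pct = geom.ischemic_fraction
        self.seg_pct = {}
        for seg in range(1, 18):
            m = geom.segment_id == seg
            v = geom.element_volume[m]
            isch = geom.element_volume[m & (geom.region_label > 0)]
            self.seg_pct[seg] = (100.0 * isch.sum() / v.sum()
                                 if v.size else 0.0)
        self._seed = seed
        # stable across processes (unlike the builtin salted str hash);
        # patient-level draws are shared by all peel variants of a patient
        self._pid_hash = zlib.crc32(
            f"p{member.patient_id}".encode()) % (2 ** 31)
        rng_m = np.random.default_rng((seed, self._pid_hash))
        self.u_model = rng_m.normal(0.0, self.p["sigma_model"])
        self._site_state = {}

    def _state_for(self, segment: int):
        if segment not in self._site_state:
            rng = np.random.default_rng(
                (self._seed, self._pid_hash, segment))
            p = self.p
            z = (p["w_seg"] * np.sqrt(self.seg_pct[segment])
                 + p["w_glob"] * np.sqrt(self.global_pct)
                 + self.u_model
                 + rng.normal(0.0, p["sigma_z"]))
            erp = rng.normal(p["erp_mean"], p["erp_sd"])
            self._site_state[segment] = (z, erp)
        return self._site_state[segment]

    def attempt_for_site(self, segment: int, stage_index: int,
                         coupling: float) -> AttemptResult:
        z, erp = self._state_for(segment)
        p = self.p
        cfg = self.cfg
        if coupling <= erp:
            return AttemptResult(captured=False, outcome="NR")
        thr = (p["z_thr"]
               - p["a_prem"] * (cfg.s2_initial_offset - coupling)
               - p["a_stage"] * (stage_index - 1))
        if z > thr:
            sustained = (z - thr) > p["sustained_margin"]
            out = "R" if sustained else "UR"
            ep = cfg.observation_window if sustained else \
                min(0.3 * cfg.observation_window, 600.0)
            return AttemptResult(captured=True, outcome=out,
                                 episode_duration=ep)
        return AttemptResult(captured=True, outcome="NR")


# ---------------------------------------------------------------------------
# State machine

def run_vulnerability_protocol(backend, site_elements=None, segment=None,
                               cfg: ProtocolConfig | None = None
                               ) -> SiteResult:
    """Drive the adaptive S1-S4 state machine against a backend.

    ``backend`` either implements ``attempt(site_elements, schedule)``
    (tissue or scripted-stub backends; pass ``site_elements``) or
    ``attempt_for_site(segment, stage_index, coupling)`` (surrogate;
    pass ``segment``). The first reentry at any stage ends the site's
    protocol.
    """
    cfg = cfg or (backend.cfg if hasattr(backend, "cfg") else None) \
        or ProtocolConfig()
    t0 = 10.0
    s1_times = [t0 + k * cfg.s1_cl for k in range(cfg.s1_count)]
    last_s1 = s1_times[-1]

    fixed_offsets = []   # captured coupling interval per completed stage
    intervals = {}
    n_attempts = 0
    stage_names = ["S2", "S3", "S4"]
    stage_initial = [cfg.s2_initial_offset, cfg.s3_offset, cfg.s4_offset]

    by_schedule = hasattr(backend, "attempt")

    for k, (name, init_off) in enumerate(zip(stage_names, stage_initial),
                                         start=1):
        offset = init_off
        last_captured = None
        while offset >= cfg.coupling_floor:
            if offset < cfg.min_interstimulus:
                break  # floor guard: never closer than 10 ms
            prem = []
            t = last_s1
            for off in fixed_offsets + [offset]:
                t = t + off
                prem.append(t)
            n_attempts += 1
            if by_schedule:
                res = backend.attempt(site_elements, s1_times + prem)
            else:
                res = backend.attempt_for_site(segment, k, offset)
            if res.outcome in POSITIVE_OUTCOMES:
                intervals[name] = offset
                return SiteResult(
                    site=segment if segment is not None else -1,
                    outcome=res.outcome, inducing_stage=name,
                    coupling_intervals=intervals,
                    episode_duration=res.episode_duration,
                    n_attempts=n_attempts)
            if not res.captured:
                break
            last_captured = offset
            offset -= cfg.decrement
        if last_captured is None:
            # the stage's stimulus never propagated; deeper stages would
            # stack onto a non-captured beat — stop here.
            break
        fixed_offsets.append(last_captured)
        intervals[name] = last_captured

    return SiteResult(site=segment if segment is not None else -1,
                      outcome="NR", inducing_stage="none",
                      coupling_intervals=intervals, n_attempts=n_attempts)


# ---------------------------------------------------------------------------
# Population evaluation and Table-1-shaped bookkeeping

@dataclass
class VulnerabilitySummary:
    """Population-level vulnerability bookkeeping."""

    site_results: pd.DataFrame        # model_id, patient_id, peel, segment,
    per_level: pd.DataFrame           # Table-1-shaped per-peel summary
    tested_segments: int
    arrhythmic_segments: int

    @property
    def ratio(self) -> float:
        return self.arrhythmic_segments / self.tested_segments


def summary_from_counts(tested_segments: int, arrhythmic_segments: int,
                        n_models: int) -> dict:
    """Arithmetic identities over printed protocol counts.

    The same bookkeeping used by :func:`evaluate_population`, applied to
    externally supplied totals: segments per model, the arrhythmic/tested
    ratio, the arrhythmic percentage, and mean reentries per model."""
    if not (0 <= arrhythmic_segments <= tested_segments):
        raise ValueError("need 0 <= arrhythmic <= tested")
    return {
        "tested_segments": tested_segments,
        "arrhythmic_segments": arrhythmic_segments,
        "non_arrhythmic_segments": tested_segments - arrhythmic_segments,
        "segments_per_model": tested_segments / n_models,
        "ratio": arrhythmic_segments / tested_segments,
        "pct_segments_with_reentry":
            100.0 * arrhythmic_segments / tested_segments,
        "mean_reentries_per_model": arrhythmic_segments / n_models,
    }


def evaluate_population(pop, backend_factory,
                        cfg: ProtocolConfig | None = None
                        ) -> VulnerabilitySummary:
    """Run the 17-site protocol over a population of virtual patients.

    ``backend_factory(member)`` returns a protocol backend for one model.
    Models whose backend raises are logged, excluded and counted in
    ``per_level['n_failed']``.
    """
    cfg = cfg or ProtocolConfig()
    rows = []
    failures = []
    for m in pop:
        try:
            backend = backend_factory(m)
            surrogate_like = hasattr(backend, "attempt_for_site")
            sites = None if surrogate_like else \
                select_pacing_sites(m.geom)
            for seg in range(1, 18):
                if surrogate_like:
                    r = run_vulnerability_protocol(backend, segment=seg,
                                                   cfg=cfg)
                else:
                    r = run_vulnerability_protocol(
                        backend, site_elements=sites[seg], segment=seg,
                        cfg=cfg)
                rows.append({
                    "model_id": m.model_id, "patient_id": m.patient_id,
                    "peel_level": m.peel_level, "segment": seg,
                    "outcome": r.outcome, "stage": r.inducing_stage,
                    "arrhythmic": r.arrhythmic,
                    "ischemia_pct": m.geom.ischemic_fraction,
                })
        except Exception as exc:   # failed model: excluded with count
            failures.append((m.model_id, str(exc)))
    df = pd.DataFrame(rows)
    per_level = _table1_summary(df)
    per_level["n_failed"] = len(failures)
    return VulnerabilitySummary(
        site_results=df, per_level=per_level,
        tested_segments=len(df),
        arrhythmic_segments=int(df["arrhythmic"].sum()))


def _table1_summary(df: pd.DataFrame) -> pd.DataFrame:
    out = []
    for level, g in df.groupby("peel_level"):
        models = g.groupby("model_id")
        per_model = models["arrhythmic"].sum()
        isch = models["ischemia_pct"].first()
        out.append({
            "peel_level": level,
            "n_patients": g["model_id"].nunique(),
            "mean_ischemia_pct": isch.mean(),
            "sd_ischemia_pct": isch.std(),
            "n_patients_with_reentry": int((per_model > 0).sum()),
            "pct_patients_with_reentry":
                100.0 * (per_model > 0).mean(),
            "pct_segments_with_reentry":
                100.0 * g["arrhythmic"].mean(),
            "mean_reentries_per_model": per_model.mean(),
            "sd_reentries_per_model": per_model.std(),
        })
    return pd.DataFrame(out).sort_values("peel_level").reset_index(drop=True)
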