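"""Protocol state machine, capture/outcome classification, population
bookkeeping — exercised against scripted stub simulators."""

import numpy as np
import pandas as pd
import pytest

from reentryforge import (ProtocolConfig, SiteResult, check_capture,
                          classify_outcome, evaluate_population,
                          run_vulnerability_protocol, select_pacing_sites,
                          summary_from_counts)
from reentryforge.geometry import GeometryError
from reentryforge.protocol import AttemptResult


class ScriptedBackend:
    """Stub simulator: behaviour is a function of (stage, coupling).

    ``script`` maps (stage_name, coupling) to one of 'NR', 'UR', 'R',
    'nocapture'; unlisted attempts capture with no reentry."""

    def __init__(self, script, cfg=None):
        self.script = script
        self.cfg = cfg or ProtocolConfig()
        self.log = []

    def attempt_for_site(self, segment, stage_index, coupling):
        stage = {1: "S2", 2: "S3", 3: "S4"}[stage_index]
        self.log.append((stage, coupling))
        action = self.script.get((stage, coupling), "NR")
        if action == "nocapture":
            return AttemptResult(captured=False, outcome="NR")
        return AttemptResult(captured=True, outcome=action,
                             episode_duration=500.0 if action != "NR"
                             else 0.0)


class TestStateMachine:
    def test_reentry_at_s2_160_stops_protocol(self):
        """Hand trace: S2 captures at 200..170 without reentry, then the
        160 ms attempt induces — outcome stage S2, final interval 160."""
        b = ScriptedBackend({("S2", 160.0): "R"})
        r = run_vulnerability_protocol(b, segment=4)
        assert r.outcome == "R"
        assert r.inducing_stage == "S2"
        assert r.coupling_intervals["S2"] == 160.0
        assert b.log == [("S2", c) for c in (200., 190., 180., 170., 160.)]

    def test_capture_failure_moves_to_s3_with_s2_fixed(self):
        """S2 fails to propagate at 140 ms: S2 is fixed at the last
        captured interval (150) and the first S3 attempt induces."""
        b = ScriptedBackend({("S2", 140.0): "nocapture",
                             ("S3", 250.0): "UR"})
        r = run_vulnerability_protocol(b, segment=9)
        assert r.inducing_stage == "S3"
        assert r.outcome == "UR"
        assert r.coupling_intervals["S2"] == 150.0
        assert r.coupling_intervals["S3"] == 250.0

    def test_all_stages_exhausted_is_nr(self):
        """Capture failures at every stage with no reentry end in NR."""
        b = ScriptedBackend({("S2", 150.0): "nocapture",
                             ("S3", 180.0): "nocapture",
                             ("S4", 200.0): "nocapture"})
        r = run_vulnerability_protocol(b, segment=1)
        assert r.outcome == "NR"
        assert r.inducing_stage == "none"
        # every stage kept its last captured interval
        assert r.coupling_intervals == {"S2": 160.0, "S3": 190.0,
                                        "S4": 210.0}

    def test_s4_reentry_reached_through_full_cascade(self):
        b = ScriptedBackend({("S2", 180.0): "nocapture",
                             ("S3", 210.0): "nocapture",
                             ("S4", 220.0): "R"})
        r = run_vulnerability_protocol(b, segment=17)
        assert r.inducing_stage == "S4"
        assert r.coupling_intervals == {"S2": 190.0, "S3": 220.0,
                                        "S4": 220.0}

    def test_hard_floor_bounds_attempts(self):
        """A site that always captures and never induces stops at the
        100 ms coupling floor in each stage."""
        b = ScriptedBackend({})
        r = run_vulnerability_protocol(b, segment=2)
        assert r.outcome == "NR"
        couplings = [c for _, c in b.log]
        assert min(couplings) >= 100.0
        # intervals never violate the 10 ms inter-stimulus guard
        assert all(c >= 10.0 for c in couplings)

    def test_first_stage_never_capturing_ends_protocol(self):
        script = {("S2", float(c)): "nocapture"
                  for c in range(100, 210, 10)}
        b = ScriptedBackend(script)
        r = run_vulnerability_protocol(b, segment=3)
        assert r.outcome == "NR"
        assert all(stage == "S2" for stage, _ in b.log)

    def test_nr_outcome_must_pair_with_stage_none(self):
        with pytest.raises(ValueError):
            SiteResult(site=1, outcome="NR", inducing_stage="S2",
                       coupling_intervals={})


class TestClassifyOutcome:
    def test_empty_event_list_is_nr(self):
        assert classify_outcome([], last_stim_onset=100.0) == "NR"

    def test_single_activations_only_is_nr(self):
        events = [(e, 200.0 + e) for e in range(20)]
        assert classify_outcome(events, 100.0) == "NR"

    def test_activity_into_final_window_is_sustained(self):
        cfg = ProtocolConfig()
        events = [(1, t) for t in np.arange(200.0, 2100.0, 120.0)]
        assert classify_outcome(events, 100.0, cfg) == "R"

    def test_extinguishing_activity_is_unsustained(self):
        events = [(1, 200.0), (1, 400.0), (1, 600.0), (2, 700.0)]
        assert classify_outcome(events, 100.0) == "UR"

    def test_latency_excludes_the_paced_beat(self):
        # both activations inside the 50 ms post-stimulus latency
        events = [(1, 110.0), (1, 145.0)]
        assert classify_outcome(events, 100.0) == "NR"


class TestCheckCapture:
    def test_refractory_tissue_not_captured(self, full_slab):
        geom, _ = full_slab
        assert not check_capture([], geom, [0], stim_onset=10.0)

    def test_propagating_beat_captured(self, full_slab):
        geom, _ = full_slab
        site = [0]
        far = int(np.argmax(
            np.linalg.norm(geom.centers - geom.centers[0], axis=1)))
        events = [(far, 40.0)]
        assert check_capture(events, geom, site, stim_onset=10.0)

    def test_local_only_excitation_not_captured(self, full_slab):
        geom, _ = full_slab
        site = [0]
        near = np.flatnonzero(
            np.linalg.norm(geom.centers - geom.centers[0], axis=1) < 4.0)
        events = [(int(e), 30.0) for e in near[:10]]
        assert not check_capture(events, geom, site, stim_onset=10.0)

    def test_late_distant_activation_not_capture(self, full_slab):
        geom, _ = full_slab
        far = int(np.argmax(
            np.linalg.norm(geom.centers - geom.centers[0], axis=1)))
        events = [(far, 500.0)]  # outside the 100 ms capture window
        assert not check_capture(events, geom, [0], stim_onset=10.0)


class TestPacingSites:
    def test_17_sites_one_per_segment(self, full_slab):
        geom, _ = full_slab
        sites = select_pacing_sites(geom)
        assert sorted(sites) == list(range(1, 18))
        for seg, elems in sites.items():
            assert (geom.segment_id[elems] == seg).all()

    def test_empty_segment_rejected(self, full_slab):
        geom, _ = full_slab
        g = geom.copy()
        g.segment_id[g.segment_id == 17] = 16
        with pytest.raises(GeometryError, match="17"):
            select_pacing_sites(g)


class TestBookkeeping:
    def test_printed_baseline_counts_identities(self):
        s = summary_from_counts(510, 111, 30)
        assert round(s["ratio"], 3) == 0.218
        assert s["non_arrhythmic_segments"] == 399
        assert s["segments_per_model"] == 17.0
        assert round(s["mean_reentries_per_model"], 2) == 3.70
        assert round(s["pct_segments_with_reentry"], 2) == 21.76

    def test_printed_augmented_counts_identities(self):
        s = summary_from_counts(2193, 285, 129)
        assert round(s["ratio"], 3) == 0.130
        assert s["non_arrhythmic_segments"] == 1908
        assert s["segments_per_model"] == 17.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            summary_from_counts(100, 200, 10)

    def test_all_nr_population_has_zero_ratio(self):
        from reentryforge.ischemia import PopulationMember, LayeredIschemia
        from reentryforge import IschemiaSpec, generate_slab, \
            assign_aha_segments
        from reentryforge.ischemia import assign_layers

        members = []
        for pid in range(3):
            spec = IschemiaSpec(center=(7.5, 7.5), radius=3.0)
            g = generate_slab(60, 60, 0.25, spec, seed=pid)
            g = assign_aha_segments(g)
            g, layers = assign_layers(g, 5)
            members.append(PopulationMember(pid, 0, g, layers))

        class AllNR:
            def attempt_for_site(self, segment, stage_index, coupling):
                return AttemptResult(captured=coupling > 150.0,
                                     outcome="NR")

        summary = evaluate_population(members, lambda m: AllNR())
        assert summary.ratio == 0.0
        assert summary.arrhythmic_segments == 0
        assert summary.tested_segments == 3 * 17
        assert (summary.per_level["n_patients_with_reentry"] == 0).all()
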