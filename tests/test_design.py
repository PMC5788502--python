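"""Connector design: window enumeration, chimera assembly, structural
scoring, ranking and sequestration-switch logic."""

import math

import numpy as np
import pytest

from riboconnect.design import (
    DesignError,
    antisense_for_window,
    assemble_activator,
    assemble_repressor,
    assemble_switch_activator,
    design_connectors,
    enumerate_windows,
    evaluate_switch,
    position_prior,
    rank_designs,
    score_design,
)
from riboconnect.fixtures import sensor_for_antisense
from riboconnect.fold import fold
from riboconnect.rna_io import Aptamer, Transcript, packaged_aptamer_library, reverse_complement


@pytest.fixture(scope="module")
def lib():
    return packaged_aptamer_library()


class TestWindows:
    def test_step_windows_inside_utr(self):
        t = Transcript(id="t", sequence="A" * 100, utr5_end=25, cds_end=100)
        ws = enumerate_windows(t, "utr5", length=20, step=5)
        assert ws == [(0, 20), (5, 25)]

    def test_region_shorter_than_window_empty(self):
        t = Transcript(id="t", sequence="A" * 100, utr5_end=10, cds_end=100)
        assert enumerate_windows(t, "utr5", length=20) == []

    def test_step_one_count(self):
        t = Transcript(id="t", sequence="A" * 80, utr5_end=50, cds_end=80)
        assert len(enumerate_windows(t, "utr5", length=20, step=1)) == 31

    def test_both_regions_ascending(self):
        t = Transcript(id="t", sequence="A" * 100, utr5_end=40, cds_end=100)
        ws = enumerate_windows(t, "both", length=20, step=10)
        assert ws == sorted(ws)
        assert all(e - s == 20 for s, e in ws)


class TestAssembly:
    def test_repressor_contains_sensor_copies(self, lib):
        d = assemble_repressor("A" * 20, lib["theo"], copies=2)
        assert d.full_sequence.count(lib["theo"].sequence) == 2
        assert d.topology == "repressor"
        assert d.module_summary() == [("antisense", 1), ("theo", 2)]

    def test_single_copy_length_arithmetic(self, lib):
        d = assemble_repressor("A" * 20, lib["theo"], copies=1, linker="AAA")
        assert len(d.full_sequence) == 20 + 3 + len(lib["theo"].sequence)

    @pytest.mark.parametrize("copies", [0, 4])
    def test_copies_outside_explored_valencies(self, lib, copies):
        with pytest.raises(DesignError, match="copies"):
            assemble_repressor("A" * 20, lib["theo"], copies=copies)

    def test_activator_requires_effector_role(self, lib):
        with pytest.raises(DesignError, match="role"):
            assemble_activator("A" * 20, lib["theo"])

    def test_activator_default_two_effector_copies(self, lib):
        d = assemble_activator("A" * 20, lib["eif4g"])
        assert d.full_sequence.count(lib["eif4g"].sequence) == 2
        assert d.notes == ()

    def test_single_effector_flagged_reduced_efficacy(self, lib):
        d = assemble_activator("A" * 20, lib["eif4g"], copies=1)
        assert "reduced-efficacy" in d.notes

    def test_antisense_duplexes_with_its_window(self, transcript, lib):
        """Designed antisense always forms a perfect 20/20 duplex."""
        for window in [(0, 20), (30, 50), (100, 120)]:
            anti = antisense_for_window(transcript, window)
            target_seq = transcript.sequence[window[0] : window[1]]
            assert anti == reverse_complement(target_seq)
            assert len(anti) == 20


class TestSwitchAssembly:
    def make_switch(self, lib, antisense="GGGGAGGAGGAGGAGGAGGA"):
        sensor = sensor_for_antisense(antisense, id="sw_sensor", ligand="theophylline")
        return assemble_switch_activator(sensor, antisense, lib["eif4g"], 2)

    def test_complementary_antisense_builds(self, lib):
        d = self.make_switch(lib)
        assert d.topology == "switch_activator"

    def test_mismatched_antisense_lists_positions(self, lib):
        sensor = sensor_for_antisense(
            "GGGGAGGAGGAGGAGGAGGA", id="s", ligand="theophylline"
        )
        with pytest.raises(DesignError, match="mismatch"):
            assemble_switch_activator(sensor, "CCCCAGGAGGAGGAGGAGGA", lib["eif4g"], 2)

    def test_ligand_flips_switch_on(self, lib):
        d = self.make_switch(lib)
        assert evaluate_switch(d, ligand_present=False).state == "OFF"
        assert evaluate_switch(d, ligand_present=True).state == "ON"

    def test_zero_bonus_means_no_ligand_effect(self, lib):
        anti = "GGGGAGGAGGAGGAGGAGGA"
        sensor = sensor_for_antisense(
            anti, id="s0", ligand="theophylline", binding_bonus=0.0
        )
        d = assemble_switch_activator(
            sensor, anti, lib["eif4g"], 2, verify_off_state=False
        )
        assert (
            evaluate_switch(d, True).state == evaluate_switch(d, False).state
        )

    def test_increasing_bonus_never_turns_off(self, lib):
        """Two-state logic is monotone in the binding bonus: OFF→ON only."""
        anti = "GGGGAGGAGGAGGAGGAGGA"
        prev_on = False
        for bonus in (0.5, 2.0, 5.0, 20.0):
            sensor = sensor_for_antisense(
                anti, id=f"s{bonus}", ligand="theophylline", binding_bonus=bonus
            )
            d = assemble_switch_activator(
                sensor, anti, lib["eif4g"], 2, verify_off_state=False
            )
            on = evaluate_switch(d, True).state == "ON"
            assert on or not prev_on
            prev_on = on

    def test_wrong_topology_rejected(self, lib):
        d = assemble_repressor("A" * 20, lib["theo"], 2)
        with pytest.raises(DesignError, match="switch_activator"):
            evaluate_switch(d, True)


class TestScoring:
    def test_position_prior_boundary_and_decay(self, transcript):
        assert position_prior(0, transcript) == 1.0
        assert position_prior(300, transcript, lam=300.0) == pytest.approx(
            math.exp(-1), rel=1e-12
        )

    def test_position_prior_strictly_decreasing(self, transcript):
        priors = [position_prior(s, transcript) for s in range(0, 500, 50)]
        assert all(a > b for a, b in zip(priors, priors[1:]))

    def test_exposed_tail_keeps_hairpin(self, lib):
        """A poly-A antisense tail on a GC hairpin aptamer stays unpaired and
        the hairpin is fully preserved (verified by direct folding)."""
        apt = Aptamer(
            id="hp", ligand="toy", sequence="GGGGAAAACCCC",
            reference_structure="((((....))))", stem=(0, 4),
        )
        target = Transcript(id="t", sequence="U" * 40, utr5_end=30, cds_end=40)
        lib2 = packaged_aptamer_library()
        lib2.add(apt)
        d = assemble_repressor(
            "A" * 20, apt, 1, target_id="t", window=(0, 20)
        )
        scored = score_design(d, target, lib2)
        assert scored.scores.exposedness == 1.0
        assert scored.scores.preservation == 1.0
        # direct check on the fold itself
        structure = fold(d.full_sequence)
        assert all(i >= 20 and j >= 20 for i, j in structure.pairs)

    def test_antisense_window_mismatch_rejected(self, transcript, lib):
        d = assemble_repressor(
            "A" * 20, lib["theo"], 2, target_id=transcript.id, window=(0, 20)
        )
        with pytest.raises(DesignError, match="reverse complement"):
            score_design(d, transcript, lib)

    def test_score_bounds_on_random_windows(self, transcript, lib):
        """Exposedness and preservation stay in [0, 1] across designs."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            start = int(rng.integers(0, len(transcript.sequence) - 20))
            window = (start, start + 20)
            d = assemble_repressor(
                antisense_for_window(transcript, window), lib["theo"], 2,
                target_id=transcript.id, window=window,
            )
            s = score_design(d, transcript, lib).scores
            assert 0.0 <= s.exposedness <= 1.0
            assert 0.0 <= s.preservation <= 1.0
            assert 0.0 < s.position_prior <= 1.0
            assert s.composite <= min(s.exposedness, 1.0) + 1e-12


class TestRanking:
    def _scored(self, transcript, lib, starts):
        out = []
        for s in starts:
            window = (s, s + 20)
            d = assemble_repressor(
                antisense_for_window(transcript, window), lib["theo"], 2,
                target_id=transcript.id, window=window,
            )
            out.append(score_design(d, transcript, lib))
        return out

    def test_sorted_by_composite_then_start(self, transcript, lib):
        designs = self._scored(transcript, lib, [25, 0, 440])
        ranked = rank_designs(designs, thresholds=(0.5, 0.5))
        comps = [d.scores.composite for d in ranked]
        assert comps == sorted(comps, reverse=True)

    def test_failing_designs_excluded(self, transcript, lib):
        designs = self._scored(transcript, lib, [0, 25])
        ranked = rank_designs(designs, thresholds=(1.01, 0.0))
        assert ranked == []

    def test_pure_function_of_scores(self, transcript, lib):
        designs = self._scored(transcript, lib, [0, 25, 440])
        a = [d.id for d in rank_designs(designs)]
        b = [d.id for d in rank_designs(list(reversed(designs)))]
        assert a == b

    def test_unscored_rejected(self, transcript, lib):
        d = assemble_repressor(
            antisense_for_window(transcript, (0, 20)), lib["theo"], 2,
            target_id=transcript.id, window=(0, 20),
        )
        with pytest.raises(DesignError, match="unscored"):
            rank_designs([d])


class TestPipeline:
    def test_design_connectors_end_to_end(self, transcript, lib):
        designs = design_connectors(
            transcript, lib, "repressor", sensor_id="theo",
            region="utr5", step=5,
        )
        assert designs, "expected at least one passing UTR design"
        assert all(d.scores.passed for d in designs)
        assert all(d.region == "UTR5" for d in designs)
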