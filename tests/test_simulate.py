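import numpy as np
import pytest

from circuitseq import (CircuitAnnotation, FragmentLengthDistribution,
                        GroundTruth, Part, PartType, analytic_end_coverage,
                        build_strand_profiles, sample_fragments,
                        simulate_expected_profile, simulate_experiment)
from circuitseq.io import SENSE, TranscriptionProfile
from circuitseq.simulate import (AntisensePromoter, _overlay, default_fld,
                                 transcript_species)
from tests.conftest import REF, build_truth


def _single_promoter_annotation(ts=None):
    parts = [Part("P", PartType.PROMOTER, REF, 100, 135, "+", {"tss": 135})]
    if ts is not None:
        parts.append(Part("T", PartType.TERMINATOR, REF, 2000, 2060, "+"))
    return CircuitAnnotation(parts, REF, 4000)


class TestExpectedProfile:
    def test_flux_over_degradation_plateau(self):
        annotation = _single_promoter_annotation()
        truth = GroundTruth(promoter_activities={"s": {"P": 2.01}})
        sense, antisense = simulate_expected_profile(annotation, truth, "s")
        assert sense.values[1000] == pytest.approx(300.0)
        assert antisense.values.sum() == 0.0

    def test_terminator_reduces_downstream_plateau(self):
        annotation = _single_promoter_annotation(ts=True)
        truth = GroundTruth(promoter_activities={"s": {"P": 2.01}},
                            terminator_ts={"T": 100.0})
        sense, _ = simulate_expected_profile(annotation, truth, "s")
        assert sense.values[1000] == pytest.approx(300.0)
        assert sense.values[2500] == pytest.approx(3.0)

    def test_antisense_promoter_covers_upstream_region(self):
        annotation = _single_promoter_annotation()
        truth = GroundTruth(
            promoter_activities={"s": {"P": 2.01}},
            antisense_promoters=(AntisensePromoter("AS", tss=3000,
                                                   activity=0.67,
                                                   stop=2500),))
        _, antisense = simulate_expected_profile(annotation, truth, "s")
        assert antisense.values[2700] == pytest.approx(100.0)
        assert antisense.values[3200] == 0.0

    def test_species_overlay_equals_traced_profile(self, annotation):
        # two independent constructions of the same expectation: transcript
        # species bookkeeping vs the 5'->3' tracing rules
        truth = build_truth()
        activities = truth.promoter_activities["s1"]
        species = transcript_species(annotation, truth, activities)
        overlay = _overlay(species, annotation.reference_length)
        sense, _ = simulate_expected_profile(annotation, truth, "s1")
        assert np.allclose(overlay, sense.values)


class TestSampleFragments:
    def _flat_profile(self, length=2000, height=10.0):
        return TranscriptionProfile(REF, SENSE, np.full(length, height))

    def test_same_seed_identical_fragments(self):
        fld = default_fld()
        profile = self._flat_profile()
        a = sample_fragments(profile, fld, 5000, seed=3)
        b = sample_fragments(profile, fld, 5000, seed=3)
        assert [(f.start, f.end) for f in a] == [(f.start, f.end) for f in b]

    def test_coverage_mass_conservation(self):
        fld = default_fld()
        fragments = sample_fragments(self._flat_profile(), fld, 20000, seed=1)
        sense, _ = build_strand_profiles(fragments, 2000)
        assert sense.values.sum() == sum(f.length for f in fragments)

    def test_end_coverage_matches_placement_counts(self):
        L, N = 100, 2000
        fld = FragmentLengthDistribution.point_mass(L)
        fragments = sample_fragments(self._flat_profile(N), fld, 300_000,
                                     seed=2)
        sense, _ = build_strand_profiles(fragments, N)
        x = np.arange(1, 501)
        expected = np.array([analytic_end_coverage(int(i), L, N) for i in x],
                            dtype=float)
        observed = sense.values[:500]
        assert np.abs(observed / observed[L:500].mean()
                      - expected / L).max() < 0.05

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            sample_fragments(self._flat_profile(), default_fld(), 0, seed=0)

    def test_fragments_longer_than_every_unit_rejected(self):
        fld = FragmentLengthDistribution.point_mass(500)
        short = TranscriptionProfile(REF, SENSE,
                                     np.concatenate([np.zeros(100),
                                                     np.full(50, 5.0),
                                                     np.zeros(100)]))
        with pytest.raises(ValueError):
            sample_fragments(short, fld, 10, seed=0)


class TestSimulateExperiment:
    def _eight_state_truth(self, sigma=0.0):
        activities = {}
        for i in range(8):
            bits = [(i >> b) & 1 for b in range(3)]
            activities[f"s{i}"] = {"P1": 2.0 * bits[0] + 0.01,
                                   "P2": 4.0 * bits[1] + 0.01}
        return GroundTruth(promoter_activities=activities,
                           terminator_ts={"T1": 80.0, "T2": 150.0},
                           ribozyme_pc={"R1": 0.95, "R2": 0.95},
                           noise_sigma=sigma)

    def test_eight_states_produce_eight_bundles(self, annotation):
        truth = self._eight_state_truth()
        experiment = simulate_experiment(annotation, truth,
                                         [f"s{i}" for i in range(8)],
                                         depth=2000, seed=1)
        assert len(experiment.fragments) == 8
        assert len(experiment.true_profiles) == 8

    def test_zero_noise_profiles_reproducible_from_truth(self, annotation,
                                                         truth):
        experiment = simulate_experiment(annotation, truth, ["s1"],
                                         depth=1000, seed=5)
        sense, _ = simulate_expected_profile(annotation, truth, "s1")
        got, _ = experiment.true_profiles["s1"]
        assert np.array_equal(got.values, sense.values)
        assert experiment.realized_activities["s1"] == \
            truth.promoter_activities["s1"]

    def test_same_seed_bit_identical(self, annotation, truth):
        a = simulate_experiment(annotation, truth, ["s1"], depth=3000,
                                seed=7)
        b = simulate_experiment(annotation, truth, ["s1"], depth=3000,
                                seed=7)
        assert [(f.start, f.end, f.strand_class)
                for f in a.fragments["s1"]] == \
               [(f.start, f.end, f.strand_class) for f in b.fragments["s1"]]

    def test_lognormal_noise_perturbs_activities(self, annotation):
        truth = self._eight_state_truth(sigma=0.2)
        experiment = simulate_experiment(annotation, truth, ["s1"],
                                         depth=1000, seed=2)
        realized = experiment.realized_activities["s1"]
        assert realized != truth.promoter_activities["s1"]
        assert all(v > 0 for v in realized.values())

    def test_empty_state_list_rejected(self, annotation, truth):
        with pytest.raises(ValueError):
            simulate_experiment(annotation, truth, [], depth=100, seed=0)

    def test_antisense_fragments_emitted_on_minus_strand(self, annotation):
        truth = GroundTruth(
            promoter_activities={"s": {"P1": 2.0}},
            terminator_ts={"T1": 80.0},
            ribozyme_pc={"R1": 0.95},
            antisense_promoters=(AntisensePromoter("AS", tss=3000,
                                                   activity=1.0,
                                                   stop=2400),))
        experiment = simulate_experiment(annotation, truth, ["s"],
                                         depth=20_000, seed=3)
        anti = [f for f in experiment.fragments["s"]
                if f.strand_class == "antisense"]
        assert anti
        assert all(2400 <= f.start and f.end <= 3001 for f in anti)
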