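"""Cleft-width profiling, vesicle-state classification and the criteria report."""

import numpy as np
import pytest

from cryoclem.morphometry import (
    CriteriaConfig,
    MembraneTrace,
    StateThresholds,
    SynapseAnnotation,
    Vesicle,
    classify_vesicle_state,
    evaluate_synapse_criteria,
    measure_cleft_width,
    vesicle_population_stats,
)
from cryoclem.synthetic import generate_synapse_phantom


def parallel_traces(width=20.0, px=1.0, length=400.0):
    x = np.arange(0.0, length, 2.0) / px
    pre = MembraneTrace(np.column_stack([x, np.zeros_like(x)]), px, "presynaptic")
    post = MembraneTrace(np.column_stack([x, np.full_like(x, width / px)]), px, "postsynaptic")
    return pre, post


class TestCleftWidth:
    def test_parallel_lines_exact_width_zero_cv(self):
        pre, post = parallel_traces(20.0)
        prof = measure_cleft_width(pre, post, step_nm=2.0)
        assert prof.mean_nm == pytest.approx(20.0, abs=1e-12)
        assert prof.cv == 0.0
        assert prof.n_dropped == 0

    def test_concentric_arcs_analytic_width(self):
        th_pre = np.linspace(0.2, np.pi - 0.2, 20001)
        th_post = np.linspace(0.1, np.pi - 0.1, 22001)
        pre = MembraneTrace(200.0 * np.column_stack([np.cos(th_pre), np.sin(th_pre)]), 1.0, "presynaptic")
        post = MembraneTrace(220.0 * np.column_stack([np.cos(th_post), np.sin(th_post)]), 1.0, "postsynaptic")
        prof = measure_cleft_width(pre, post, step_nm=2.0)
        assert np.abs(prof.widths_nm - 20.0).max() < 1e-6

    def test_phantom_jitter_statistics_recovered(self):
        means, sds = [], []
        for s in range(25):
            ann, _ = generate_synapse_phantom(7000 + s, width_nm=20.0, width_jitter_sd=2.0, n_vesicles=5)
            prof = measure_cleft_width(
                ann.membrane("presynaptic"), ann.membrane("postsynaptic"), step_nm=2.0
            )
            means.append(prof.mean_nm)
            sds.append(prof.sd_nm)
        assert abs(np.mean(means) - 20.0) < 0.5
        assert abs(np.mean(sds) - 2.0) / 2.0 < 0.3

    def test_swap_symmetry_within_step(self):
        ann, _ = generate_synapse_phantom(123, width_nm=20.0, width_jitter_sd=2.0, n_vesicles=3)
        pre, post = ann.membrane("presynaptic"), ann.membrane("postsynaptic")
        a = measure_cleft_width(pre, post, step_nm=2.0)
        b = measure_cleft_width(post, pre, step_nm=2.0)
        assert abs(a.mean_nm - b.mean_nm) <= 2.0

    def test_intersecting_traces_rejected(self):
        pre = MembraneTrace([[0, 0], [10, 0]], 1.0, "presynaptic")
        post = MembraneTrace([[5, -5], [5, 5]], 1.0, "postsynaptic")
        with pytest.raises(ValueError, match="intersect"):
            measure_cleft_width(pre, post, 1.0)

    def test_no_crossing_raises(self):
        pre = MembraneTrace([[0, 0], [10, 0]], 1.0, "presynaptic")
        post = MembraneTrace([[100, 1000], [110, 1000]], 1.0, "postsynaptic")
        with pytest.raises(ValueError, match="crosses|crossing"):
            measure_cleft_width(pre, post, 1.0, max_ray_nm=50.0)

    def test_pixel_size_invariance(self):
        # the same physical phantom annotated at 2x pixel size gives identical nm results
        prof1 = measure_cleft_width(*parallel_traces(20.0, px=1.0), step_nm=2.0)
        prof2 = measure_cleft_width(*parallel_traces(20.0, px=2.0), step_nm=2.0)
        assert prof1.mean_nm == pytest.approx(prof2.mean_nm, abs=1e-6)
        assert prof1.sd_nm == pytest.approx(prof2.sd_nm, abs=1e-6)


class TestVesicleStates:
    pre = MembraneTrace(np.column_stack([np.arange(0.0, 200.0, 2.0), np.zeros(100)]), 1.0, "presynaptic")

    def classify(self, gap, radius=20.0, flag=None):
        v = Vesicle(center=(100.0, -(radius + gap)), radius_nm=radius, state_flag=flag)
        return classify_vesicle_state(v, self.pre, pixel_size_nm=1.0)

    def test_rim_contact_is_docked(self):
        assert self.classify(0.0) == "docked_or_primed"

    def test_gap_8nm_is_tethered_candidate(self):
        # filamentous tethers are shorter than ~10 nm
        assert self.classify(8.0) == "tethered_candidate"

    def test_gap_100nm_is_free(self):
        assert self.classify(100.0) == "free"

    def test_flags_take_precedence(self):
        assert self.classify(50.0, flag="fusing") == "fusing"
        assert self.classify(-7.0, flag="fully_fused") == "fully_fused"

    def test_deep_overlap_without_flag_is_error(self):
        with pytest.raises(ValueError, match="inconsistent"):
            self.classify(-15.0, radius=20.0)

    def test_states_form_total_partition(self, rng):
        thresholds = StateThresholds()
        for gap in np.concatenate([rng.uniform(-9, 60, 200), [0.0, 2.0, 10.0]]):
            state = self.classify(float(gap))
            assert state in ("docked_or_primed", "tethered_candidate", "free")

    def test_generator_state_mix_recovered(self):
        mix = {"docked_or_primed": 2, "tethered_candidate": 3, "fusing": 1, "fully_fused": 1}
        ann, truth = generate_synapse_phantom(55, n_vesicles=15, state_mix=mix)
        pre = ann.membrane("presynaptic")
        states = [classify_vesicle_state(v, pre, pixel_size_nm=ann.pixel_size_nm) for v in ann.vesicles]
        assert states == truth["labels"]


class TestCriteria:
    def test_canonical_phantom_passes_all(self):
        ann, _ = generate_synapse_phantom(9, width_nm=20.0, width_jitter_sd=1.0, n_vesicles=30,
                                          state_mix={"tethered_candidate": 3})
        prof = measure_cleft_width(ann.membrane("presynaptic"), ann.membrane("postsynaptic"), 2.0)
        report = evaluate_synapse_criteria(ann, prof)
        assert report.all_pass
        assert report.evidence["n_vesicles_presynaptic_side"] >= 25
        assert report.evidence["n_attached_vesicles"] >= 3

    def test_single_membrane_no_vesicles_fails_c1(self):
        pre, _ = parallel_traces()
        report = evaluate_synapse_criteria(
            SynapseAnnotation(membranes=[pre], vesicles=[]), None
        )
        assert not report.c1_opposed_membranes
        assert not report.all_pass

    def test_wide_cleft_fails_c3_only(self):
        ann, _ = generate_synapse_phantom(10, width_nm=40.0, width_jitter_sd=1.0, n_vesicles=30,
                                          state_mix={"tethered_candidate": 3})
        prof = measure_cleft_width(ann.membrane("presynaptic"), ann.membrane("postsynaptic"), 2.0)
        report = evaluate_synapse_criteria(ann, prof)
        assert report.c1_opposed_membranes and report.c2_attached_vesicle
        assert not report.c3_uniform_cleft

    def test_density_flag_is_honored(self):
        ann, _ = generate_synapse_phantom(11, n_vesicles=30, state_mix={"tethered_candidate": 3})
        prof = measure_cleft_width(ann.membrane("presynaptic"), ann.membrane("postsynaptic"), 2.0)
        with_density = evaluate_synapse_criteria(ann, prof, cleft_density_present=True)
        without = evaluate_synapse_criteria(ann, prof, cleft_density_present=False)
        assert with_density.c3_uniform_cleft and not without.c3_uniform_cleft

    def test_no_membranes_is_error(self):
        with pytest.raises(ValueError, match="no membranes"):
            evaluate_synapse_criteria(SynapseAnnotation(membranes=[], vesicles=[]), None)

    def test_no_vesicles_fails_c1_and_c2(self):
        ann, _ = generate_synapse_phantom(12, n_vesicles=0)
        prof = measure_cleft_width(ann.membrane("presynaptic"), ann.membrane("postsynaptic"), 2.0)
        report = evaluate_synapse_criteria(ann, prof)
        assert not report.c1_opposed_membranes and not report.c2_attached_vesicle


class TestPopulationStats:
    def test_empty_annotation(self):
        pre, _ = parallel_traces()
        stats = vesicle_population_stats(SynapseAnnotation(membranes=[pre], vesicles=[]))
        assert stats["n_vesicles"] == 0
        assert stats["state_histogram"] == {} and stats["degree_histogram"] == {}

    def test_uniform_diameters(self):
        pre, _ = parallel_traces()
        vesicles = [Vesicle(center=(20.0 * i, -200.0), radius_nm=20.0) for i in range(10)]
        stats = vesicle_population_stats(SynapseAnnotation(membranes=[pre], vesicles=vesicles))
        assert stats["diameter_mean_nm"] == pytest.approx(40.0)
        assert stats["diameter_sd_nm"] == pytest.approx(0.0)

    def test_connector_degrees_match_generator_truth(self):
        ann, truth = generate_synapse_phantom(31, n_vesicles=12, n_connectors=5)
        stats = vesicle_population_stats(ann)
        assert stats["connector_degrees"] == truth["connector_degrees"]
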