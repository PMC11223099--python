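import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from shapely.geometry import Polygon

from _oracles import phasor_oracle
from srsphasor.errors import (
    AmbiguousReferenceError,
    DegenerateReferenceError,
    DegenerateSpectrumError,
    EmptySegmentError,
    InvalidParameterError,
)
from srsphasor.hyperstack_io import average_projection, background_mask
from srsphasor.phasor_core import (
    PhasorMap,
    PhasorROI,
    derive_roi_from_reference,
    local_maximum_shift,
    phasor_density,
    phasor_polar,
    phasor_transform,
    segment_by_rois,
    segment_spectrum,
    spectrum_phasor,
)
from srsphasor.pipeline import derive_class_rois
from srsphasor.synth_phantom import NEAT_LIPIDS, evaluate_spectrum


def square_roi(label, cg, cs, half=0.1):
    return PhasorROI(
        label=label,
        vertices=np.array(
            [[cg - half, cs - half], [cg + half, cs - half],
             [cg + half, cs + half], [cg - half, cs + half]]
        ),
    )


class TestPhasorTransform:
    def test_flat_spectrum_maps_to_origin(self):
        data = np.full((2, 2, 40), 7.0)
        pmap = phasor_transform(data)
        assert np.allclose(pmap.G, 0.0, atol=1e-12)
        assert np.allclose(pmap.S, 0.0, atol=1e-12)

    def test_delta_spectrum_on_unit_circle(self):
        spectrum = np.zeros(40)
        spectrum[0] = 5.0
        g, s = spectrum_phasor(spectrum)
        assert (g, s) == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_equal_delta_mixture_at_half_half(self):
        # deltas at k=0 -> (1,0) and k=10 of 40 -> (0,1); equal mix -> (0.5, 0.5)
        spectrum = np.zeros(40)
        spectrum[0] = 3.0
        spectrum[10] = 3.0
        assert spectrum_phasor(spectrum) == pytest.approx((0.5, 0.5), abs=1e-12)

    @pytest.mark.parametrize("harmonic", [1, 2])
    def test_matches_direct_summation_oracle(self, rng, harmonic):
        for _ in range(10):
            spectrum = rng.uniform(0.0, 10.0, size=17)
            expected = phasor_oracle(spectrum, harmonic)
            assert spectrum_phasor(spectrum, harmonic) == pytest.approx(expected, abs=1e-12)

    def test_mixture_linearity_against_oracle(self, rng):
        # phasor of aA + bB is the intensity-weighted chord point of A and B
        A = rng.uniform(0.0, 5.0, size=40)
        B = rng.uniform(0.0, 5.0, size=40)
        for a, b in [(1.0, 1.0), (0.3, 2.7), (5.0, 0.1)]:
            mix = a * A + b * B
            gA, sA = phasor_oracle(A)
            gB, sB = phasor_oracle(B)
            wA, wB = a * A.sum(), b * B.sum()
            expected = (
                (wA * gA + wB * gB) / (wA + wB),
                (wA * sA + wB * sB) / (wA + wB),
            )
            assert spectrum_phasor(mix) == pytest.approx(expected, abs=1e-12)

    def test_intensity_scale_invariance(self, rng):
        data = rng.uniform(0.1, 5.0, size=(6, 6, 40))
        a = phasor_transform(data)
        b = phasor_transform(1234.5 * data)
        assert np.allclose(a.G, b.G, atol=1e-12)
        assert np.allclose(a.S, b.S, atol=1e-12)
        assert np.array_equal(a.valid, b.valid)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        arrays(
            np.float64,
            (3, 3, 12),
            elements=st.floats(0.0, 1e6, allow_nan=False, allow_infinity=False),
        )
    )
    def test_unit_disc_bound_property(self, data):
        pmap = phasor_transform(data)
        radius2 = pmap.G[pmap.valid] ** 2 + pmap.S[pmap.valid] ** 2
        assert np.all(radius2 <= 1.0 + 1e-9)

    def test_zero_total_intensity_invalid(self):
        data = np.zeros((2, 2, 40))
        data[0, 0] = 1.0
        pmap = phasor_transform(data)
        assert pmap.valid[0, 0] and not pmap.valid[1, 1]
        assert pmap.G[1, 1] == 0.0

    def test_single_channel_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            phasor_transform(np.ones((2, 2, 1)))

    def test_mask_restricts_validity(self):
        data = np.ones((2, 2, 40))
        mask = np.array([[True, False], [False, True]])
        pmap = phasor_transform(data, mask=mask)
        assert np.array_equal(pmap.valid, mask)


class TestPhasorPolar:
    def test_origin_and_circle_extremes(self):
        flat = np.full((1, 1, 40), 2.0)
        mod, _ = phasor_polar(phasor_transform(flat))
        assert mod[0, 0] == pytest.approx(0.0, abs=1e-12)
        delta = np.zeros((1, 1, 40))
        delta[0, 0, 3] = 1.0
        mod, _ = phasor_polar(phasor_transform(delta))
        assert mod[0, 0] == pytest.approx(1.0, abs=1e-9)


class TestPhasorDensity:
    def test_counts_conserve_valid_pixels(self, rng):
        data = rng.uniform(0.0, 2.0, size=(10, 10, 40))
        pmap = phasor_transform(data)
        counts, _, _ = phasor_density(pmap, bins=64)
        assert counts.sum() == pmap.valid.sum()

    def test_identical_pixels_fill_single_bin(self):
        data = np.tile(np.linspace(1, 2, 40), (5, 5, 1))
        counts, _, _ = phasor_density(phasor_transform(data), bins=32)
        assert (counts > 0).sum() == 1
        assert counts.max() == 25

    def test_two_compartment_stack_occupies_two_analytic_bins(self, library, axis40):
        specs = [
            evaluate_spectrum(library["nucleus"], axis40),
            evaluate_spectrum(library["steatosis-droplet"], axis40),
        ]
        data = np.empty((2, 8, 40))
        data[0] = specs[0]
        data[1] = specs[1]
        pmap = phasor_transform(data)
        counts, ge, se = phasor_density(pmap, bins=128)
        occupied = np.argwhere(counts > 0)
        assert len(occupied) == 2
        for spec in specs:
            g, s = phasor_oracle(spec)
            ib = np.searchsorted(ge, g) - 1
            jb = np.searchsorted(se, s) - 1
            assert counts[ib, jb] == 8

    def test_too_few_bins_rejected(self):
        pmap = phasor_transform(np.ones((2, 2, 40)))
        with pytest.raises(InvalidParameterError):
            phasor_density(pmap, bins=1)


class TestSegmentByRois:
    def _uniform_pmap(self, g, s, shape=(4, 4)):
        G = np.full(shape, g)
        S = np.full(shape, s)
        return PhasorMap(G=G, S=S, harmonic=1, valid=np.ones(shape, dtype=bool))

    def test_vertex_point_is_inside(self):
        pmap = self._uniform_pmap(0.1, 0.1)
        roi = square_roi("nucleus", 0.2, 0.2)  # (0.1, 0.1) is a vertex
        labels = segment_by_rois(pmap, [roi])
        assert np.all(labels == 1)

    def test_whole_disc_roi_labels_every_valid_pixel(self, rng):
        data = rng.uniform(0.0, 3.0, size=(6, 6, 40))
        mask = rng.uniform(size=(6, 6)) > 0.3
        pmap = phasor_transform(data, mask=mask)
        disc = PhasorROI(
            label="cytoplasm",
            vertices=np.array([[-1.05, -1.05], [1.05, -1.05], [1.05, 1.05], [-1.05, 1.05]]),
        )
        labels = segment_by_rois(pmap, [disc])
        assert np.array_equal(labels > 0, pmap.valid)

    def test_later_listed_roi_wins_overlap(self):
        pmap = self._uniform_pmap(0.0, 0.0)
        a = square_roi("nucleus", 0.0, 0.0)
        b = square_roi("cytoplasm", 0.0, 0.0)
        assert np.all(segment_by_rois(pmap, [a, b]) == 2)
        assert np.all(segment_by_rois(pmap, [b, a]) == 1)

    def test_total_lipid_never_overwrites_specific_classes(self):
        pmap = self._uniform_pmap(0.3, 0.3)
        steat = square_roi("steatosis", 0.3, 0.3)
        umbrella = square_roi("total_lipid", 0.3, 0.3, half=0.3)
        for order in ([steat, umbrella], [umbrella, steat]):
            labels = segment_by_rois(pmap, order)
            assert np.all(labels == 3)

    def test_partition_every_valid_pixel_single_label(self, noisy_phantom):
        planar = noisy_phantom.stack.plane(0)
        mask = background_mask(average_projection(planar))
        pmap = phasor_transform(planar, 1, mask)
        rois = derive_class_rois(
            ("nucleus", "cytoplasm", "steatosis", "phospholipidosis"),
            planar.axis,
            noise=noisy_phantom.config.noise,
            seed=1,
        )
        labels = segment_by_rois(pmap, rois)
        assert labels.shape == pmap.G.shape
        assert np.all(labels[~pmap.valid] == 0)

    def test_invalid_roi_polygons_rejected(self):
        with pytest.raises(InvalidParameterError):
            PhasorROI("nucleus", np.array([[0, 0], [0.1, 0.1]]))  # too few
        with pytest.raises(InvalidParameterError):
            PhasorROI("nucleus", np.array([[0, 0], [2.0, 0], [0, 0.5]]))  # outside
        with pytest.raises(InvalidParameterError):  # bow-tie self-intersection
            PhasorROI("nucleus", np.array([[0, 0], [1, 1], [1, 0], [0, 1]]))


class TestDeriveRoi:
    def test_model_reference_centers_on_analytic_phasor(self, library, axis40):
        model = library["cytoplasm"]
        roi = derive_roi_from_reference(model, padding=0.05, label="cytoplasm", axis=axis40)
        g, s = phasor_oracle(evaluate_spectrum(model, axis40))
        centroid = Polygon(roi.vertices).centroid
        assert centroid.x == pytest.approx(g, abs=1e-6)
        assert centroid.y == pytest.approx(s, abs=1e-6)

    def test_zero_padding_single_point_degenerate(self, library, axis40):
        with pytest.raises(DegenerateReferenceError):
            derive_roi_from_reference(library["nucleus"], padding=0.0, axis=axis40)

    def test_sprawling_reference_cloud_ambiguous(self):
        G = np.linspace(-0.9, 0.9, 100).reshape(10, 10)
        S = np.zeros((10, 10))
        pmap = PhasorMap(G=G, S=S, harmonic=1, valid=np.ones((10, 10), bool))
        with pytest.raises(AmbiguousReferenceError):
            derive_roi_from_reference(pmap, padding=0.02)

    def test_small_reference_cloud_rejected(self):
        shape = (2, 2)
        pmap = PhasorMap(
            G=np.zeros(shape), S=np.zeros(shape), harmonic=1, valid=np.ones(shape, bool)
        )
        with pytest.raises(InvalidParameterError):
            derive_roi_from_reference(pmap)

    def test_nine_neat_lipid_rois_mutually_disjoint(self, library, axis40):
        from srsphasor.pipeline import _reference_phasor_map
        from srsphasor.synth_phantom import NoiseModel

        noise = NoiseModel()
        rois = []
        for i, name in enumerate(NEAT_LIPIDS):
            ref = _reference_phasor_map(
                library[name], axis40, noise, 1000.0, (24, 24), seed=300 + i, harmonic=1
            )
            rois.append(derive_roi_from_reference(ref, label=name))
        polys = [Polygon(r.vertices) for r in rois]
        for i in range(9):
            for j in range(i + 1, 9):
                assert polys[i].disjoint(polys[j]), (NEAT_LIPIDS[i], NEAT_LIPIDS[j])


class TestSegmentSpectrum:
    def test_homogeneous_region_recovers_model_exactly(self, library, axis40):
        spec = evaluate_spectrum(library["nucleus"], axis40)
        data = np.tile(spec, (4, 4, 1))
        labels = np.ones((4, 4), dtype=int)
        seg = segment_spectrum(data, labels, 1, "max")
        assert np.allclose(seg.mean_spectrum, spec / spec.max(), rtol=1e-12)
        assert seg.pixel_count == 16

    def test_area_normalization_sums_to_one(self, library, axis40):
        spec = evaluate_spectrum(library["cytoplasm"], axis40)
        data = np.tile(spec, (3, 3, 1))
        seg = segment_spectrum(data, np.ones((3, 3), int), 1, "area")
        assert seg.mean_spectrum.sum() == pytest.approx(1.0)

    def test_empty_label_is_an_error(self, library, axis40):
        data = np.tile(evaluate_spectrum(library["nucleus"], axis40), (3, 3, 1))
        with pytest.raises(EmptySegmentError):
            segment_spectrum(data, np.zeros((3, 3), int), 4)

    def test_phantom_nucleus_peak_and_steatosis_ch2(self, noiseless_phantom):
        planar = noiseless_phantom.stack.plane(0)
        truth = noiseless_phantom.truth_labels[0]
        nucleus = segment_spectrum(planar, truth, 1)
        peak = local_maximum_shift(nucleus.mean_spectrum, planar.axis, (2940.0, 2990.0))
        assert abs(peak - 2965.0) <= np.diff(planar.axis.values).max()
        steat = segment_spectrum(planar, truth, 3)
        cyto = segment_spectrum(planar, truth, 2)
        i851 = planar.axis.index_of(2851.0)
        assert steat.mean_spectrum[i851] > cyto.mean_spectrum[i851]
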