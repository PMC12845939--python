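"""Iris module: segmentation accuracy on known geometry, rubber-sheet
properties, phase-code statistics, Hamming oracle equivalence, matching and
FAR/FRR/EER behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculogate import irisid, simgen
from oculogate.protocols import _perturb, enroll_identity


def _render(identity=11, dilation=0.2, seed=1, noise=0.02, rotation=0.0):
    p = simgen.IrisIdentityParams(identity_seed=identity, intra_noise_sd=noise,
                                  rotation_jitter_deg=rotation)
    return simgen.simulate_iris_image(p, dilation=dilation, seed=seed)


class TestLocateBoundaries:
    def test_recovers_ground_truth_circles(self):
        img = _render()
        fit = irisid.locate_boundaries(img)
        gt = img.ground_truth
        assert abs(fit.pupil[0] - gt["cx"]) <= 1 and abs(fit.pupil[1] - gt["cy"]) <= 1
        assert abs(fit.pupil[2] - gt["r_pupil"]) <= 2
        assert abs(fit.limbus[2] - gt["r_limbus"]) <= 2

    def test_flat_image_raises(self):
        img = irisid.EyeImage(np.full((128, 128), 0.5))
        with pytest.raises(irisid.DetectionError):
            irisid.locate_boundaries(img)

    def test_dilated_render_radius_ratio(self):
        img = _render(dilation=0.40)
        fit = irisid.locate_boundaries(img)
        gt_ratio = img.ground_truth["r_pupil"] / img.ground_truth["r_limbus"]
        assert fit.pupil[2] / fit.limbus[2] == pytest.approx(gt_ratio, rel=0.03)


class TestRubberSheet:
    def test_output_dimensions(self, iris_image_pair):
        img, _ = iris_image_pair
        fit = irisid.locate_boundaries(img)
        tex = irisid.rubber_sheet(img, fit, n_radial=16, n_angular=16)
        assert tex.values.shape == (16, 16)

    def test_dilation_invariance(self, iris_image_pair):
        a, b = iris_image_pair
        ta = irisid.rubber_sheet(a, irisid.locate_boundaries(a), 16, 16)
        tb = irisid.rubber_sheet(b, irisid.locate_boundaries(b), 16, 16)
        r = np.corrcoef(ta.values.ravel(), tb.values.ravel())[0, 1]
        assert r > 0.9

    def test_angular_offset_equals_column_shift(self, iris_image_pair):
        img, _ = iris_image_pair
        fit = irisid.locate_boundaries(img)
        base = irisid.rubber_sheet(img, fit, 16, 16)
        shifted = irisid.rubber_sheet(img, fit, 16, 16, angular_offset=2)
        assert np.max(np.abs(shifted.values - np.roll(base.values, -2, axis=1))) \
            < 1e-6

    def test_rotated_render_matches_after_shift(self):
        """A physical rotation of the eye by two angular steps is recovered
        as a circular shift of the normalised texture (up to pixelation)."""
        base = _render(noise=0.0)
        rot = _render(noise=0.0, rotation=2 * 360.0 / 16.0)
        tb = irisid.rubber_sheet(base, irisid.locate_boundaries(base), 16, 16)
        tr = irisid.rubber_sheet(rot, irisid.locate_boundaries(rot), 16, 16)
        corrs = [np.corrcoef(tr.values.ravel(),
                             np.roll(tb.values, s, axis=1).ravel())[0, 1]
                 for s in range(-4, 5)]
        assert int(np.argmax(corrs)) - 4 == -2
        # bilinear pixelation at 16 angular samples caps the agreement
        assert max(corrs) > 0.8

    def test_sampling_outside_image_raises(self, iris_image_pair):
        img, _ = iris_image_pair
        bad = irisid.BoundaryFit(pupil=(10.0, 10.0, 40.0),
                                 limbus=(10.0, 10.0, 400.0))
        with pytest.raises(ValueError, match="outside"):
            irisid.rubber_sheet(img, bad, 16, 16)


class TestEncode:
    def test_code_lengths(self):
        rng = np.random.default_rng(0)
        t16 = irisid.NormalizedTexture(rng.normal(size=(16, 16)))
        t32 = irisid.NormalizedTexture(rng.normal(size=(16, 32)))
        assert len(irisid.encode(t16, 512)) == 512
        assert len(irisid.encode(t32, 1024)) == 1024

    def test_identical_texture_identical_code(self):
        rng = np.random.default_rng(1)
        t = irisid.NormalizedTexture(rng.normal(size=(16, 16)))
        a, b = irisid.encode(t, 512), irisid.encode(t, 512)
        assert np.array_equal(a.bits, b.bits)
        assert irisid.hamming(a, b) == 0.0

    def test_dimension_mismatch_raises(self):
        t = irisid.NormalizedTexture(np.zeros((16, 16)))
        with pytest.raises(ValueError):
            irisid.encode(t, 1024)

    def test_independent_textures_near_half_distance(self):
        """Phase bits of independent textures are Bernoulli(0.5): mean
        pairwise distance 0.5 +/- 0.02 without shift search."""
        rng = np.random.default_rng(7)
        ds = []
        for _ in range(120):
            a = irisid.encode(irisid.NormalizedTexture(rng.normal(size=(16, 16))), 512)
            b = irisid.encode(irisid.NormalizedTexture(rng.normal(size=(16, 16))), 512)
            ds.append(irisid.hamming(a, b, max_shift=0))
        assert np.mean(ds) == pytest.approx(0.5, abs=0.02)


def _brute_force_hamming(bits_a, bits_b, max_shift):
    """Flat-bit-string oracle: min over circular shifts in steps of 2 bits."""
    n = len(bits_a)
    best = n
    for s in range(-max_shift, max_shift + 1):
        rolled = np.roll(bits_b, 2 * s)
        best = min(best, int(np.sum(bits_a != rolled)))
    return best / n


class TestHamming:
    def test_self_distance_zero_and_complement_one(self):
        rng = np.random.default_rng(3)
        c = irisid.IrisCode(rng.integers(0, 2, 512), 16, 16)
        comp = irisid.IrisCode(1 - c.bits, 16, 16)
        assert irisid.hamming(c, c) == 0.0
        assert irisid.hamming(c, comp, max_shift=0) == 1.0

    def test_sixteen_bit_difference(self):
        bits = np.zeros(512, dtype=np.uint8)
        a = irisid.IrisCode(bits.copy(), 16, 16)
        bits2 = bits.copy()
        bits2[:16] = 1
        b = irisid.IrisCode(bits2, 16, 16)
        assert irisid.hamming(a, b, max_shift=0) == pytest.approx(0.03125)

    def test_length_mismatch_raises(self):
        a = irisid.IrisCode(np.zeros(512, dtype=np.uint8), 16, 16)
        b = irisid.IrisCode(np.zeros(1024, dtype=np.uint8), 16, 32)
        with pytest.raises(ValueError):
            irisid.hamming(a, b)

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(2, 32), st.integers(0, 2 ** 31 - 1), st.integers(0, 4))
    def test_matches_brute_force_oracle(self, n_ang, seed, max_shift):
        """On single-row codes the angular roll is exactly the flat 2-bit
        circular shift, checked against an independent XOR popcount oracle."""
        rng = np.random.default_rng(seed)
        ba = rng.integers(0, 2, 2 * n_ang).astype(np.uint8)
        bb = rng.integers(0, 2, 2 * n_ang).astype(np.uint8)
        a = irisid.IrisCode(ba, 1, n_ang)
        b = irisid.IrisCode(bb, 1, n_ang)
        assert irisid.hamming(a, b, max_shift=max_shift) == \
            pytest.approx(_brute_force_hamming(ba, bb, max_shift))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = irisid.IrisCode(rng.integers(0, 2, 128), 4, 16)
        b = irisid.IrisCode(rng.integers(0, 2, 128), 4, 16)
        d = irisid.hamming(a, b)
        assert 0.0 <= d <= 1.0
        assert d == irisid.hamming(b, a)


class TestIdentify:
    def test_enrolled_probe_accepted_at_zero(self):
        rng = np.random.default_rng(5)
        gallery = [irisid.IrisCode(rng.integers(0, 2, 512), 16, 16,
                                   identity=f"id{i}") for i in range(10)]
        res = irisid.identify(gallery[3], gallery)
        assert res.accepted and res.best_id == "id3" and res.distance == 0.0

    def test_random_gallery_rejected(self):
        rng = np.random.default_rng(6)
        probe = irisid.encode(irisid.NormalizedTexture(rng.normal(size=(16, 16))), 512)
        gallery = [irisid.encode(
            irisid.NormalizedTexture(rng.normal(size=(16, 16))), 512)
            for _ in range(20)]
        res = irisid.identify(probe, gallery, threshold=0.32)
        assert not res.accepted
        assert 0.38 <= res.distance <= 0.55

    def test_tie_breaks_by_gallery_order(self):
        c = irisid.IrisCode(np.zeros(512, dtype=np.uint8), 16, 16)
        gallery = [irisid.IrisCode(np.zeros(512, dtype=np.uint8), 16, 16,
                                   identity=f"id{i}") for i in range(3)]
        assert irisid.identify(c, gallery).best_id == "id0"

    def test_empty_gallery_raises(self):
        c = irisid.IrisCode(np.zeros(512, dtype=np.uint8), 16, 16)
        with pytest.raises(ValueError):
            irisid.identify(c, [])

    def test_genuine_noisy_probes_accepted(self):
        """Perturbed re-acquisitions of an enrolled identity are accepted in
        >= 99% of 1000 trials at the default intra-class noise level."""
        base = enroll_identity(identity_seed=21, dilation=0.2)
        rng = np.random.default_rng(0)
        accepted = 0
        for _ in range(1000):
            rot = int(rng.integers(-4, 5))
            probe = _perturb(base, 0.08, rot, rng)
            if irisid.hamming(probe, base) <= 0.32:
                accepted += 1
        assert accepted >= 990

    def test_rotation_robustness(self):
        base = enroll_identity(identity_seed=22, dilation=0.2)
        rng = np.random.default_rng(1)
        probe = _perturb(base, 0.05, 3, rng)
        assert irisid.hamming(probe, base, max_shift=4) <= \
            irisid.hamming(probe, base, max_shift=0)


class TestBiometricEval:
    def test_fully_separated_zero_eer(self):
        ev = irisid.evaluate_biometrics([0.1, 0.12, 0.15], [0.4, 0.45, 0.5])
        assert ev.eer == 0.0

    def test_identical_sets_half_eer(self):
        s = np.linspace(0.1, 0.9, 50)
        ev = irisid.evaluate_biometrics(s, s)
        assert ev.eer == pytest.approx(0.5, abs=0.02)

    def test_linear_interpolation_oracle(self):
        """FAR [0,.02,.10] vs FRR [.10,.04,0]: crossing on the last segment
        at EER = 1/30."""
        grid = np.array([0.2, 0.3, 0.4])
        far = np.array([0.0, 0.02, 0.10])
        frr = np.array([0.10, 0.04, 0.0])
        eer, _ = irisid.eer_from_curves(grid, far, frr)
        assert eer == pytest.approx(0.0333, abs=1e-3)

    def test_monotonicity_and_gar_identity(self):
        rng = np.random.default_rng(2)
        ev = irisid.evaluate_biometrics(rng.normal(0.15, 0.03, 200).clip(0, 1),
                                        rng.normal(0.45, 0.03, 200).clip(0, 1))
        assert np.all(np.diff(ev.far) >= 0)   # FAR grows with threshold
        assert np.all(np.diff(ev.frr) <= 0)   # FRR shrinks with threshold
        assert np.allclose(ev.gar + ev.frr, 1.0)
        assert 0.0 <= ev.eer <= 0.5

    def test_empty_scores_raise(self):
        with pytest.raises(ValueError):
            irisid.evaluate_biometrics([], [0.5])


class TestSerialisation:
    def test_hex_round_trip(self):
        rng = np.random.default_rng(9)
        c = irisid.IrisCode(rng.integers(0, 2, 512), 16, 16, identity="idX")
        back = irisid.code_from_hex(irisid.code_to_hex(c), 16, 16, identity="idX")
        assert np.array_equal(c.bits, back.bits)

    def test_gallery_round_trip(self, tmp_path):
        rng = np.random.default_rng(10)
        codes = [irisid.IrisCode(rng.integers(0, 2, 512), 16, 16,
                                 identity=f"id{i}") for i in range(4)]
        path = tmp_path / "gallery.jsonl"
        irisid.write_gallery(codes, path)
        back = irisid.read_gallery(path)
        assert [c.identity for c in back] == [c.identity for c in codes]
        for a, b in zip(codes, back):
            assert np.array_equal(a.bits, b.bits)
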