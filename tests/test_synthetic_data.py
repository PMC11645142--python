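"""Generator contracts: determinism, geometric consistency, conservation,
realized correlations and class proportions."""

import numpy as np
import pytest

import apicoloc as ap
from apicoloc.images import InfeasibleSpecError, translate


class TestGenerateTissue:
    def test_determinism_bit_identical(self):
        a_ch, a_gt = ap.generate_tissue(ap.TissueSpec(seed=5))
        b_ch, b_gt = ap.generate_tissue(ap.TissueSpec(seed=5))
        for name in a_ch:
            assert np.array_equal(a_ch[name].pixels, b_ch[name].pixels)
        for name in a_gt.masks:
            assert np.array_equal(a_gt.masks[name], b_gt.masks[name])
        assert a_gt.params["umod_positive"] == b_gt.params["umod_positive"]

    def test_masks_partition_each_tubule(self, clean_tissue):
        _, _, gt = clean_tissue
        lumen, apical, intra = (gt.masks[k] for k in
                                ("lumen", "apical", "intracellular"))
        tubule = gt.masks["tubule"]
        assert not (lumen & apical).any()
        assert not (lumen & intra).any()
        assert not (apical & intra).any()
        assert np.array_equal(lumen | apical | intra, tubule)

    def test_apical_fraction_one_puts_all_cargo_in_band(self):
        spec = ap.TissueSpec(seed=9, apical_fraction=1.0, noise_sd=0.0,
                             psf_sigma_um=0.0)
        ch, gt = ap.generate_tissue(spec)
        cargo = ch["UMOD"].pixels - spec.background_level
        outside_band = ~gt.masks["apical"] & ~gt.masks["lumen"]
        assert np.all(cargo[outside_band] == 0)
        assert cargo[gt.masks["apical"]].sum() > 0

    def test_apical_fraction_half_splits_cargo_sum_equally(self):
        spec = ap.TissueSpec(seed=11, apical_fraction=0.5, noise_sd=0.0,
                             psf_sigma_um=0.0)
        ch, gt = ap.generate_tissue(spec)
        cargo = ch["UMOD"].pixels - spec.background_level
        s_ap = cargo[gt.masks["apical"]].sum()
        s_in = cargo[gt.masks["intracellular"]].sum()
        assert s_ap == pytest.approx(s_in, rel=0.01)

    def test_cargo_conservation(self):
        # total rendered cargo equals signal_level x apical-band pixel count
        spec = ap.TissueSpec(seed=13, apical_fraction=0.3, noise_sd=0.0,
                             psf_sigma_um=0.0)
        ch, gt = ap.generate_tissue(spec)
        cargo = ch["UMOD"].pixels - spec.background_level
        n_designated = gt.masks["apical"].sum()
        assert cargo.sum() == pytest.approx(spec.signal_level * n_designated,
                                            rel=1e-9)

    def test_no_positive_tubules_means_background_only(self):
        spec = ap.TissueSpec(seed=15, umod_positive_fraction=0.0, noise_sd=0.0,
                             psf_sigma_um=0.0)
        ch, gt = ap.generate_tissue(spec)
        inside = gt.masks["tubule"]
        assert np.all(ch["UMOD"].pixels[inside] == spec.background_level)

    def test_tubule_centers_respect_minimum_spacing(self, clean_tissue):
        spec, _, gt = clean_tissue
        centers = np.asarray(gt.params["tubule_centers_px"])
        d = np.sqrt(((centers[:, None] - centers[None]) ** 2).sum(-1))
        d[np.diag_indices_from(d)] = np.inf
        min_sep = 2 * spec.tubule_outer_radius_um / spec.pixel_size_um
        assert d.min() >= min_sep

    @pytest.mark.parametrize("bad", [
        dict(lumen_radius_um=12.0, apical_band_um=3.0, tubule_outer_radius_um=14.0),
        dict(apical_fraction=1.5),
        dict(pixel_size_um=-1.0),
        dict(n_tubules=500),  # cannot be placed without overlap
    ])
    def test_infeasible_specs_are_rejected(self, bad):
        with pytest.raises(InfeasibleSpecError):
            ap.generate_tissue(ap.TissueSpec(seed=1, **bad))


class TestGenerate4iStack:
    def test_determinism_bit_identical(self):
        spec = dict(seed=3, image_size_px=(192, 192), n_cells=9, noise_sd=5.0,
                    max_shift_px=8)
        a, _ = ap.generate_4i_stack(ap.FourISpec(**spec))
        b, _ = ap.generate_4i_stack(ap.FourISpec(**spec))
        for ia, ib in zip(a.iter_images(), b.iter_images()):
            assert np.array_equal(ia.pixels, ib.pixels)

    def test_cycles_are_translations_of_cycle_one(self, small_4i):
        spec, stack, gt = small_4i
        d1 = stack.get(1, "DAPI").pixels
        for c, (dy, dx) in enumerate(gt.params["cycle_shifts_px"], start=1):
            expect = translate(d1, dy, dx, fill=spec.background_level)
            assert np.array_equal(stack.get(c, "DAPI").pixels, expect)

    def test_perfect_correlation_for_rho_one(self):
        spec = ap.FourISpec(
            seed=21, image_size_px=(256, 256), n_cells=9, n_cycles=1,
            noise_sd=0.0, target_correlations={("A", "B"): 1.0},
            channel_plan=[["DAPI", "A", "B"]])
        stack, gt = ap.generate_4i_stack(spec)
        a = stack.get(1, "A").pixels
        b = stack.get(1, "B").pixels
        cells = gt.labels["cells"] > 0
        r = np.corrcoef(a[cells], b[cells])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_target_correlation_realized_within_tolerance(self):
        # large cells so each has >= 1e4 pixels
        spec = ap.FourISpec(
            seed=23, image_size_px=(512, 512), n_cells=4, n_cycles=1,
            cell_radius_um=12.0, nucleus_radius_um=4.0, noise_sd=2.0,
            target_correlations={("A", "B"): 0.6},
            channel_plan=[["DAPI", "A", "B"]])
        stack, gt = ap.generate_4i_stack(spec)
        cells = gt.labels["cells"]
        assert (np.bincount(cells.ravel())[1:] >= 1e4).all()
        a, b = stack.get(1, "A").pixels, stack.get(1, "B").pixels
        r = np.corrcoef(a[cells > 0], b[cells > 0])[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)

    def test_compartment_cargo_split_matches_spec(self, small_4i):
        spec, _, gt = small_4i
        cargo = gt.masks["cargo"]
        for comp, frac in spec.compartment_fractions.items():
            got = (cargo & gt.masks[f"compartment_{comp}"]).sum() / cargo.sum()
            assert got == pytest.approx(frac, abs=0.02)

    def test_z_projection_reconstructs_scene(self):
        kw = dict(seed=3, n_cycles=2, cycle_shifts_px=[(0, 0), (3, 2)],
                  noise_sd=0.0, n_cells=9, image_size_px=(256, 256))
        zstack, _ = ap.generate_4i_stack(ap.FourISpec(n_z=5, **kw))
        flat, _ = ap.generate_4i_stack(ap.FourISpec(n_z=1, **kw))
        proj = ap.project_stack(zstack)
        for c in (1, 2):
            assert np.allclose(proj.get(c, "DAPI").pixels,
                               flat.get(c, "DAPI").pixels)

    def test_unrealizable_correlation_matrix_rejected(self):
        spec = ap.FourISpec(
            seed=1, n_cycles=1, n_cells=4, image_size_px=(192, 192),
            target_correlations={("A", "B"): 0.9, ("B", "C"): 0.9,
                                 ("A", "C"): -0.9},
            channel_plan=[["DAPI", "A", "B", "C"]])
        with pytest.raises(InfeasibleSpecError):
            ap.generate_4i_stack(spec)

    def test_shift_exceeding_declared_maximum_rejected(self):
        with pytest.raises(InfeasibleSpecError):
            ap.generate_4i_stack(ap.FourISpec(
                seed=1, n_cycles=2, cycle_shifts_px=[(0, 0), (99, 0)],
                max_shift_px=10))


class TestBimodalField:
    def test_two_separated_modes(self):
        img = ap.generate_bimodal_field(50, 200, 1.0, 0.5, (128, 128), seed=1)
        v = img.pixels
        assert ((v < 60) | (v > 190)).all()
        assert (v < 60).any() and (v > 190).any()

    def test_class_proportions(self):
        img = ap.generate_bimodal_field(50, 200, 20.0, 0.3, (1000, 1000), seed=2)
        low = (img.pixels < 125).mean()
        assert low == pytest.approx(0.3, abs=0.02)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(InfeasibleSpecError):
            ap.generate_bimodal_field(50, 200, 0.0, 0.5, (8, 8), seed=1)
        with pytest.raises(InfeasibleSpecError):
            ap.generate_bimodal_field(50, 200, 1.0, 1.5, (8, 8), seed=1)

    def test_equal_means_unimodal_field_thresholds_do_not_crash(self):
        img = ap.generate_bimodal_field(100, 100, 5.0, 0.5, (64, 64), seed=3)
        ap.threshold_otsu2(img)
        ap.threshold_min_cross_entropy(img)
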