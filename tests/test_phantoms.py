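"""Phantom, tumor and prior generation."""

import numpy as np
import pytest
from scipy import ndimage

from csinet.constants import DEFAULT_TISSUE_TABLE, LABEL_EXTERIOR, LABEL_FAT, \
    LABEL_FIBROGLANDULAR, LABEL_SKIN, LABEL_TUMOR
from csinet.csi import contrast_of
from csinet.phantoms import (assign_permittivity, generate_dataset, grow_tumor,
                             load_phantom, make_base_model, make_phantom,
                             make_prior)


class TestBaseModels:
    def test_fatty_model_dimensions(self):
        lab = make_base_model("II", (128, 128), 0.1, np.random.default_rng(7))
        breast = lab.labels != LABEL_EXTERIOR
        rows = np.flatnonzero(breast.any(axis=1))
        cols = np.flatnonzero(breast.any(axis=0))
        width_px = cols[-1] - cols[0] + 1
        height_px = rows[-1] - rows[0] + 1
        assert abs(width_px - 112) <= 3
        assert abs(height_px - 96) <= 3

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="I, II, III"):
            make_base_model("IV", (64, 64), 0.2, np.random.default_rng(0))

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_base_model("II", (32, 32), 0.1, np.random.default_rng(0))

    def test_density_class_ordering(self):
        """Fibroglandular area fraction: fatty < heterogeneously dense < very dense."""
        fracs = {}
        for model in ("I", "II", "III"):
            vals = []
            for seed in range(12):
                lab = make_base_model(model, (64, 64), 0.2, np.random.default_rng(seed))
                interior = np.isin(lab.labels, (LABEL_FAT, LABEL_FIBROGLANDULAR))
                vals.append((lab.labels == LABEL_FIBROGLANDULAR).sum() / interior.sum())
            fracs[model] = np.mean(vals)
        assert fracs["II"] < fracs["I"] < fracs["III"]

    def test_deterministic_given_seed(self):
        a = make_base_model("I", (64, 64), 0.2, np.random.default_rng(5))
        b = make_base_model("I", (64, 64), 0.2, np.random.default_rng(5))
        np.testing.assert_array_equal(a.labels, b.labels)

    @pytest.mark.parametrize("model", ["I", "II", "III"])
    def test_skin_ring_closed(self, model):
        """Flood fill from the border never reaches interior tissue without
        crossing skin."""
        lab = make_base_model(model, (64, 64), 0.2, np.random.default_rng(3)).labels
        passable = lab != LABEL_SKIN
        comp, _ = ndimage.label(passable)
        border_comps = set(comp[0]) | set(comp[-1]) | set(comp[:, 0]) | set(comp[:, -1])
        interior = np.isin(lab, (LABEL_FAT, LABEL_FIBROGLANDULAR))
        assert not np.isin(comp[interior], list(border_comps)).any()


class TestTumorGrowth:
    @pytest.fixture(scope="class")
    def labels(self):
        return make_base_model("I", (64, 64), 0.2, np.random.default_rng(11))

    def test_single_pixel_when_max_diameter_is_one_pixel(self, labels):
        mask = grow_tumor(labels, labels.pixel_size, np.random.default_rng(0))
        assert mask.sum() == 1

    def test_masks_inside_fibroglandular_and_bounded(self, labels):
        px = labels.pixel_size
        for seed in range(50):
            rng = np.random.default_rng(seed)
            dmax = rng.uniform(1.1, 1.5)
            mask = grow_tumor(labels, dmax, rng)
            assert (labels.labels[mask] == LABEL_FIBROGLANDULAR).all()
            pts = np.argwhere(mask).astype(float)
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)).max() * px
            assert d <= dmax <= 1.5
            # 4-connectivity
            lab, n = ndimage.label(mask)
            assert n == 1

    def test_random_location(self, labels):
        cents = set()
        for seed in range(10):
            mask = grow_tumor(labels, 1.3, np.random.default_rng(seed))
            cents.add(tuple(np.round(ndimage.center_of_mass(mask), 1)))
        assert len(cents) >= 2

    def test_too_small_region_rejected(self):
        lab = make_base_model("II", (64, 64), 0.2, np.random.default_rng(1))
        lab.labels[lab.labels == LABEL_FIBROGLANDULAR] = LABEL_FAT
        with pytest.raises(ValueError, match="too small"):
            grow_tumor(lab, 1.2, np.random.default_rng(0))


class TestPermittivityAssignment:
    @pytest.fixture(scope="class")
    def labels(self):
        lab = make_base_model("I", (64, 64), 0.2, np.random.default_rng(2))
        tumor = grow_tumor(lab, 1.4, np.random.default_rng(3))
        return lab, tumor

    def test_zero_texture_is_exact(self, labels):
        lab, tumor = labels
        table = dict(DEFAULT_TISSUE_TABLE)
        table[LABEL_TUMOR] = 50.0 - 10.0j
        p = assign_permittivity(lab, table, texture_level=0.0,
                                rng=np.random.default_rng(0), tumor_mask=tumor)
        assert (p.eps_real[p.tumor_mask] == 50.0).all()
        assert (p.eps_imag[p.tumor_mask] == 10.0).all()

    def test_exterior_is_background(self, labels):
        lab, tumor = labels
        p = assign_permittivity(lab, texture_level=0.1,
                                rng=np.random.default_rng(0), tumor_mask=tumor)
        ext = p.labels.labels == LABEL_EXTERIOR
        assert (p.eps[ext] == DEFAULT_TISSUE_TABLE[LABEL_EXTERIOR]).all()

    def test_texture_preserves_tissue_means(self, labels):
        lab, tumor = labels
        p = assign_permittivity(lab, texture_level=0.1,
                                rng=np.random.default_rng(1), tumor_mask=tumor)
        for code in (LABEL_SKIN, LABEL_FAT, LABEL_FIBROGLANDULAR):
            sel = p.labels.labels == code
            ref = DEFAULT_TISSUE_TABLE[code].real
            assert abs(p.eps_real[sel].mean() - ref) / ref < 0.03

    def test_missing_label_rejected(self, labels):
        lab, tumor = labels
        table = {k: v for k, v in DEFAULT_TISSUE_TABLE.items() if k != LABEL_TUMOR}
        with pytest.raises(ValueError, match="missing"):
            assign_permittivity(lab, table, tumor_mask=tumor)


class TestPrior:
    @pytest.fixture(scope="class")
    def phantom(self):
        rng = np.random.default_rng(8)
        lab = make_base_model("I", (64, 64), 0.2, rng)
        tumor = grow_tumor(lab, 1.4, rng)
        return assign_permittivity(lab, texture_level=0.0, rng=rng, tumor_mask=tumor)

    def test_exact_prior_differs_only_at_tumor(self, phantom):
        prior = make_prior(phantom, 0.0, 0.0, np.random.default_rng(0))
        diff = prior.eps_n != phantom.eps
        np.testing.assert_array_equal(diff, phantom.tumor_mask)
        fib = DEFAULT_TISSUE_TABLE[LABEL_FIBROGLANDULAR]
        assert (prior.eps_n[phantom.tumor_mask] == fib).all()

    def test_exact_prior_gives_zero_contrast_off_tumor(self, phantom):
        prior = make_prior(phantom, 0.0, 0.0, np.random.default_rng(0))
        chi = contrast_of(phantom.eps, prior.eps_n)
        assert np.abs(chi[~phantom.tumor_mask]).max() == 0.0
        assert np.abs(chi[phantom.tumor_mask]).min() > 0.1

    def test_prior_never_contains_tumor_label(self, phantom):
        for seed in range(5):
            prior = make_prior(phantom, 2.0, 0.05, np.random.default_rng(seed))
            assert not (prior.region_labels.labels == LABEL_TUMOR).any()

    def test_jittered_prior_mostly_agrees(self, phantom):
        prior = make_prior(phantom, 2.0, 0.05, np.random.default_rng(1))
        ref = phantom.labels.labels.copy()
        ref[phantom.tumor_mask] = LABEL_FIBROGLANDULAR
        agree = (prior.region_labels.labels == ref).mean()
        assert agree >= 0.95


class TestDatasetGeneration:
    def test_one_phantom_per_model(self, tmp_path):
        manifest = generate_dataset(1, 0, 3, tmp_path, grid_shape=(64, 64),
                                    pixel_size=0.2)
        assert len(manifest.entries) == 3
        assert sorted(e["model_id"] for e in manifest.entries) == ["I", "II", "III"]

    def test_counts_and_balanced_folds(self, tmp_path):
        manifest = generate_dataset(4, 4, 11, tmp_path, grid_shape=(64, 64),
                                    pixel_size=0.2)
        assert len(manifest.entries) == 24
        n1 = sum(e["n_tumors"] == 1 for e in manifest.entries)
        assert n1 == 12
        from collections import Counter
        c = Counter((e["fold"], e["model_id"]) for e in manifest.entries)
        assert all(v == 2 for v in c.values())

    def test_reproducible_from_master_seed(self, tmp_path):
        m1 = generate_dataset(1, 1, 5, tmp_path / "a", grid_shape=(64, 64),
                              pixel_size=0.2)
        m2 = generate_dataset(1, 1, 5, tmp_path / "b", grid_shape=(64, 64),
                              pixel_size=0.2)
        for e1, e2 in zip(m1.entries, m2.entries):
            p1, _ = load_phantom(tmp_path / "a" / e1["path"])
            p2, _ = load_phantom(tmp_path / "b" / e2["path"])
            np.testing.assert_array_equal(p1.eps_real, p2.eps_real)
            np.testing.assert_array_equal(p1.labels.labels, p2.labels.labels)

    def test_two_tumor_phantoms_have_two_components(self, tmp_path):
        manifest = generate_dataset(0, 2, 9, tmp_path, grid_shape=(64, 64),
                                    pixel_size=0.2)
        for e in manifest.entries:
            p, _ = load_phantom(tmp_path / e["path"])
            _, n = ndimage.label(p.tumor_mask)
            assert n == 2 and p.n_tumors == 2

    def test_negative_counts_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(-1, 0, 0, tmp_path)


def test_make_phantom_tumors_inside_fibroglandular(small_phantom):
    assert small_phantom.tumor_mask.sum() > 0
    assert (small_phantom.labels.labels[small_phantom.tumor_mask] == LABEL_TUMOR).all()
    assert small_phantom.eps_imag.min() >= 0.0
    assert (small_phantom.eps_real[small_phantom.labels.labels > 0] >= 1.0).all()
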