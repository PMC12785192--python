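"""The synthetic generator: determinism, ground-truth consistency, cohorts."""

import numpy as np
import pytest

from cotyquant import morphometry as mm, necrosis as nx, pipeline as pl, synthetic as syn


def test_leaf_image_deterministic_under_seed():
    leaf = syn.LeafSpec()
    lesions = [syn.Lesion((0.1, 0.4), 20.0)]
    a, _ = syn.make_leaf_image(leaf, lesions, noise_sd=4.0, seed=42)
    b, _ = syn.make_leaf_image(leaf, lesions, noise_sd=4.0, seed=42)
    c, _ = syn.make_leaf_image(leaf, lesions, noise_sd=4.0, seed=43)
    assert (a.pixels == b.pixels).all()
    assert (a.pixels != c.pixels).any()


def test_noise_free_recovery_is_exact(simple_leaf):
    leaf, record, truth = simple_leaf
    meas, _ = nx.measure_necrosis(record, spot_floor=1000)
    assert meas.total_dead_area_px == truth.total_lesion_px
    area, centroid = truth.largest_spot(1000)
    assert meas.largest_spot_area_px == area
    assert np.hypot(*(np.subtract(meas.largest_spot_centroid, centroid))) < 1.0


def test_zero_lesions_zero_signal():
    rec, truth = syn.make_leaf_image(syn.LeafSpec(), [], seed=0)
    meas, _ = nx.measure_necrosis(rec)
    assert meas.total_dead_area_px == 0 and not meas.has_spot
    assert truth.total_lesion_px == 0


def test_lesion_clipped_to_leaf_updates_truth():
    leaf = syn.LeafSpec()
    rec, truth = syn.make_leaf_image(
        leaf, [syn.Lesion((0.0, 0.97), 30.0)], seed=0
    )
    full_disk = np.pi * 30.0**2
    assert truth.lesion_pixel_counts[0] < 0.8 * full_disk  # clipped at the tip
    assert not (truth.lesion_mask & ~truth.leaf_mask).any()
    meas, _ = nx.measure_necrosis(rec, spot_floor=100)
    assert meas.total_dead_area_px == truth.total_lesion_px


def test_colors_validated_against_stain_box():
    leaf = syn.LeafSpec(leaf_color=(70, 70, 160))  # stain-colored leaf: invalid
    with pytest.raises(ValueError, match="outside"):
        syn.make_leaf_image(leaf, [], seed=0)
    with pytest.raises(ValueError, match="inside"):
        syn.make_leaf_image(
            syn.LeafSpec(), [syn.Lesion((0, 0), 10.0, color=(255, 255, 255))], seed=0
        )


def test_leaf_must_fit_in_frame():
    with pytest.raises(ValueError, match="fit"):
        syn.make_leaf_image(syn.LeafSpec(size=(128, 128)), [], seed=0)


def test_recovery_degrades_gracefully_with_noise():
    """Area recovery error grows with noise without a cliff below sd=8."""
    leaf = syn.LeafSpec()
    lesions = [syn.Lesion((0.0, 0.5), 25.0), syn.Lesion((0.3, -0.3), 15.0)]
    errors = []
    for sd in (0.0, 2.0, 4.0, 6.0, 8.0):
        rec, truth = syn.make_leaf_image(leaf, lesions, noise_sd=sd, seed=5)
        meas, _ = nx.measure_necrosis(rec)
        errors.append(abs(meas.total_dead_area_px - truth.total_lesion_px)
                      / truth.total_lesion_px)
    assert errors[0] == 0.0
    assert all(e < 0.25 for e in errors)
    assert max(np.diff(errors)) < 0.15  # no cliff between successive levels


def test_callose_image_deterministic_and_truth():
    a, ta = syn.make_callose_image(n_puncta=4, seed=8)
    b, tb = syn.make_callose_image(n_puncta=4, seed=8)
    assert (a.pixels == b.pixels).all() and ta.puncta_count == tb.puncta_count
    none, t0 = syn.make_callose_image(n_puncta=0, seed=8)
    assert t0.puncta_count == 0


def test_callose_merged_puncta_truth_at_observable_level():
    _, truth = syn.make_callose_image(n_puncta=12, min_separation=0.0, seed=2,
                                      size=120)
    assert truth.puncta_count <= 12  # merges collapse to single components


def test_callose_density_scales_with_pixel_size():
    from cotyquant import callose as cq

    rec1, _ = syn.make_callose_image(n_puncta=5, seed=3, pixel_size_um=2.0)
    rec2, _ = syn.make_callose_image(n_puncta=5, seed=3, pixel_size_um=4.0)
    thr = cq.PunctaThreshold(60, 1, 1, 1e-4)
    d1 = cq.count_puncta(rec1, thr)
    d2 = cq.count_puncta(rec2, thr)
    assert d1.spot_count == d2.spot_count
    assert d2.density_per_mm2 == pytest.approx(d1.density_per_mm2 / 4.0)


def test_cohort_shape_and_sheet():
    spec = syn.default_cohort_spec(master_seed=1, image_size=256, n_per_cell=2,
                                   days=(4, 5), ca_mM=(0.2, 0.1))
    cohort = syn.make_cohort(spec)
    assert len(cohort.leaf_images) == 2 * 2 * 2 * 2
    assert len(cohort.sheet) == len(cohort.leaf_images)
    assert set(cohort.sheet["genotype"]) == {"Col-0", "gsl10-5"}
    assert cohort.sheet["image_id"].is_unique
    assert set(cohort.sheet["experiment"]) == {"exp1", "exp2"}


def test_default_cohort_is_study_shaped():
    spec = syn.default_cohort_spec()
    assert spec.genotypes == ("Col-0", "gsl10-5")
    assert spec.days == (4, 5, 6, 7) and spec.ca_mM == (0.2, 0.1)
    assert spec.n_per_cell == 15
    # 2 genotypes x 4 days x 2 Ca x 15 = 240 images
    n = len(spec.genotypes) * len(spec.days) * len(spec.ca_mM) * spec.n_per_cell
    assert n == 240


def test_cohort_deterministic_and_seed_sensitive():
    kw = dict(image_size=256, n_per_cell=2, days=(4,), ca_mM=(0.2,))
    a = syn.make_cohort(syn.default_cohort_spec(master_seed=7, **kw))
    b = syn.make_cohort(syn.default_cohort_spec(master_seed=7, **kw))
    c = syn.make_cohort(syn.default_cohort_spec(master_seed=8, **kw))
    for (ra, _), (rb, _) in zip(a.leaf_images, b.leaf_images):
        assert (ra.pixels == rb.pixels).all()
    assert any(
        (ra.pixels != rc.pixels).any()
        for (ra, _), (rc, _) in zip(a.leaf_images, c.leaf_images)
    )


def test_cohort_write_to_disk_roundtrip(tmp_path):
    from cotyquant import image_io

    spec = syn.default_cohort_spec(master_seed=2, image_size=256, n_per_cell=1,
                                   days=(4,), ca_mM=(0.2,))
    cohort = syn.make_cohort(spec, out_dir=tmp_path)
    sheet = image_io.read_sample_sheet(tmp_path / "samples.csv")
    assert len(sheet) == 2
    rec0, _ = cohort.leaf_images[0]
    row = sheet[sheet["image_id"] == rec0.image_id].iloc[0]
    loaded = image_io.load_image(row["path"], row)
    assert (loaded.pixels == rec0.pixels).all()
    assert (tmp_path / f"{rec0.image_id}.truth.json").exists()


def test_y_rel_difference_recovered_end_to_end():
    """Mean largest-spot y_rel difference tracks the generating laws."""
    params = {
        "Col-0": syn.GenotypeParams(law=syn.PositionalLaw(mu_y=0.6, sigma_y=0.2)),
        "gsl10-5": syn.GenotypeParams(law=syn.PositionalLaw(mu_y=0.0, sigma_y=0.2)),
    }
    spec = syn.default_cohort_spec(
        master_seed=5, days=(4, 5), ca_mM=(0.2,), n_per_cell=10,
        image_size=256, params=params,
    )
    cohort = syn.make_cohort(spec)
    # at 256 px the pixel-size thresholds scale with the frame area
    table = pl.quantify_necrosis_cohort(
        [r for r, _ in cohort.leaf_images], min_area=9, spot_floor=444
    )
    diff = (
        table[table["genotype"] == "Col-0"]["y_rel"].mean()
        - table[table["genotype"] == "gsl10-5"]["y_rel"].mean()
    )
    assert abs(diff - 0.6) < 0.1
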