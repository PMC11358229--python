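"""Center-surround saliency maps, the grid saliency index, image motion."""

import numpy as np
import pytest

from emosearch.salience import (
    IttiKochSaliency,
    SaliencyMap,
    compute_saliency_map,
    image_motion,
    run_salience_simulation,
    saliency_index,
)
from emosearch.stimuli import GridLayout, generate_display, neutral_patch


@pytest.fixture(scope="module")
def model():
    return IttiKochSaliency()


def _disc_image(cy=90, cx=200, radius=20, size=288):
    img = np.zeros((size, size))
    yy, xx = np.mgrid[:size, :size]
    img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = 1.0
    return img


def test_uniform_image_yields_null_map(model):
    smap = model.transform(np.full((288, 288), 0.4))
    assert smap.values.max() <= 1e-9


def test_disc_attracts_global_maximum(model):
    smap = model.transform(_disc_image())
    iy, ix = np.unravel_index(np.argmax(smap.values), smap.values.shape)
    assert (iy - 90) ** 2 + (ix - 200) ** 2 <= 26**2


def test_mirrored_image_gives_mirrored_activations(model):
    img = _disc_image(cy=144, cx=80, radius=16)
    mirrored = img[:, ::-1]
    a = model.transform(img).values
    b = model.transform(mirrored).values
    # total activation in the disc region equals that of the mirrored disc
    act_a = a[128:160, 64:96].sum()
    act_b = b[128:160, 192:224].sum()
    assert act_b == pytest.approx(act_a, rel=0.01)


def test_color_opponency_channel_sees_isoluminant_contrast(model):
    # red disc on green background, matched intensity -> only the color
    # channel can flag it
    size = 288
    img = np.zeros((size, size, 3))
    img[..., 1] = 0.5
    yy, xx = np.mgrid[:size, :size]
    disc = (yy - 144) ** 2 + (xx - 144) ** 2 <= 20**2
    img[disc, 0], img[disc, 1] = 0.5, 0.0
    smap = model.transform(img)
    assert "color" in smap.conspicuity
    iy, ix = np.unravel_index(np.argmax(smap.values), smap.values.shape)
    assert (iy - 144) ** 2 + (ix - 144) ** 2 <= 30**2


def test_input_validation(model):
    with pytest.raises(ValueError):
        model.transform(np.full((64, 64), 0.5))  # too small for the pyramid
    bad = np.full((288, 288), 0.5)
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        model.transform(bad)
    with pytest.raises(ValueError):
        model.transform(np.full((288, 288), 1.5))
    with pytest.raises(ValueError):
        SaliencyMap(values=-np.ones((4, 4)))


def test_identical_patch_display_index_near_one(model):
    for slot in (0, 4):
        lay = GridLayout.regular(target_slot=slot)
        disp = generate_display(lay, [neutral_patch()] * 9, rng=0)
        res = saliency_index(model.transform(disp.image), disp.layout)
        assert res.saliency_index == pytest.approx(1.0, abs=0.01)


def test_index_is_exact_ratio_of_region_activations():
    lay = GridLayout.regular(target_slot=4)
    values = np.zeros((288, 288))
    for i, (t, l, h, w) in enumerate(lay.rects):
        values[t : t + h, l : l + w] = 2.0 if i == 4 else 1.0
    res = saliency_index(SaliencyMap(values=values), lay)
    assert res.saliency_index == pytest.approx(2.0)
    np.testing.assert_allclose(res.activations[4], 2 * res.activations[0])


def test_high_contrast_target_raises_index(model):
    patches = [neutral_patch()] * 9
    patches[2] = neutral_patch(contrast=2.0)
    lay = GridLayout.regular(target_slot=2)
    disp = generate_display(lay, patches, rng=0)
    res = saliency_index(model.transform(disp.image), disp.layout)
    assert res.saliency_index > 1.2


def test_index_invariant_to_global_intensity_rescaling(model):
    patches = [neutral_patch()] * 9
    patches[6] = neutral_patch(contrast=1.5)
    lay = GridLayout.regular(target_slot=6)
    disp = generate_display(lay, patches, rng=0)
    r1 = saliency_index(model.transform(disp.image), disp.layout)
    r2 = saliency_index(model.transform(disp.image * 0.5), disp.layout)
    assert r2.saliency_index == pytest.approx(r1.saliency_index, rel=0.02)


def test_index_requires_target_and_nondegenerate_map():
    lay = GridLayout.regular()
    with pytest.raises(ValueError, match="target"):
        saliency_index(SaliencyMap(values=np.ones((288, 288))), lay)
    lay = GridLayout.regular(target_slot=0)
    with pytest.raises(ValueError, match="degenerate"):
        saliency_index(SaliencyMap(values=np.zeros((288, 288))), lay)
    with pytest.raises(ValueError, match="shape"):
        saliency_index(SaliencyMap(values=np.ones((64, 64))), lay)


def test_simulation_deterministic_and_well_formed():
    targets = {"angry": [neutral_patch(1.2)], "happy": [neutral_patch(0.8)]}
    distractors = [neutral_patch(float(c)) for c in np.linspace(0.9, 1.1, 10)]
    lay = GridLayout.regular(jitter=6.0)
    t1, s1 = run_salience_simulation(targets, distractors, 6, rng_seed=3, layout=lay)
    t2, s2 = run_salience_simulation(targets, distractors, 6, rng_seed=3, layout=lay)
    assert t1.equals(t2)
    assert s1["mean_difference"] == s2["mean_difference"]
    assert set(t1.columns) == {"replicate", "emotion", "target_slot", "index"}
    assert len(t1) == 12
    assert t1.target_slot.between(0, 8).all()
    assert (t1["index"] > 0).all()
    # higher-contrast targets really are more salient on average
    assert s1["mean_index_angry"] > s1["mean_index_happy"]


def test_simulation_validation():
    with pytest.raises(ValueError):
        run_salience_simulation({}, [neutral_patch()], 5)
    with pytest.raises(ValueError):
        run_salience_simulation({"a": [neutral_patch()]}, [neutral_patch()], 0)


# -- image motion ------------------------------------------------------------


def test_motion_zero_for_identical_frames(rng):
    f = rng.uniform(size=(200, 200))
    assert image_motion(f, f) == 0.0


def test_motion_single_block_closed_form():
    a = np.zeros((200, 200))
    b = a.copy()
    b[:20, :20] += 0.1
    assert image_motion(a, b) == pytest.approx(0.1 * 400)
    assert image_motion(a, b, normalized=True) == pytest.approx(0.1 * 400 / 100)


def test_motion_symmetric_and_triangle_bound(rng):
    a, b, c = (rng.uniform(size=(120, 120)) for _ in range(3))
    assert image_motion(a, b) == image_motion(b, a)
    assert image_motion(a, c) <= image_motion(a, b) + image_motion(b, c) + 1e-9


def test_motion_whole_block_translation_preserves_total_sum():
    a = np.zeros((100, 100))
    a[:20, :20] = 0.5
    b = np.zeros((100, 100))
    b[:20, 20:40] = 0.5
    from skimage.measure import block_reduce

    ra = block_reduce(a, (20, 20), np.sum)
    rb = block_reduce(b, (20, 20), np.sum)
    assert ra.sum() == rb.sum()
    assert image_motion(a, b) == pytest.approx(2 * 0.5 * 400)


def test_motion_validation():
    with pytest.raises(ValueError):
        image_motion(np.zeros((10, 10)), np.zeros((12, 10)))
    with pytest.raises(ValueError):
        image_motion(np.zeros((10, 10, 3)), np.zeros((10, 10, 3)))
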