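import numpy as np
import pytest

from dcect_radiomics.phantom import PhantomSpec


def desk_spec(**kw):
    """Desk-scale phantom: 4 axial slices, 64x64 in-plane, 2/7/7 sequences."""
    base = dict(grid_shape=(4, 64, 64), lesion_radii=(10.0, 9.0, 9.0),
                n_nce=2, n_lap=7, n_pvp=7)
    base.update(kw)
    return PhantomSpec(**base)


def jittered_spec(**kw):
    """Desk-scale phantom with the cohort-level patient variability on."""
    base = dict(baseline_jitter_sd=6.0, amplitude_jitter_sd=0.2,
                radii_jitter_frac=0.15)
    base.update(kw)
    return desk_spec(**base)


@pytest.fixture
def sphere_mask():
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in (4, 64, 64)], indexing="ij")
    return (((zz - 1.5) / 8) ** 2 + ((yy - 32) / 10) ** 2 + ((xx - 32) / 10) ** 2) <= 1


@pytest.fixture
def textured_voi(sphere_mask):
    """A noisy lesion volume + spherical mask, fixed seed."""
    rng = np.random.default_rng(42)
    vol = 60 + rng.standard_normal(sphere_mask.shape) * 4
    vol[sphere_mask] += 40 + rng.standard_normal(int(sphere_mask.sum())) * 12
    return vol, sphere_mask


def random_small_quantized(rng, max_side=8, n_slices=3, n_levels=4):
    """Random quantized volume <= 8x8x3 with a random nonempty mask."""
    from dcect_radiomics.features.quantize import QuantizedVolume
    h = int(rng.integers(3, max_side + 1))
    w = int(rng.integers(3, max_side + 1))
    z = int(rng.integers(1, n_slices + 1))
    labels = rng.integers(1, n_levels + 1, size=(z, h, w))
    mask = rng.random((z, h, w)) < 0.8
    if not mask.any():
        mask[0, 0, 0] = True
    labels = np.where(mask, labels, 0)
    return QuantizedVolume(labels=labels, mask=mask,
                           n_levels=int(labels.max()) if labels.max() else 1,
                           bin_width=25.0, min_in_mask=0.0)
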