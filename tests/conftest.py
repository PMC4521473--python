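import numpy as np
import pytest

from organoscreen.segmentation import SectionMask
from organoscreen.synthetic import OrganoidSpec, render_well_stack


def disk_mask(radius: int, center: tuple[int, int] = (0, 0)) -> SectionMask:
    """Digital disk: pixels whose centers lie within `radius` of the center."""
    cx, cy = center
    r = int(np.ceil(radius)) + 1
    xs, ys = np.mgrid[-r:r + 1, -r:r + 1]
    keep = xs**2 + ys**2 <= radius**2
    return SectionMask(0, np.column_stack([xs[keep] + cx, ys[keep] + cy]))


def mask_from_pixels(pixels) -> SectionMask:
    return SectionMask(0, np.asarray(pixels, dtype=np.int64))


@pytest.fixture(scope="session")
def clean_well():
    """A noise-free, blur-free three-organoid well with exact ground truth."""
    specs = [
        OrganoidSpec(center=(60.0, 60.0, 3.0), radius=12, nuclei_count=5,
                     z_halfspan=1.6),
        OrganoidSpec(center=(170.0, 70.0, 3.0), radius=10, n_branches=3,
                     branch_length=12, branch_angles=(0.3, 2.2, 4.4),
                     nuclei_count=5, z_halfspan=1.6),
        OrganoidSpec(center=(110.0, 180.0, 3.0), radius=11, hollow=True,
                     nuclei_placement="boundary", nuclei_count=5, z_halfspan=1.6),
    ]
    stack, truth = render_well_stack(
        specs, geometry=(6, 240, 240), noise_sd=0.0, seed=11)
    return stack, truth


@pytest.fixture(scope="session")
def noisy_well():
    """A realistic well: noise, PSF blur, speckle texture, one defocused section."""
    specs = [
        OrganoidSpec(center=(60.0, 60.0, 3.0), radius=12, nuclei_count=6,
                     z_halfspan=1.6, texture_sd=0.25),
        OrganoidSpec(center=(170.0, 70.0, 3.0), radius=10, n_branches=3,
                     branch_length=12, nuclei_count=6, z_halfspan=1.6,
                     texture_sd=0.25),
        OrganoidSpec(center=(110.0, 180.0, 3.0), radius=11, nuclei_count=6,
                     z_halfspan=1.6, texture_sd=0.25),
    ]
    stack, truth = render_well_stack(
        specs, geometry=(6, 240, 240), noise_sd=150.0, defocus_sections=(0,),
        seed=23, psf_sigma=1.0)
    return stack, truth
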