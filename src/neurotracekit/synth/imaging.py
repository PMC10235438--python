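"""Two-channel nucleus/cytoplasm cell image generator."""

from __future__ import annotations

import numpy as np

from .params import GroundTruth

__all__ = ["simulate_cell_image"]


def simulate_cell_image(
    nuc_intensity: float = 200.0,
    cyto_intensity: float = 100.0,
    geometry: tuple[int, int] = (10, 25),
    noise_sd: float = 0.0,
    seed: int = 0,
    image_size: int = 64,
    stain_intensity: float = 150.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Synthesise a two-channel cell image with known intensity ratio.

    Channel 0 (marker): ``nuc_intensity`` on the nucleus disk,
    ``cyto_intensity`` on the soma annulus, background 0, plus Gaussian
    noise.  Channel 1 (nuclear stain): ``stain_intensity`` on the nucleus
    only.  ``geometry = (nucleus_radius_px, soma_radius_px)``.  Ground truth
    is the programmed nuclear/cytoplasmic ratio.
    """
    nuc_r, soma_r = geometry
    if nuc_r <= 0 or soma_r <= 0:
        raise ValueError("radii must be positive")
    if not nuc_r < soma_r:
        raise ValueError("nucleus radius must be smaller than soma radius")
    if 2 * soma_r >= image_size:
        raise ValueError("soma does not fit in the image")
    rng = np.random.default_rng(seed)
    c = image_size / 2 - 0.5
    yy, xx = np.mgrid[:image_size, :image_size]
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    nucleus = r2 <= nuc_r**2
    soma = r2 <= soma_r**2

    marker = np.zeros((image_size, image_size))
    marker[soma & ~nucleus] = cyto_intensity
    marker[nucleus] = nuc_intensity
    stain = np.where(nucleus, stain_intensity, 0.0)
    image = np.stack([marker, stain])
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    truth = GroundTruth(nuclear_intensity=nuc_intensity,
                        cytoplasmic_intensity=cyto_intensity,
                        nuc_cyto_ratio=nuc_intensity / cyto_intensity)
    return image, truth
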