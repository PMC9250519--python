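import numpy as np
import pytest

from ffpshg.model import CollagenParams, PhantomRegion, PhantomSpec, generate_stack


def region_grid_spec(
    combos,
    tile: int = 8,
    width_tiles: int = 8,
    i0: float = 40.0,
    background: float = 0.0,
    noise_model: str = "none",
    noise_sigma: float = 2.0,
    bit_depth=None,
    seed: int = 0,
) -> PhantomSpec:
    """Phantom with one square tile per (b, c, phi) combination, row-major."""
    n = len(combos)
    rows = (n + width_tiles - 1) // width_tiles
    height, width = rows * tile, width_tiles * tile
    regions = []
    for idx, (b, c, phi) in enumerate(combos):
        r, q = divmod(idx, width_tiles)
        mask = np.zeros((height, width), dtype=bool)
        mask[r * tile : (r + 1) * tile, q * tile : (q + 1) * tile] = True
        regions.append(PhantomRegion(mask, CollagenParams(i0, b, c, phi)))
    return PhantomSpec(
        height=height,
        width=width,
        regions=regions,
        background_level=background,
        noise_model=noise_model,
        noise_sigma=noise_sigma,
        bit_depth=bit_depth,
        seed=seed,
    )


@pytest.fixture
def clean_single_region_stack():
    """Noiseless float phantom: one uniform collagen region, zero background."""
    mask = np.ones((6, 6), dtype=bool)
    spec = PhantomSpec(
        6, 6,
        [PhantomRegion(mask, CollagenParams(1.3, 1.0, 2.0, 30.0))],
        background_level=0.0, noise_model="none", bit_depth=None,
    )
    return generate_stack(spec), spec


@pytest.fixture
def rng():
    return np.random.default_rng(20220702)
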