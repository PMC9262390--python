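import numpy as np
import pytest

from mitopolar import synthgen


@pytest.fixture(scope="session")
def small_config():
    """A small noise-free domain used by several measurement tests."""
    return synthgen.SyntheticDomainConfig(
        n_cells_per_side=6,
        image_size=256,
        noise=synthgen.NoiseModel(gaussian_sd=0.0, poisson=False),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_domain(small_config):
    geometry, truth = synthgen.generate_domain(small_config)
    return geometry, truth


@pytest.fixture(scope="session")
def clean_polarity_image(small_domain, small_config):
    geometry, truth = small_domain
    return synthgen.render_polarity_image(geometry, truth, apply_noise=False)


def square_contour(cx=32.0, cy=32.0, half=10.0, ccw_in_view=True, **kw):
    """An axis-aligned square contour; orientation set in the anterior-up view."""
    from mitopolar.profiles import CellContour

    # (x, row): listed counterclockwise in the y-up view means clockwise in rows
    pts = np.array(
        [
            [cx + half, cy + half],
            [cx + half, cy - half],
            [cx - half, cy - half],
            [cx - half, cy + half],
        ]
    )
    if not ccw_in_view:
        pts = pts[::-1]
    kw.setdefault("cell_id", "sq")
    kw.setdefault("embryo_id", "e")
    kw.setdefault("side", "unassigned")
    return CellContour(vertices=pts, **kw)
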