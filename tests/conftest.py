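import numpy as np
import pytest

from shgmorph import BinaryMask, Fiber, FiberNetwork


@pytest.fixture
def horizontal_ribbon_mask():
    """A 5-row horizontal ribbon spanning the full image width, so every
    center-row pixel is exactly 3 px from the nearest background pixel."""
    m = np.zeros((21, 40), dtype=bool)
    m[8:13, :] = True
    return BinaryMask(labels=m, pixel_size_um=0.554)


def make_fiber(vertices, fid=0):
    return Fiber(vertices=np.asarray(vertices, dtype=float), id=fid)


def make_network(fibers, crosslinks=(), pixel_size_um=1.0):
    return FiberNetwork(
        fibers=tuple(fibers),
        crosslinks=frozenset((int(r), int(c)) for r, c in crosslinks),
        pixel_size_um=pixel_size_um,
    )


@pytest.fixture
def toy_grid_network():
    """3 horizontal x 3 vertical straight fibers of length 30 px each,
    crossing at 9 isolated points 10 px apart."""
    fibers = []
    links = []
    for i, r in enumerate((5, 15, 25)):
        fibers.append(make_fiber([(r, 5), (r, 35)], fid=i))
    for j, c in enumerate((10, 20, 30)):
        fibers.append(make_fiber([(5, c), (35, c)], fid=3 + j))
    for r in (5, 15, 25):
        for c in (10, 20, 30):
            links.append((r, c))
    return make_network(fibers, links, pixel_size_um=1.0)
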