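import numpy as np
import pytest

from esovol import CTVolume, SliceContour


def circle_contour(slice_index: int, r: float, cx: float = 0.0, cy: float = 0.0, n: int = 64) -> SliceContour:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return SliceContour(slice_index, np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)]))


def centered_grid(nz: int, ny: int, nx: int, dx: float, dy: float, dz: float) -> CTVolume:
    """Empty volume with the in-plane origin at the grid center."""
    origin = (-(nx - 1) / 2 * dx, -(ny - 1) / 2 * dy, 0.0)
    return CTVolume(np.zeros((nz, ny, nx), dtype=np.float32), (dx, dy, dz), origin)


@pytest.fixture
def square_grid():
    """21-slice, 128x128, 0.5 mm in-plane, 2.5 mm slices, centered."""
    return centered_grid(21, 128, 128, 0.5, 0.5, 2.5)


@pytest.fixture(scope="session")
def study_fixture():
    from esovol import load_study_fixture

    return load_study_fixture()
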