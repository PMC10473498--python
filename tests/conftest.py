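import numpy as np
import pytest

from cryptmorph import BoundaryPolygon, LobedShapeSpec, make_lobed_boundary


def circle_polygon(radius=1.0, n=256, centre=(0.0, 0.0)):
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return BoundaryPolygon(
        np.column_stack(
            [centre[0] + radius * np.cos(th), centre[1] + radius * np.sin(th)]
        )
    )


def square_polygon(side=1.0):
    return BoundaryPolygon(
        np.array([[0.0, 0.0], [side, 0.0], [side, side], [0.0, side]])
    )


@pytest.fixture
def circle():
    return circle_polygon()


@pytest.fixture
def square():
    return square_polygon()


@pytest.fixture
def four_lobed():
    poly, k = make_lobed_boundary(LobedShapeSpec(k=4))
    return poly, k
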