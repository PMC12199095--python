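import pytest

from cnc_cslabel import (
    LabelGeometry,
    OccupancyModel,
    ProbeParams,
    build_cnc,
    build_unit_cell,
    decorate_model,
)

FULL_CS = OccupancyModel(f_cs=1.0, f_na=0.0, f_h=0.0, coverage=1.0, seed=0)


@pytest.fixture(scope="session")
def cell():
    return build_unit_cell()


@pytest.fixture(scope="session")
def diamond24(cell):
    return build_cnc(cell, "diamond", 24, 4)


@pytest.fixture(scope="session")
def rect24(cell):
    return build_cnc(cell, "rectangular", 24, 4)


def decorate_family(model, label, occupancy=FULL_CS, geom=None, **kw):
    """Decorate both facets of one family at the given occupancy."""
    return decorate_model(
        model, [model.facet(label, True), model.facet(label, False)],
        occupancy, geom or LabelGeometry(), **kw,
    )


@pytest.fixture(scope="session")
def diamond24_cs(diamond24):
    return decorate_family(diamond24, "(110)")


@pytest.fixture(scope="session")
def rect24_cs(rect24):
    return decorate_family(rect24, "(010)")


@pytest.fixture(scope="session")
def probe():
    return ProbeParams()


def assert_close(a, b, tol, msg=""):
    assert abs(a - b) <= tol, f"{a} != {b} (tol {tol}) {msg}"
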