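import numpy as np
import pytest

from immugrade.cohort_io import CellClass, CoreCellMap, Marker, Region
from immugrade.synthetic import fixture_config, simulate_cohort, write_cohort


@pytest.fixture(scope="session")
def fixture_cohort():
    """The 40-case test cohort, generated once per session from a frozen config."""
    return simulate_cohort(fixture_config())


@pytest.fixture(scope="session")
def cohort_dir(fixture_cohort, tmp_path_factory):
    """The test cohort written out in the pipeline's input formats."""
    out = tmp_path_factory.mktemp("cohort")
    write_cohort(fixture_cohort, out)
    return out


def make_core(tumor=(), immune=(), other=(), radius=500.0, case_id="c1", core_id="k1",
              region=Region.CENTER, marker=Marker.CD3):
    """Build a CoreCellMap from explicit coordinate lists."""
    pts = list(tumor) + list(immune) + list(other)
    cls = (
        [CellClass.TUMOR] * len(tumor)
        + [CellClass.IMMUNE] * len(immune)
        + [CellClass.OTHER] * len(other)
    )
    xy = np.asarray(pts, dtype=float).reshape(-1, 2)
    return CoreCellMap(
        case_id=case_id,
        core_id=core_id,
        region=region,
        marker=marker,
        x_um=xy[:, 0],
        y_um=xy[:, 1],
        cls=np.asarray(cls, dtype=object),
        core_radius_um=radius,
    )


def random_core(rng, n_tumor, n_immune, radius=500.0, **kw):
    """Uniform random core for oracle comparisons."""
    def draw(n):
        r = radius * np.sqrt(rng.uniform(size=n))
        th = rng.uniform(0, 2 * np.pi, size=n)
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    return make_core(tumor=draw(n_tumor), immune=draw(n_immune), radius=radius, **kw)
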