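import numpy as np
import pytest

import focimap as fm


@pytest.fixture
def layout():
    """Default catheter at the origin: inner loop 5 mm, outer 15 mm."""
    return fm.build_pentaray_layout()


@pytest.fixture
def planar_geometry(layout):
    return fm.PlanarGeometry.from_layout(layout)


def single_source_matrix(layout, src_xyz=(25.0, 5.0, 0.0), n=60, sigma=0.0, cv_sd=0.0, seed=1):
    """Noise-configurable single-source LAT table on the default layout."""
    src = fm.SourceSpec(np.asarray(src_xyz, dtype=float), np.arange(1, n + 1) * 400.0)
    return (
        fm.simulate_lat_matrix(
            [src],
            sensor_sites=layout.pair_midpoints,
            cv=fm.CVModel(1.0, cv_sd),
            noise=fm.NoiseModel(sigma),
            seed=seed,
        ),
        src,
    )


@pytest.fixture
def noiseless_single_source(layout):
    """Deterministic single-source matrix: LAT = onset + distance / 1.0."""
    return single_source_matrix(layout)


@pytest.fixture
def make_single_source(layout):
    """Factory for single-source matrices with configurable noise."""

    def _make(**kwargs):
        return single_source_matrix(layout, **kwargs)

    return _make


@pytest.fixture
def icosphere(tmp_path):
    """Unit icosphere scaled to 20 mm radius, written and re-read as OFF."""
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=2, radius=20.0)
    p = tmp_path / "icosphere.off"
    tm.export(str(p))
    return fm.load_surface_mesh(p)
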