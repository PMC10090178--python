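import numpy as np
import pytest

from hippocount import filterpost, preprocess, segment, synthgen


@pytest.fixture(scope="session")
def default_slab():
    return synthgen.generate_slab(synthgen.SlabSpec(seed=21))


@pytest.fixture(scope="session")
def default_rendered(default_slab):
    return synthgen.render_partition(default_slab, seed=21)


@pytest.fixture(scope="session")
def default_partition(default_rendered):
    return preprocess.preprocess_rendered(default_rendered)


@pytest.fixture(scope="session")
def default_instances(default_partition):
    return segment.segment(default_partition, segment.SegmentationParams())


def grid_slab(n_side=4, spacing_um=60.0, diam_um=18.0, thickness_um=20.39):
    """Slab with neurons on a regular grid, safely separated and in-plane."""
    cells = []
    for i in range(n_side):
        for j in range(n_side):
            cells.append(
                {
                    "cell_id": i * n_side + j,
                    "cls": synthgen.CLASS_PYRAMIDAL,
                    "x_um": spacing_um * (j + 0.75),
                    "y_um": spacing_um * (i + 0.75),
                    "z_um": thickness_um / 2.0,
                    "diam_um": diam_um,
                }
            )
    extent = spacing_um * (n_side + 0.5)
    return synthgen.slab_from_cells(cells, extent, extent, thickness_um)


def partition_from_image(image, pixel_size_um=0.75):
    """Wrap a raw uint8 array (dark-on-light) as a preprocessed partition."""
    mask = np.ones(image.shape, dtype=bool)
    inv = preprocess.invert(image.astype(np.uint8), mask)
    return preprocess.PartitionImage(
        image=inv,
        valid_mask=mask,
        polygon=np.array(
            [[0, 0], [0, image.shape[1] - 1],
             [image.shape[0] - 1, image.shape[1] - 1], [image.shape[0] - 1, 0]],
            dtype=float,
        ),
        pixel_size_um=pixel_size_um,
    )


def make_records(diameters_um):
    """Minimal kept records with prescribed diameters for filter tests."""
    return [
        filterpost.SegmentRecord(
            id=i + 1,
            pixel_count=10,
            mean_gray=200.0,
            ellipse=filterpost.EllipseFit((0.0, 0.0), d / 0.75, d / 0.75, 0.0),
            diameter_um=float(d),
        )
        for i, d in enumerate(diameters_um)
    ]
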