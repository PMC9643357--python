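import numpy as np
import pytest

from mifquant.fields import LabelMask, MultiChannelField
from mifquant.simulate import Placement, TissueSpec, render_field


def disk_mask(shape, centers_radii_labels, pixel_size_um):
    """Rasterize labeled disks: pixel centers at integer multiples of px."""
    labels = np.zeros(shape, dtype=np.int32)
    yy = np.arange(shape[0])[:, None] * pixel_size_um
    xx = np.arange(shape[1])[None, :] * pixel_size_um
    for (cx, cy), r, lab in centers_radii_labels:
        labels[np.hypot(yy - cy, xx - cx) <= r] = lab
    return LabelMask(labels=labels, kind="nucleus")


def uniform_field(shape, values, pixel_size_um=0.5, **meta):
    """Field with constant-valued channels."""
    return MultiChannelField(
        channels={name: np.full(shape, float(v)) for name, v in values.items()},
        pixel_size_um=pixel_size_um,
        **meta,
    )


@pytest.fixture
def small_spec():
    """A quick-to-render field with all three cell classes."""
    return TissueSpec(
        field_size_um=(100.0, 100.0),
        pixel_size_um=0.325,
        n_cells=40,
        fraction_cd8=0.35,
        fraction_neutrophil=0.3,
        min_clearance_um=0.7,  # keeps rasterized nuclei from touching at 0.325 um/px
        autofluorescence_level=20.0,
        gzmk_base=100.0,
        gzmk_contact_fold=2.0,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture
def manual_render():
    """Three hand-placed cells: a neutrophil, a contact cd8, a far cd8."""
    spec = TissueSpec(
        field_size_um=(60.0, 60.0),
        pixel_size_um=0.25,
        n_cells=3,
        gzmk_base=100.0,
        gzmk_contact_fold=3.0,
        autofluorescence_level=0.0,
        noise_sd=0.0,
        seed=0,
    )
    placement = [
        Placement(centroid_um=(15.0, 15.0), radius_um=3.0, cell_type="neutrophil"),
        Placement(centroid_um=(22.0, 15.0), radius_um=3.0, cell_type="cd8"),  # d = 7
        Placement(centroid_um=(48.0, 48.0), radius_um=3.0, cell_type="cd8"),  # d ~ 46
    ]
    field, mask, truth = render_field(spec, placement, patient_id="P0", field_id="F0")
    return spec, placement, field, mask, truth
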