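import numpy as np
import pytest

from flaps_phenotyper.detect import DetectedObject
from flaps_phenotyper.io_formats import AcquisitionMeta, ChannelImage


def make_channel(
    raster, role="FLAPS", exposure_ms=35.0, bit_max=4095
) -> ChannelImage:
    return ChannelImage(
        raster=np.asarray(raster),
        channel_role=role,
        exposure_ms=exposure_ms,
        bit_max=bit_max,
    )


def obj_from_mask(
    mask,
    role="FLAPS",
    sbr=10.0,
    exposure_ms=35.0,
    object_id=0,
    saturated=False,
    pixel_size_um=0.1,
) -> DetectedObject:
    """Build a DetectedObject directly from a boolean mask (test helper)."""
    mask = np.asarray(mask, bool)
    pix = np.flatnonzero(mask)
    rows, cols = pix // mask.shape[1], pix % mask.shape[1]
    return DetectedObject(
        object_id=object_id,
        channel_role=role,
        exposure_ms=exposure_ms,
        pixels=pix,
        shape=mask.shape,
        area_um2=pix.size * pixel_size_um**2,
        centroid=(float(rows.mean()), float(cols.mean())),
        mean_intensity=float(sbr * 100.0),
        sbr=float(sbr),
        saturated=saturated,
    )


@pytest.fixture
def meta_small() -> AcquisitionMeta:
    return AcquisitionMeta(
        pixel_size_um=0.1,
        fov_area_um2=64 * 64 * 0.01,
        filter_area_um2=2.0e8,
        volume_filtered_L=0.01,
        sample_id="test",
        timepoint_h=1.0,
    )
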