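import numpy as np
import pytest
import scipy.ndimage as ndi

from cmlcells.segmentation import CellRecord
from cmlcells.synth import PALETTE, SyntheticCellSpec, render_cell, sample_spec


def record_from_truth(scene, cell_id=1) -> CellRecord:
    """Build a CellRecord directly from a scene's ground-truth masks."""
    cell, nuc, _ = scene.truth[0]
    rows, cols = np.nonzero(cell)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
    return CellRecord(cell_id, cell, nuc & cell, cell & ~nuc, bbox, frozenset())


def random_blob(rng, size=96, smooth=6.0, quantile=78):
    """Random blobby single-component mask (smoothed-noise threshold)."""
    noise = ndi.gaussian_filter(rng.normal(size=(size, size)), smooth)
    mask = noise > np.percentile(noise, quantile)
    lab, n = ndi.label(mask)
    if n == 0:
        return None
    areas = np.bincount(lab.ravel())[1:]
    mask = lab == (int(areas.argmax()) + 1)
    mask = ndi.binary_fill_holes(mask)
    if mask.sum() < 60 or not ndi.binary_erosion(mask).any():
        return None
    return mask


def dice(a, b) -> float:
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def mb_scene():
    return render_cell(sample_spec("MB", seed=101))


@pytest.fixture(scope="session")
def band_scene():
    return render_cell(sample_spec("B", seed=202))


@pytest.fixture(scope="session")
def trilobe_scene():
    rc = 255.0
    area = 0.24 * np.pi * rc * rc
    spec = SyntheticCellSpec(
        target_class="N",
        cell_radius=rc,
        nucleus_shape="lobed",
        nc_ratio_target=0.24,
        cytoplasm_rgb=PALETTE["cyto_pink"],
        nucleus_rgb=PALETTE["nucleus_mature"],
        noise_sigma=3.0,
        seed=7,
        n_lobes=3,
        geometry={
            "rotation": 0.7,
            "shape": "lobed",
            "k": 3,
            "lobe_r": float(np.sqrt(area / (3 * np.pi))),
            "ring_r": 0.60 * rc,
        },
    )
    return render_cell(spec)
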