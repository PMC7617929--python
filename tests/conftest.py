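import numpy as np
import pytest

from rhizotrack import swim_sim as ss


@pytest.fixture
def imaging512():
    """Camera at the reduced 512 x 512 analysis frame, 10 fps, 0.2 μm/px."""
    return ss.ImagingParams(frame_width=512, frame_height=512, seed=99)


@pytest.fixture
def imaging512_noiseless():
    return ss.ImagingParams(frame_width=512, frame_height=512, noise_sd=0.0,
                            seed=99)


def make_trackset(positions_um, imaging, speeds=None, tumbles=None):
    """Build a GroundTruthTrackSet directly from per-cell position arrays
    (list of (n_i, 2) arrays in μm) — handy for rendering hand-made
    geometries."""
    cells = []
    for i, pos in enumerate(positions_um):
        pos = np.asarray(pos, dtype=float).reshape(-1, 2)
        cells.append(ss.TrueCellTrack(
            cell_id=i, frames=np.arange(pos.shape[0]), x_um=pos[:, 0],
            y_um=pos[:, 1],
            speed=float(speeds[i]) if speeds is not None else 0.0,
            tumble_frames=np.asarray(tumbles[i] if tumbles else [], dtype=int)))
    params = ss.SwimmerParams(n_cells=len(cells),
                              fov_width=imaging.fov_width_um,
                              fov_height=imaging.fov_height_um)
    return ss.GroundTruthTrackSet(cells, params)
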