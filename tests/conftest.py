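import numpy as np
import pytest

from territory.arena import default_layout
from territory.tracks import BODYPARTS, track_from_arrays

#: low frame rate used for scripted fixtures — keeps arrays small while
#: exercising the same frame-resolution code paths as 45 Hz recordings
FPS = 9.0


@pytest.fixture(scope="session")
def layout():
    return default_layout(frame_rate_hz=FPS)


@pytest.fixture(scope="session")
def layout45():
    return default_layout()


def make_track(path_xy, fps=FPS, mouse_id="m1", likelihood=None):
    """PoseTrack whose every body part follows the given (n, 2) path."""
    path_xy = np.asarray(path_xy, dtype=float)
    coords = {bp: path_xy.copy() for bp in BODYPARTS}
    lik = None if likelihood is None else {bp: np.asarray(likelihood, float) for bp in BODYPARTS}
    return track_from_arrays(mouse_id, fps, coords, lik)


def scripted_path(segments, fps=FPS):
    """Concatenate (duration_s, (x, y)) stay-put segments into a path."""
    chunks = []
    for dur, xy in segments:
        n = int(round(dur * fps))
        chunks.append(np.tile(np.asarray(xy, float), (n, 1)))
    return np.vstack(chunks)
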