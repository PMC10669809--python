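import numpy as np
import pytest

from lcpipe.ratio_imaging import ZScoreTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ztrace(z, frame_interval=1.0, t_start=0.0, baseline=(0.0, 300.0)):
    """Wrap a bare Z array in a ZScoreTrace for direct fwhm/window tests."""
    z = np.asarray(z, dtype=float)
    return ZScoreTrace(
        z=z,
        baseline_window=baseline,
        ratio_raw=z,
        frame_interval=frame_interval,
        t_start=t_start,
    )


def fwhm_bruteforce(z, ma_frames=120):
    """Independent threshold-scan oracle for the FWHM statistic.

    Explicit loops: centered moving average truncated at the edges, global
    minimum, then first/last index strictly below half that minimum.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    ma = np.empty(n)
    half_lo = ma_frames // 2  # centered window: [i - w//2, i + (w - w//2))
    half_hi = ma_frames - half_lo
    for i in range(n):
        lo = max(0, i - half_lo)
        hi = min(n, i + half_hi)
        ma[i] = z[lo:hi].mean()
    z_min = ma.min()
    threshold = 0.5 * z_min
    below = [i for i in range(n) if z[i] < threshold]
    return z_min, below[0], below[-1], below[-1] - below[0]
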