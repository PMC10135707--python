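import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def minimal_gap_oracle(volume: np.ndarray) -> int:
    """Independent brute-force oracle: scan every axial slice for the minimal
    column gap between exactly-two-run rows (left and right lateral structures)."""
    best = None
    nx = volume.shape[0]
    for z in range(volume.shape[2]):
        for y in range(volume.shape[1]):
            row = volume[:, y, z]
            runs = []
            in_run = False
            for i in range(nx):
                if row[i] and not in_run:
                    runs.append([i, i])
                    in_run = True
                elif row[i]:
                    runs[-1][1] = i
                else:
                    in_run = False
            # two runs reaching into the outer thirds = the two lateral wings
            if len(runs) == 2 and runs[0][0] < nx / 3 and runs[1][1] > 2 * nx / 3:
                gap = runs[1][0] - runs[0][1] - 1
                best = gap if best is None else min(best, gap)
    return best
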