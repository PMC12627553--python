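import numpy as np
import pytest

from bowpam.ice_metrics import IceField, classify_and_filter


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20221001)


def brute_mean_concentration(field: IceField, radius_km: float) -> float:
    """Exhaustive-loop oracle for the radius average."""
    conc = field.concentration
    rows, cols = conc.shape
    acc, n = 0.0, 0
    for r in range(rows):
        for c in range(cols):
            if not np.isfinite(conc[r, c]):
                continue
            d = np.hypot((r - field.recorder_row) * field.cell_size_km,
                         (c - field.recorder_col) * field.cell_size_km)
            if d <= radius_km:
                acc += conc[r, c]
                n += 1
    return acc / n if n else float("nan")


def brute_edge_distance(field: IceField, ice_threshold=15.0, max_patch=50):
    """Exhaustive-loop oracle for the signed edge distance magnitude.

    Uses the same patch classification (the filtering itself is checked
    through its documented boundary behavior) but scans every candidate
    cell with an explicit distance computation.
    """
    filt = classify_and_filter(field, ice_threshold, max_patch)
    r0, c0 = field.recorder_row, field.recorder_col
    if not filt.valid[r0, c0]:
        return None
    in_ice = bool(filt.ice_mask[r0, c0])
    targets = filt.water_candidates if in_ice else filt.ice_candidates
    best = None
    rows, cols = field.concentration.shape
    for r in range(rows):
        for c in range(cols):
            if targets[r, c]:
                d = np.hypot((r - r0) * field.cell_size_km,
                             (c - c0) * field.cell_size_km)
                if best is None or d < best:
                    best = d
    if best is None:
        return None
    return (-best if in_ice else best)
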