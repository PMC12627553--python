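"""Waveform conditioning, spectrogram tiling, and the chunked tile store.

The detector consumes band-limited log-magnitude spectrograms computed with
a fixed recipe: audio resampled to 5 kHz and peak-normalised, a 2,800-sample
Hann window zero-padded to a 4,096-point DFT, hop 1,400 samples, rows
restricted to bin centers in [50, 1000] Hz (779 rows), and the frame axis
zero-padded (at the log floor) to the frame count of a full-length clip.

Framing is non-centered: the first window starts at sample 0 and frames
advance by the hop, so a clip of L samples yields 1 + floor((L-2800)/1400)
data frames.  A full 600-s clip at 5 kHz gives 2,141 frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import List, Optional, Sequence, Tuple

import numpy as np
import zarr
from scipy.fft import rfft
from scipy.signal import resample_poly, windows

TARGET_RATE = 5000.0
WINDOW_SAMPLES = 2800
DFT_SIZE = 4096
HOP_SAMPLES = 1400
BAND_HZ = (50.0, 1000.0)
FULL_CLIP_SECONDS = 600.0
LOG_FLOOR_EPS = 1e-10
#: value of a log-scaled zero-magnitude cell
LOG_FLOOR = float(np.log10(LOG_FLOOR_EPS))

#: DFT bin indices whose center frequency k*5000/4096 lies in [50, 1000] Hz.
_bin_centers = np.arange(DFT_SIZE // 2 + 1) * TARGET_RATE / DFT_SIZE
BAND_BINS = np.flatnonzero((_bin_centers >= BAND_HZ[0]) & (_bin_centers <= BAND_HZ[1]))
BAND_FREQS = _bin_centers[BAND_BINS]
N_FREQ_BINS = BAND_BINS.size  # 779

_HANN = windows.hann(WINDOW_SAMPLES, sym=False)


@dataclass
class SpectrogramTile:
    """Log-magnitude spectrogram of one clip; the CNN's input image.

    ``values`` has shape [n_freq_bins, n_frames] with rows ordered low->high
    frequency and columns in time order.
    """

    values: np.ndarray
    freqs_hz: np.ndarray
    clip_id: str = ""
    start_time: Optional[object] = None
    label: Optional[int] = None

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


def n_frames_for(n_samples: int) -> int:
    """Data frames produced by non-centered framing of ``n_samples``."""
    if n_samples < WINDOW_SAMPLES:
        return 0
    return 1 + (n_samples - WINDOW_SAMPLES) // HOP_SAMPLES


def target_frames(clip_seconds: float = FULL_CLIP_SECONDS) -> int:
    """Frame count a tile is zero-padded to (2141 for 600-s clips)."""
    return n_frames_for(int(round(clip_seconds * TARGET_RATE)))


def prepare_waveform(audio: np.ndarray, orig_rate: float) -> np.ndarray:
    """Anti-aliased resample to 5 kHz plus peak normalisation.

    Only downsampling is supported (the recorders all sample at >= 5 kHz);
    input already at 5 kHz passes through untouched apart from the peak
    normalisation to max |x| = 1.
    """
    audio = np.asarray(audio, dtype=np.float64)
    if audio.size == 0:
        raise ValueError("empty audio")
    if audio.ndim != 1:
        raise ValueError("audio must be mono (1-D)")
    if orig_rate < TARGET_RATE:
        raise ValueError("upsampling unsupported: original rate below 5 kHz")
    if orig_rate != TARGET_RATE:
        ratio = Fraction(TARGET_RATE / orig_rate).limit_denominator(10000)
        audio = resample_poly(audio, ratio.numerator, ratio.denominator)
    peak = np.abs(audio).max()
    if peak > 0:
        audio = audio / peak
    return audio


def tile_spectrogram(waveform: np.ndarray,
                     sample_rate: float = TARGET_RATE,
                     clip_seconds: float = FULL_CLIP_SECONDS,
                     clip_id: str = "",
                     start_time=None,
                     label: Optional[int] = None) -> SpectrogramTile:
    """Compute the band-limited log-magnitude tile of one clip.

    Frames computed from real audio are never altered by the padding:
    frames beyond the waveform's end are filled with the log floor up to the
    frame count of a ``clip_seconds`` clip.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    if sample_rate != TARGET_RATE:
        raise ValueError("tile_spectrogram expects 5 kHz input; "
                         "run prepare_waveform first")
    max_samples = int(round(clip_seconds * TARGET_RATE))
    if waveform.size > max_samples:
        raise ValueError(f"waveform longer than {clip_seconds:.0f} s")

    n_total = target_frames(clip_seconds)
    values = np.full((N_FREQ_BINS, n_total), LOG_FLOOR, dtype=np.float32)
    n_data = n_frames_for(waveform.size)
    if n_data > 0:
        frames = np.lib.stride_tricks.sliding_window_view(
            waveform, WINDOW_SAMPLES)[::HOP_SAMPLES][:n_data]
        spec = rfft(frames * _HANN, n=DFT_SIZE, axis=1)
        mag = np.abs(spec[:, BAND_BINS])
        values[:, :n_data] = np.log10(mag + LOG_FLOOR_EPS).T.astype(np.float32)
    return SpectrogramTile(values=values, freqs_hz=BAND_FREQS.copy(),
                           clip_id=clip_id, start_time=start_time, label=label)


# ---------------------------------------------------------------------------
# Chunked tile store (Zarr, one group per recorder)
# ---------------------------------------------------------------------------

def persist_tiles(tiles: Sequence[SpectrogramTile],
                  labels: Sequence[int],
                  store_path,
                  recorder: str = "default",
                  attrs: Optional[dict] = None) -> None:
    """Write tiles and labels as chunked arrays under one recorder group.

    All tiles must share a shape; the store keeps one chunk per tile so a
    training loop can load tiles independently.  Round-tripping returns
    values and labels bit-identically.
    """
    if len(tiles) != len(labels):
        raise ValueError("tiles and labels length mismatch")
    if not tiles:
        raise ValueError("no tiles to persist")
    shape = tiles[0].shape
    if any(t.shape != shape for t in tiles):
        raise ValueError("all tiles must share one shape")
    stacked = np.stack([t.values for t in tiles]).astype(np.float32)

    root = zarr.open_group(store_path, mode="a")
    if recorder in root:
        del root[recorder]
    grp = root.create_group(recorder)
    arr = grp.create_array("tiles", shape=stacked.shape,
                           chunks=(1,) + shape, dtype="float32")
    arr[:] = stacked
    lab = grp.create_array("labels", shape=(len(labels),), dtype="int8")
    lab[:] = np.asarray(labels, dtype=np.int8)
    meta = {
        "sample_rate_hz": TARGET_RATE,
        "window_samples": WINDOW_SAMPLES,
        "dft_size": DFT_SIZE,
        "hop_samples": HOP_SAMPLES,
        "band_hz": list(BAND_HZ),
        "clip_ids": [t.clip_id for t in tiles],
        "start_times": [str(t.start_time) for t in tiles],
    }
    if attrs:
        meta.update(attrs)
    grp.attrs.update(meta)


def load_tiles(store_path, recorder: str = "default",
               sel: slice | None = None) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Load (tiles, labels, attrs) back; ``sel`` reads a subset of tiles."""
    root = zarr.open_group(store_path, mode="r")
    grp = root[recorder]
    sel = sel if sel is not None else slice(None)
    return grp["tiles"][sel], grp["labels"][sel], dict(grp.attrs)
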