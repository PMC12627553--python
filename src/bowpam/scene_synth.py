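"""Synthetic passive-acoustic scenes and ice fields with known ground truth.

Every downstream stage (spectrogram preparation, CNN training, detection
review, presence metrics, ice covariates) is exercised on data produced
here, so each generator is a pure function of its specification including
the seed.

The acoustic repertoire is a statistical stand-in for the two recording
regions, not a perceptual imitation: "Fram-like" clips carry simple
frequency-modulated (FM) calls mainly below 1 kHz, "Svalbard-like" clips
carry repeated song-like unit sequences with harmonics.  Two confounders are
mixed into scenes of either label without affecting it: short broadband ice
transients (<= 0.2 s) and long, slowly descending seal-like trills (> 10 s)
— the false-positive sources a detector faces in Arctic recordings.
Event amplitudes are calibrated as signal-to-noise ratios measured in the
50–1000 Hz band, the band the detector sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.ndimage import gaussian_filter
from scipy.signal import butter, sosfilt, windows

from .ice_metrics import DEFAULT_CELL_KM, IceField

#: Event kinds whose presence sets the clip label to 1.
BOWHEAD_KINDS = frozenset({"simple_fm", "song_unit"})
#: All recognised event kinds.
ALL_KINDS = frozenset({"simple_fm", "song_unit", "ice_transient", "seal_trill"})
#: Band (Hz) in which event SNR is measured — the detector's input band.
SNR_BAND_HZ = (50.0, 1000.0)
#: Default event SNR range (dB) for generated datasets: "moderate" levels.
DEFAULT_SNR_RANGE_DB = (3.0, 12.0)
#: Fraction of clips (either label) carrying an ice-transient confounder.
ICE_TRANSIENT_CLIP_RATE = 0.25
#: Fraction of clips (either label) carrying a seal-trill confounder.
SEAL_TRILL_CLIP_RATE = 0.10
#: Spacing of the synthetic recording grid (one file per slot).
FILE_GRID_MINUTES = 10


@dataclass(frozen=True)
class CallTemplate:
    """Parametric description of one sound event.

    ``kind`` controls only the clip label downstream (bowhead kinds are
    ``simple_fm`` and ``song_unit``); the waveform itself is a windowed tone
    whose instantaneous frequency sweeps linearly ``f_start`` -> ``f_end``
    over ``duration`` seconds, with ``n_harmonics`` overtones at integer
    multiples of the fundamental, the k-th scaled by ``harmonic_decay**k``.
    """

    kind: str
    f_start: float
    f_end: float
    duration: float
    n_harmonics: int = 0
    harmonic_decay: float = 0.5
    snr_db: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.f_start <= 0 or self.f_end <= 0:
            raise ValueError("frequencies must be positive")
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")
        if not (0 < self.harmonic_decay <= 1):
            raise ValueError("harmonic_decay must lie in (0, 1]")


@dataclass(frozen=True)
class SceneSpec:
    """Full recipe for one clip: noise model plus (template, onset) events."""

    sample_rate: float
    clip_duration: float = 600.0
    noise_model: str = "pink"
    noise_level: float = 1.0
    events: Tuple[Tuple[CallTemplate, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("white", "pink"):
            raise ValueError("noise_model must be 'white' or 'pink'")
        for tmpl, onset in self.events:
            if onset < 0 or onset + tmpl.duration > self.clip_duration:
                raise ValueError(
                    f"event at {onset:.2f}s ({tmpl.duration:.2f}s long) does "
                    f"not fit in a {self.clip_duration:.0f}s clip")


@dataclass
class LabeledClip:
    """One synthetic recording with its ground-truth annotations."""

    waveform: np.ndarray
    sample_rate: float
    label: int
    events: Tuple[Tuple[CallTemplate, float], ...]
    clip_id: str = ""
    start_time: Optional[pd.Timestamp] = None


def synth_call(template: CallTemplate, sample_rate: float) -> np.ndarray:
    """Synthesise one event as a linearly swept, windowed tone.

    Harmonics whose frequency would exceed Nyquist anywhere during the sweep
    are clipped (dropped); the fundamental itself must stay below Nyquist.
    Peak amplitude is 1 before mixing.
    """
    nyquist = sample_rate / 2
    if max(template.f_start, template.f_end) >= nyquist:
        raise ValueError("fundamental reaches Nyquist at this sample rate")
    n = max(int(round(template.duration * sample_rate)), 2)
    t = np.arange(n) / sample_rate
    # Linear sweep: phase(t) = 2*pi*(f0*t + (f1-f0)*t^2/(2*D))
    sweep_phase = 2 * np.pi * (
        template.f_start * t
        + (template.f_end - template.f_start) * t ** 2 / (2 * template.duration))
    x = np.sin(sweep_phase)
    f_max = max(template.f_start, template.f_end)
    for k in range(1, template.n_harmonics + 1):
        if (k + 1) * f_max >= nyquist:
            break
        x = x + template.harmonic_decay ** k * np.sin((k + 1) * sweep_phase)
    x *= windows.tukey(n, alpha=0.2)
    peak = np.abs(x).max()
    if peak > 0:
        x /= peak
    return x.astype(np.float64)


def _band_sos(sample_rate: float):
    lo, hi = SNR_BAND_HZ
    hi = min(hi, 0.45 * sample_rate)
    return butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")


def _band_power(x: np.ndarray, sos) -> float:
    y = sosfilt(sos, x)
    return float(np.mean(y ** 2))


def _make_noise(n: int, model: str, level: float, rng: np.random.Generator) -> np.ndarray:
    w = rng.standard_normal(n)
    if model == "pink":
        spec = np.fft.rfft(w)
        f = np.fft.rfftfreq(n)
        shape = np.ones_like(f)
        nz = f > 0
        shape[nz] = 1.0 / np.sqrt(f[nz] / f[nz][0])
        w = np.fft.irfft(spec * shape, n=n)
    rms = np.sqrt(np.mean(w ** 2))
    return w * (level / rms)


def synth_clip(spec: SceneSpec) -> LabeledClip:
    """Mix a scene: noise floor plus events scaled to their in-band SNR.

    The label is 1 iff at least one bowhead-kind event (``simple_fm`` or
    ``song_unit``) is present; confounders never set it.  Identical specs
    (including seed) give bit-identical waveforms.  The final waveform is
    rescaled, if needed, so its peak magnitude is <= 1 (SNRs are ratios and
    survive the common rescale).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.clip_duration * spec.sample_rate))
    noise = _make_noise(n, spec.noise_model, spec.noise_level, rng)
    sos = _band_sos(spec.sample_rate)
    noise_band_power = _band_power(noise, sos)

    out = noise.copy()
    for tmpl, onset in spec.events:
        call = synth_call(tmpl, spec.sample_rate)
        call_band_power = _band_power(call, sos)
        if call_band_power <= 0:
            continue
        gain = np.sqrt(noise_band_power / call_band_power
                       * 10 ** (tmpl.snr_db / 10))
        i0 = int(round(onset * spec.sample_rate))
        out[i0:i0 + call.size] += gain * call[: n - i0]

    peak = np.abs(out).max()
    if peak > 1:
        out /= peak
    label = int(any(t.kind in BOWHEAD_KINDS for t, _ in spec.events))
    return LabeledClip(waveform=out.astype(np.float32),
                       sample_rate=spec.sample_rate,
                       label=label, events=spec.events)


# ---------------------------------------------------------------------------
# Template pools
# ---------------------------------------------------------------------------

def fram_call(rng: np.random.Generator, snr_db: float) -> CallTemplate:
    """Simple FM call below 1 kHz, ~1–2.5 s, occasionally one harmonic."""
    f0 = rng.uniform(150, 750)
    f1 = np.clip(f0 + rng.uniform(-250, 250), 60, 950)
    return CallTemplate("simple_fm", f0, float(f1),
                        duration=float(rng.uniform(0.8, 2.5)),
                        n_harmonics=int(rng.integers(0, 2)),
                        harmonic_decay=0.5, snr_db=snr_db)


def song_unit(rng: np.random.Generator, snr_db: float) -> CallTemplate:
    """Song-like unit with harmonics, the building block of a sequence."""
    f0 = rng.uniform(200, 700)
    f1 = np.clip(f0 + rng.uniform(-300, 300), 80, 950)
    return CallTemplate("song_unit", f0, float(f1),
                        duration=float(rng.uniform(0.5, 1.5)),
                        n_harmonics=int(rng.integers(1, 4)),
                        harmonic_decay=0.6, snr_db=snr_db)


def ice_transient(rng: np.random.Generator, snr_db: float) -> CallTemplate:
    """Broadband transient <= 0.2 s: a very fast in-band down-sweep."""
    return CallTemplate("ice_transient",
                        f_start=float(rng.uniform(600, 950)),
                        f_end=float(rng.uniform(60, 200)),
                        duration=float(rng.uniform(0.05, 0.2)),
                        n_harmonics=0, snr_db=snr_db)


def seal_trill(rng: np.random.Generator, snr_db: float) -> CallTemplate:
    """Seal-like slow down-sweep longer than 10 s."""
    return CallTemplate("seal_trill",
                        f_start=float(rng.uniform(450, 900)),
                        f_end=float(rng.uniform(100, 300)),
                        duration=float(rng.uniform(11.0, 15.0)),
                        n_harmonics=0, snr_db=snr_db)


def _scene_events(rng: np.random.Generator, positive: bool, style: str,
                  clip_duration: float,
                  snr_range: Tuple[float, float]) -> Tuple[Tuple[CallTemplate, float], ...]:
    """Draw the event list for one scene.  Confounders appear in scenes of
    either label; only bowhead events are tied to ``positive``."""
    events: List[Tuple[CallTemplate, float]] = []
    if style == "mixed":
        style = "svalbard" if rng.random() < 0.5 else "fram"

    def place(tmpl: CallTemplate) -> None:
        latest = clip_duration - tmpl.duration
        if latest <= 0:
            return
        events.append((tmpl, float(rng.uniform(0, latest))))

    snr = lambda: float(rng.uniform(*snr_range))
    if positive:
        if style == "svalbard":
            # a repeated sequence of similar units with regular gaps
            base = song_unit(rng, snr())
            n_units = int(rng.integers(3, 7))
            gap = rng.uniform(1.5, 4.0)
            start = rng.uniform(0, max(clip_duration
                                       - n_units * (base.duration + gap), 1.0))
            for i in range(n_units):
                onset = start + i * (base.duration + gap)
                if onset + base.duration > clip_duration:
                    break
                jitter = replace(base, snr_db=snr())
                events.append((jitter, float(onset)))
        else:
            for _ in range(int(rng.integers(1, 4))):
                place(fram_call(rng, snr()))
    # confounders are present but sparse: the bulk of the emulated training
    # data is open-water recording with few confusable biological or
    # cryogenic sounds
    if rng.random() < ICE_TRANSIENT_CLIP_RATE:
        place(ice_transient(rng, snr()))
    if rng.random() < SEAL_TRILL_CLIP_RATE:
        place(seal_trill(rng, snr()))
    return tuple(events)


def synth_dataset(n_pos: int, n_neg: int, *,
                  sample_rate: float = 5000.0,
                  clip_duration: float = 600.0,
                  style: str = "fram",
                  snr_range: Tuple[float, float] = DEFAULT_SNR_RANGE_DB,
                  noise_model: str = "pink",
                  seed: int = 0,
                  start_time: str = "2022-10-01T00:00:00",
                  out_dir: Optional[str | Path] = None
                  ) -> Tuple[List[LabeledClip], pd.DataFrame]:
    """Generate a labelled clip collection plus its manifest.

    Exactly ``n_pos`` clips carry label 1 and ``n_neg`` label 0, assigned to
    a regular 10-min timestamp grid in seed-shuffled order.  With ``out_dir``
    set, clips are written as float32 WAV files and the manifest as CSV with
    header ``clip_id,start_time,label,path``.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("clip counts must be >= 0")
    if style not in ("fram", "svalbard", "mixed"):
        raise ValueError("style must be 'fram', 'svalbard' or 'mixed'")
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.array([1] * n_pos + [0] * n_neg)
    rng.shuffle(labels)
    t0 = pd.Timestamp(start_time)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    clips: List[LabeledClip] = []
    rows = []
    for i, lab in enumerate(labels):
        events = _scene_events(rng, bool(lab), style, clip_duration, snr_range)
        spec = SceneSpec(sample_rate=sample_rate, clip_duration=clip_duration,
                         noise_model=noise_model, events=events,
                         seed=int(rng.integers(0, 2 ** 31 - 1)))
        clip = synth_clip(spec)
        assert clip.label == lab, "event drawing must respect the target label"
        clip.clip_id = f"clip_{i:05d}"
        clip.start_time = t0 + pd.Timedelta(minutes=FILE_GRID_MINUTES * i)
        path = ""
        if out_path is not None:
            path = str(out_path / f"{clip.clip_id}.wav")
            wavfile.write(path, int(sample_rate), clip.waveform)
        clips.append(clip)
        rows.append({"clip_id": clip.clip_id,
                     "start_time": clip.start_time.isoformat(),
                     "label": int(lab), "path": path})
    manifest = pd.DataFrame(rows, columns=["clip_id", "start_time", "label", "path"])
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return clips, manifest


# ---------------------------------------------------------------------------
# Synthetic ice fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IceGeometrySpec:
    """Recipe for a synthetic concentration grid with known edge geometry.

    geometry:
      - ``half_plane``: ice fills columns <= ``edge_col`` (params:
        ``edge_col``, ``conc_ice``, ``conc_water``); the true signed edge
        distance from the recorder has a closed form.
      - ``disk_patch``: one disk of ice (params: ``center``, ``radius_cells``,
        ``conc_in``, ``conc_out``); patch cell count and area are attached.
      - ``noise_threshold``: smoothed random field rescaled to [0, 100]
        (params: ``sigma_cells``).
      - ``uniform``: constant concentration (params: ``value``).
    """

    shape: Tuple[int, int]
    geometry: str
    params: dict = field(default_factory=dict)
    cell_size_km: float = DEFAULT_CELL_KM
    recorder: Tuple[int, int] = (0, 0)
    seed: int = 0


def synth_icefield(spec: IceGeometrySpec) -> IceField:
    rows, cols = spec.shape
    r0, c0 = spec.recorder
    p = spec.params
    truth: dict = {}
    if spec.geometry == "half_plane":
        edge_col = int(p["edge_col"])
        conc_ice = float(p.get("conc_ice", 90.0))
        conc_water = float(p.get("conc_water", 0.0))
        grid = np.full(spec.shape, conc_water)
        grid[:, : edge_col + 1] = conc_ice
        if c0 > edge_col:  # recorder in open water
            truth["edge_distance_km"] = (c0 - edge_col) * spec.cell_size_km
        else:              # recorder inside the ice
            truth["edge_distance_km"] = -(edge_col + 1 - c0) * spec.cell_size_km
        truth["edge_distance_defined"] = 0 <= edge_col < cols - 1 or c0 > edge_col
    elif spec.geometry == "disk_patch":
        cr, cc = p.get("center", (rows // 2, cols // 2))
        radius = float(p["radius_cells"])
        conc_in = float(p.get("conc_in", 90.0))
        conc_out = float(p.get("conc_out", 0.0))
        rr, cc_idx = np.indices(spec.shape)
        disk = (rr - cr) ** 2 + (cc_idx - cc) ** 2 <= radius ** 2
        grid = np.where(disk, conc_in, conc_out)
        truth["patch_cells"] = int(disk.sum())
        truth["patch_area_km2"] = truth["patch_cells"] * spec.cell_size_km ** 2
    elif spec.geometry == "noise_threshold":
        rng = np.random.default_rng(spec.seed)
        raw = gaussian_filter(rng.standard_normal(spec.shape),
                              sigma=float(p.get("sigma_cells", 3.0)))
        lo, hi = raw.min(), raw.max()
        grid = (raw - lo) / (hi - lo) * 100.0 if hi > lo else np.zeros(spec.shape)
    elif spec.geometry == "uniform":
        grid = np.full(spec.shape, float(p.get("value", 0.0)))
        truth["edge_distance_defined"] = False
    else:
        raise ValueError(f"unknown geometry {spec.geometry!r}")
    return IceField(concentration=grid, cell_size_km=spec.cell_size_km,
                    recorder_row=r0, recorder_col=c0, ground_truth=truth)
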