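"""Channel (noise) vocoder simulating cochlear-implant hearing.

The transform: a 128-point short-time Fourier transform at 75% overlap of a
16 kHz mono signal; FFT bins grouped into 10 non-overlapping,
logarithmically spaced bands; per band the envelope is the square root of
the total energy in the band; each envelope amplitude-modulates a noise
carrier centered on the band whose spectrum is flat inside the band and
decays at 3.5 dB/octave outside it (simulating current spread along an
electrically stimulated cochlea); the modulated bands are summed.

Nominal band edges form an exact geometric progression between the low edge
and Nyquist.  Bin assignment maps the edges to FFT-bin boundaries by
rounding, with strict monotonicity enforced, so every band holds at least
one bin even where the nominal band is narrower than the 125 Hz bin spacing
(the usual channel-vocoder convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal.windows import hann

__all__ = [
    "VocoderSpec",
    "Filterbank",
    "EnvelopeMatrix",
    "design_filterbank",
    "stft",
    "band_envelopes",
    "synthesize",
    "vocode",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class VocoderSpec:
    """Fully determines the vocoding transform up to the noise seed."""

    sample_rate: int = 16000
    fft_size: int = 128
    overlap: float = 0.75
    n_bands: int = 10
    spread_slope: float = 3.5  # dB per octave decay outside the band
    low_edge: float = 80.0
    high_edge: float | None = None  # defaults to Nyquist
    noise_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.overlap < 1.0:
            raise ValueError("overlap must lie in (0, 1)")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        hop = self.fft_size * (1.0 - self.overlap)
        if abs(hop - round(hop)) > 1e-9:
            raise ValueError("fft_size * (1 - overlap) must be an integer hop")
        top = self.high_edge if self.high_edge is not None else self.sample_rate / 2
        if not 0 < self.low_edge < top <= self.sample_rate / 2:
            raise ValueError("band edges must satisfy 0 < low < high <= Nyquist")

    @property
    def hop(self) -> int:
        return round(self.fft_size * (1.0 - self.overlap))

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0

    @property
    def band_edges(self) -> np.ndarray:
        """Nominal edges: a geometric progression from the low edge to the
        high edge, n_bands + 1 points (constant successive ratio)."""
        top = self.high_edge if self.high_edge is not None else self.nyquist
        return np.geomspace(self.low_edge, top, self.n_bands + 1)


@dataclass(frozen=True)
class Filterbank:
    """Assignment of analysis bins to bands."""

    band_edges: np.ndarray
    bin_slices: tuple            # per band, (start, stop) rfft-bin indices
    n_bins: int
    bin_spacing: float

    @property
    def n_bands(self) -> int:
        return len(self.bin_slices)

    @property
    def band_centers(self) -> np.ndarray:
        """Geometric mean of the nominal edges of each band."""
        e = self.band_edges
        return np.sqrt(e[:-1] * e[1:])

    def band_bins(self, b: int) -> np.ndarray:
        start, stop = self.bin_slices[b]
        return np.arange(start, stop)


def design_filterbank(spec: VocoderSpec) -> Filterbank:
    """Group rfft bins into non-overlapping log-spaced bands.

    Every bin between the low edge and Nyquist belongs to exactly one band
    and every band is non-empty; otherwise an error is raised (the FFT is
    too short for the requested band count).
    """
    n_bins = spec.fft_size // 2 + 1
    if spec.fft_size // 2 < spec.n_bands:
        raise ValueError(
            f"{spec.n_bands} bands need at least {spec.n_bands} analysis bins; "
            f"fft_size {spec.fft_size} provides {spec.fft_size // 2}"
        )
    df = spec.sample_rate / spec.fft_size
    edges = spec.band_edges
    idx = [max(1, round(edges[0] / df))]
    for e in edges[1:]:
        idx.append(max(idx[-1] + 1, round(e / df)))
    idx[-1] = max(idx[-1], spec.fft_size // 2 + 1)  # top band reaches Nyquist
    if idx[-1] > n_bins or idx[-2] >= n_bins:
        raise ValueError(
            f"cannot fit {spec.n_bands} non-empty bands into {n_bins} bins "
            f"between {spec.low_edge} Hz and Nyquist"
        )
    slices = tuple((idx[k], idx[k + 1]) for k in range(spec.n_bands))
    return Filterbank(
        band_edges=edges, bin_slices=slices, n_bins=n_bins, bin_spacing=df
    )


def _frame_count(n_samples: int, fft_size: int, hop: int) -> int:
    """Frames cover the signal with right zero padding: the first frame
    starts at sample 0 and frames advance by ``hop`` until the last frame
    start is within the signal."""
    if n_samples <= fft_size:
        return 1
    return int(np.ceil((n_samples - fft_size) / hop)) + 1


def stft(signal, spec: VocoderSpec, sample_rate: int | None = None) -> np.ndarray:
    """Short-time spectrum, shape ``(n_bins, n_frames)``.

    Frames of ``fft_size`` samples advance by ``fft_size * (1 - overlap)``
    samples; the signal is zero-padded on the right so the last frame is
    complete.  A periodic Hann analysis window is applied (constant
    overlap-add at 75% overlap).
    """
    if sample_rate is not None and sample_rate != spec.sample_rate:
        raise ValueError(
            f"signal sampled at {sample_rate} Hz but the spec expects "
            f"{spec.sample_rate} Hz; resample the input first"
        )
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("vocoder input must be a mono (1-D) signal")
    nfft, hop = spec.fft_size, spec.hop
    n_frames = _frame_count(len(x), nfft, hop)
    padded = np.zeros((n_frames - 1) * hop + nfft)
    padded[: len(x)] = x
    frames = np.lib.stride_tricks.sliding_window_view(padded, nfft)[::hop]
    window = hann(nfft, sym=False)
    return np.fft.rfft(frames * window, axis=1).T


@dataclass(frozen=True)
class EnvelopeMatrix:
    """Band-by-frame nonnegative envelope amplitudes."""

    values: np.ndarray  # (n_bands, n_frames)
    frame_hop: int
    band_centers: np.ndarray
    fft_size: int = field(default=128)

    def __post_init__(self):
        if (self.values < 0).any():
            raise ValueError("envelopes must be nonnegative")


def band_envelopes(spectrum: np.ndarray, filterbank: Filterbank,
                   spec: VocoderSpec) -> EnvelopeMatrix:
    """Per-band envelope: the square root of the total energy of the band's
    bins in each frame."""
    if spectrum.shape[0] != filterbank.n_bins:
        raise ValueError(
            f"spectrum has {spectrum.shape[0]} bins, filterbank expects "
            f"{filterbank.n_bins}"
        )
    power = np.abs(spectrum) ** 2
    vals = np.stack(
        [power[start:stop].sum(axis=0) for start, stop in filterbank.bin_slices]
    )
    return EnvelopeMatrix(
        values=np.sqrt(vals),
        frame_hop=spec.hop,
        band_centers=filterbank.band_centers,
        fft_size=spec.fft_size,
    )


def _carrier_gain(freqs: np.ndarray, e_lo: float, e_hi: float,
                  slope_db_per_octave: float) -> np.ndarray:
    """Amplitude gain of a band carrier: unity inside [e_lo, e_hi], decaying
    at ``slope_db_per_octave`` (in level) outside; zero at DC."""
    gain = np.ones_like(freqs)
    with np.errstate(divide="ignore"):
        below = freqs < e_lo
        octaves_below = np.log2(np.where(freqs > 0, e_lo / freqs, np.inf))
        gain = np.where(below, 10.0 ** (-slope_db_per_octave * octaves_below / 20.0), gain)
        above = freqs > e_hi
        octaves_above = np.log2(np.where(freqs > 0, freqs / e_hi, 1.0))
        gain = np.where(above, 10.0 ** (-slope_db_per_octave * octaves_above / 20.0), gain)
    gain[freqs == 0] = 0.0
    return gain


def synthesize(envelopes: EnvelopeMatrix, spec: VocoderSpec,
               n_samples: int | None = None) -> np.ndarray:
    """Sum of noise carriers amplitude-modulated by the band envelopes.

    Each band's carrier is seeded Gaussian noise spectrally shaped in the
    FFT domain (flat in-band, ``spread_slope`` dB/octave decay outside) and
    normalized to unit RMS; all bands share one seed stream
    (``spec.noise_seed``) and are drawn in band order.  The envelope is
    upsampled to the audio rate by linear interpolation between frame
    centers.  Output length is ``n_samples`` (default: the span of the
    frames).
    """
    n_bands, n_frames = envelopes.values.shape
    edges = spec.band_edges
    if n_bands != spec.n_bands:
        raise ValueError("envelope band count does not match the spec")
    hop, nfft = envelopes.frame_hop, envelopes.fft_size
    total = (n_frames - 1) * hop + nfft
    if n_samples is None:
        n_samples = total
    frame_centers = np.arange(n_frames) * hop + (nfft - 1) / 2.0
    t = np.arange(total)
    rng = np.random.default_rng(spec.noise_seed)
    freqs = np.fft.rfftfreq(total, d=1.0 / spec.sample_rate)
    out = np.zeros(total)
    for b in range(n_bands):
        white = rng.standard_normal(total)
        shaped = np.fft.irfft(
            np.fft.rfft(white)
            * _carrier_gain(freqs, edges[b], edges[b + 1], spec.spread_slope),
            total,
        )
        rms = np.sqrt(np.mean(shaped**2))
        if rms > 0:
            shaped /= rms
        env = np.interp(t, frame_centers, envelopes.values[b])
        out += shaped * env
    return out[:n_samples]


def vocode(signal, spec: VocoderSpec | None = None,
           sample_rate: int | None = None) -> np.ndarray:
    """Full vocoding chain: STFT -> band envelopes -> noise-carrier
    synthesis, deterministic given ``spec.noise_seed``.

    Output length equals input length and the output RMS is renormalized to
    the input RMS (loudness matching); silence maps to silence.
    """
    spec = spec or VocoderSpec()
    x = np.asarray(signal, dtype=float)
    spectrum = stft(x, spec, sample_rate=sample_rate)
    fb = design_filterbank(spec)
    env = band_envelopes(spectrum, fb, spec)
    out = synthesize(env, spec, n_samples=len(x))
    rms_in = np.sqrt(np.mean(x**2)) if len(x) else 0.0
    rms_out = np.sqrt(np.mean(out**2)) if len(out) else 0.0
    if rms_in > 0 and rms_out > 0:
        out *= rms_in / rms_out
    elif rms_in == 0:
        out[:] = 0.0
    return out


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a mono PCM WAV as float64 in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - (info.max + 1) / 2) / ((info.max + 1) / 2)
    else:
        data = data.astype(float)
    return rate, data


def write_wav(path, rate: int, signal: np.ndarray) -> None:
    """Write float signal as 16-bit PCM, clipping to [-1, 1]."""
    clipped = np.clip(np.asarray(signal, float), -1.0, 1.0)
    wavfile.write(path, rate, (clipped * 32767).astype(np.int16))
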