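"""Band-averaged wavelet-coherence functional connectivity.

FC between two regional BOLD series is the magnitude-squared wavelet
coherence, averaged over the 0.06-0.12 Hz band and over the whole scan.
The transform is a continuous complex-Morlet wavelet transform (centre
frequency omega0 = 6 rad) on a logarithmic grid of 12 frequencies spanning
0.04-0.18 Hz, so the analysis band is interior to the grid.

Coherence requires smoothing: the raw magnitude coherence of any two
series is identically 1, so cross- and auto-spectral densities are smoothed
in time (Gaussian window with standard deviation proportional to scale) and
across scales (boxcar over ~0.6 octaves) before forming the ratio

    C(s, t) = |S(W_x W_y* / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

which is bounded in [0, 1], symmetric, phase-blind and invariant to
rescaling of either input. Edge-affected coefficients inside the Morlet
cone of influence (e-folding time sqrt(2)*scale) are excluded from the
band-time mean by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pywt
from scipy import fft as spfft
from scipy.ndimage import uniform_filter1d

from planconn.graph_metrics import CoherenceMatrix

__all__ = [
    "WaveletSpec",
    "cwt",
    "wavelet_coherence",
    "band_mean_coherence",
    "connectivity_matrix",
]

# Torrence-Compo Morlet (omega0 = 6): Fourier period = _FOURIER_FACTOR * scale.
_OMEGA0 = 6.0
_FOURIER_FACTOR = 4.0 * np.pi / (_OMEGA0 + np.sqrt(2.0 + _OMEGA0**2))


@dataclass
class WaveletSpec:
    """Morlet CWT grid and smoothing rules for coherence estimation.

    ``time_smoothing_scale`` is the Gaussian standard deviation in units of
    the wavelet scale; ``scale_smoothing_octaves`` is the boxcar width across
    scales in octaves. ``coi_policy`` is ``"exclude"`` (drop edge-affected
    cells from band means) or ``"keep-all"``. ``squared`` selects
    magnitude-squared coherence (the stored FC value) vs its square root.
    """

    omega0: float = _OMEGA0
    freq_min_hz: float = 0.04
    freq_max_hz: float = 0.18
    n_scales: int = 12
    band_hz: tuple[float, float] = (0.06, 0.12)
    time_smoothing_scale: float = 1.0
    scale_smoothing_octaves: float = 0.6
    coi_policy: str = "exclude"
    squared: bool = True

    def __post_init__(self) -> None:
        if self.n_scales < 8:
            raise ValueError("scale grid must have at least 8 scales")
        lo, hi = self.band_hz
        if not (self.freq_min_hz <= lo < hi <= self.freq_max_hz):
            raise ValueError("analysis band must lie within the scale grid")
        if self.coi_policy not in ("exclude", "keep-all"):
            raise ValueError(f"unknown coi_policy {self.coi_policy!r}")

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.geomspace(self.freq_min_hz, self.freq_max_hz, self.n_scales)

    def validate_sampling(self, tr_s: float, n_volumes: int) -> None:
        nyquist = 0.5 / tr_s
        if self.freq_max_hz >= nyquist:
            raise ValueError(
                f"grid maximum {self.freq_max_hz} Hz is not below Nyquist {nyquist} Hz"
            )
        # need ~3 cycles of the slowest analyzed rhythm to resolve it
        if n_volumes * tr_s < 3.0 / self.band_hz[0]:
            raise ValueError(
                f"{n_volumes} volumes at TR={tr_s}s are too short to resolve "
                f"{self.band_hz[0]} Hz (need >= 3 cycles)"
            )

    def scales_samples(self, tr_s: float) -> np.ndarray:
        """pywt scales (in samples) matching the frequency grid."""
        wavelet = self.pywt_name
        fc = pywt.central_frequency(wavelet)
        return fc / (self.frequencies_hz * tr_s)

    @property
    def pywt_name(self) -> str:
        # cmorB-C with B=2.0 matches the canonical exp(-t^2/2) Morlet envelope
        return f"cmor2.0-{self.omega0 / (2 * np.pi):.8f}"

    def to_dict(self) -> dict:
        return asdict(self)


def cwt(signal: np.ndarray, tr_s: float, spec: WaveletSpec | None = None):
    """Complex Morlet CWT of one series at the spec's frequency grid.

    Returns ``(coeffs, freqs_hz)`` with coeffs of shape (n_scales, T).
    """
    spec = spec or WaveletSpec()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("cwt expects a single 1-D series")
    if len(x) < 64:
        raise ValueError(f"series too short for CWT: {len(x)} < 64 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples in input series")
    coeffs, freqs = _cwt_batch(x[None, :], tr_s, spec)
    return coeffs[0], freqs


def _cwt_batch(ts: np.ndarray, tr_s: float, spec: WaveletSpec):
    """CWT of (n_series, T) rows -> coeffs (n_series, n_scales, T)."""
    spec.validate_sampling(tr_s, ts.shape[-1])
    scales = spec.scales_samples(tr_s)
    coeffs, freqs = pywt.cwt(
        ts, scales, spec.pywt_name, sampling_period=tr_s, method="fft", axis=-1
    )
    # pywt puts the scale axis first; move it after the series axis
    return np.moveaxis(coeffs, 0, 1), freqs


def _smooth(surface: np.ndarray, scales_samples: np.ndarray, spec: WaveletSpec) -> np.ndarray:
    """Grinsted-style smoothing: Gaussian in time (sigma ~ scale), boxcar in scale.

    ``surface`` has shape (..., n_scales, T); may be complex. Time smoothing
    is applied spectrally (mirror-padded FFT with an analytic Gaussian
    transfer function per scale), which batches all scales and pairs into a
    single transform.
    """
    sigmas = spec.time_smoothing_scale * scales_samples
    T = surface.shape[-1]
    pad = min(T - 1, int(np.ceil(3.0 * sigmas.max())))
    left = surface[..., 1 : pad + 1][..., ::-1]
    right = surface[..., -pad - 1 : -1][..., ::-1]
    padded = np.concatenate([left, surface, right], axis=-1)
    n = spfft.next_fast_len(padded.shape[-1])
    freqs = np.fft.fftfreq(n)
    transfer = np.exp(-2.0 * (np.pi * freqs[None, :] * sigmas[:, None]) ** 2)
    if np.iscomplexobj(surface):
        spectrum = spfft.fft(padded, n=n, axis=-1)
        spectrum *= transfer
        out = spfft.ifft(spectrum, axis=-1, overwrite_x=True)[..., pad : pad + T]
    else:
        spectrum = spfft.rfft(padded, n=n, axis=-1)
        spectrum *= transfer[:, : spectrum.shape[-1]]
        out = spfft.irfft(spectrum, n=n, axis=-1, overwrite_x=True)[..., pad : pad + T]
    n_scale_window = max(1, int(round(spec.scale_smoothing_octaves / _mean_dj(spec))))
    if n_scale_window > 1:
        if np.iscomplexobj(out):
            out = uniform_filter1d(out.real, n_scale_window, axis=-2, mode="nearest") + (
                1j * uniform_filter1d(out.imag, n_scale_window, axis=-2, mode="nearest")
            )
        else:
            out = uniform_filter1d(out, n_scale_window, axis=-2, mode="nearest")
    return out


def _mean_dj(spec: WaveletSpec) -> float:
    return float(np.log2(spec.freq_max_hz / spec.freq_min_hz) / (spec.n_scales - 1))


def coi_mask(n_volumes: int, tr_s: float, spec: WaveletSpec) -> np.ndarray:
    """Boolean (n_scales, T) mask, True where a cell is OUTSIDE the cone of influence."""
    freqs = spec.frequencies_hz
    # Morlet scale in seconds (Fourier period / fourier factor), then the
    # sqrt(2)*scale e-folding time of the wavelet envelope at each scale
    tc_scale_s = (1.0 / freqs) / _FOURIER_FACTOR
    efold_s = np.sqrt(2.0) * tc_scale_s
    t = np.arange(n_volumes) * tr_s
    dist_edge = np.minimum(t, t[::-1])
    return dist_edge[None, :] >= efold_s[:, None]


def _pair_coherence_surfaces(
    w_pairs: np.ndarray, sxx_i: np.ndarray, sxx_j: np.ndarray, spec: WaveletSpec,
    scales: np.ndarray,
) -> np.ndarray:
    sxy = _smooth(w_pairs, scales, spec)
    coh = np.abs(sxy) ** 2 / (sxx_i * sxx_j)
    if not spec.squared:
        coh = np.sqrt(coh)
    return np.clip(coh, 0.0, 1.0)


def _check_variance(ts: np.ndarray, node_ids: list[str] | None = None) -> None:
    sd = ts.std(axis=-1)
    scale = np.maximum(1.0, np.abs(ts).max(axis=-1))
    bad = np.nonzero(sd <= 1e-12 * scale)[0]
    if bad.size:
        names = [node_ids[b] for b in bad] if node_ids else list(bad)
        raise ValueError(
            f"constant (zero-variance) series: coherence undefined for {names[:5]}"
        )


def wavelet_coherence(
    x: np.ndarray, y: np.ndarray, tr_s: float, spec: WaveletSpec | None = None
):
    """Full coherence surface for one pair: returns (coh (n_scales, T), freqs_hz)."""
    spec = spec or WaveletSpec()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    ts = np.stack([x, y])
    _check_variance(ts)
    w, freqs = _cwt_batch(ts, tr_s, spec)
    scales = spec.scales_samples(tr_s)
    s_col = scales[:, None]
    auto = _smooth(np.abs(w) ** 2 / s_col, scales, spec)
    coh = _pair_coherence_surfaces(
        (w[0] * np.conj(w[1]) / s_col)[None], auto[0][None], auto[1][None], spec, scales
    )[0]
    return coh, freqs


def _band_time_mean(coh: np.ndarray, n_volumes: int, tr_s: float, spec: WaveletSpec):
    """Mean of a coherence surface over band scales and retained time points."""
    freqs = spec.frequencies_hz
    lo, hi = spec.band_hz
    in_band = (freqs >= lo) & (freqs <= hi)
    if not in_band.any():
        raise ValueError("no grid scales inside the analysis band")
    if spec.coi_policy == "exclude":
        mask = coi_mask(n_volumes, tr_s, spec)[in_band]
    else:
        mask = np.ones((int(in_band.sum()), n_volumes), dtype=bool)
    if not mask.any():
        raise ValueError(
            "cone-of-influence masking removed every band cell; series too short "
            "(use coi_policy='keep-all')"
        )
    band = coh[..., in_band, :]
    return band[..., mask].mean(axis=-1)


def band_mean_coherence(
    x: np.ndarray, y: np.ndarray, tr_s: float, spec: WaveletSpec | None = None
) -> float:
    """Scalar FC value: coherence averaged over the band and the whole scan."""
    spec = spec or WaveletSpec()
    coh, _ = wavelet_coherence(x, y, tr_s, spec)
    return float(_band_time_mean(coh, coh.shape[-1], tr_s, spec))


def connectivity_matrix(
    timeseries: np.ndarray,
    tr_s: float,
    spec: WaveletSpec | None = None,
    node_ids: list[str] | None = None,
    pair_chunk: int = 256,
) -> CoherenceMatrix:
    """Band-mean wavelet coherence for every node pair of a (volumes x nodes) matrix.

    Per-node CWTs and smoothed auto-spectral densities are computed once and
    shared across the n(n-1)/2 pairs, which are processed in chunks.
    """
    spec = spec or WaveletSpec()
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("expected a (volumes x nodes) matrix with >= 2 nodes")
    n_vol, n_nodes = ts.shape
    if node_ids is None:
        node_ids = [f"node{i:03d}" for i in range(n_nodes)]
    if len(node_ids) != n_nodes:
        raise ValueError("node_ids length does not match number of columns")
    if not np.all(np.isfinite(ts)):
        bad = node_ids[int(np.nonzero(~np.isfinite(ts).all(axis=0))[0][0])]
        raise ValueError(f"non-finite samples in node {bad}")
    _check_variance(ts.T, node_ids)

    w, _ = _cwt_batch(ts.T, tr_s, spec)  # (nodes, scales, T)
    scales = spec.scales_samples(tr_s)
    s_col = scales[:, None]
    auto = _smooth(np.abs(w) ** 2 / s_col, scales, spec)

    ii, jj = np.triu_indices(n_nodes, k=1)
    values = np.eye(n_nodes)
    for start in range(0, len(ii), pair_chunk):
        ci = ii[start : start + pair_chunk]
        cj = jj[start : start + pair_chunk]
        cross = w[ci] * np.conj(w[cj]) / s_col
        coh = _pair_coherence_surfaces(cross, auto[ci], auto[cj], spec, scales)
        vals = _band_time_mean(coh, n_vol, tr_s, spec)
        values[ci, cj] = vals
        values[cj, ci] = vals
    return CoherenceMatrix(values, list(node_ids), band_hz=spec.band_hz)
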