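"""Raw-frame conditioning: dark subtraction, despiking, averaging, cropping.

Each acquisition is at least 180 s of ~1 Hz frames; preprocessing collapses
them into the single averaged, cropped spectrum that the decomposition
consumes.
"""

from __future__ import annotations

import logging

import numpy as np

from .grid import FrameSequence, Spectrum, WavenumberGrid

__all__ = ["subtract_dark", "despike", "rolling_average", "crop"]

logger = logging.getLogger(__name__)

#: analysis wavenumber window (cm^-1)
CROP_LOW = 600.0
CROP_HIGH = 1700.0


def subtract_dark(seq: FrameSequence, dark: Spectrum) -> FrameSequence:
    """Subtract the dark (detector background) spectrum from every frame.

    No clipping is applied; negative channels are allowed and logged, since
    the later averaging and regression are linear.
    """
    if dark.grid != seq.grid:
        raise ValueError("dark spectrum grid does not match frame grid")
    data = seq.data - dark.intensities[None, :]
    n_neg = int(np.sum(data < 0))
    if n_neg:
        logger.info("dark subtraction produced %d negative channel values", n_neg)
    return FrameSequence(seq.grid, data)


def despike(seq: FrameSequence, z_threshold: float = 8.0) -> FrameSequence:
    """Remove cosmic-ray spikes by across-frame median replacement.

    A channel in one frame is a spike when it exceeds the across-frame
    median at that channel by more than ``z_threshold`` robust standard
    deviations (MAD-based).  Spikes are replaced by the channel median;
    everything else is untouched.  Needs at least 3 frames; shorter
    sequences pass through with a warning.
    """
    if seq.n_frames < 3:
        logger.warning(
            "despike needs >=3 frames, got %d; sequence passed through", seq.n_frames
        )
        return FrameSequence(seq.grid, seq.data.copy(), dark=seq.dark)
    med = np.median(seq.data, axis=0)
    mad = np.median(np.abs(seq.data - med[None, :]), axis=0)
    robust_sd = 1.4826 * mad
    # a dead-flat channel has MAD 0; any deviation there is a spike
    mask = (seq.data - med[None, :]) > z_threshold * np.where(robust_sd > 0, robust_sd, np.inf)
    flat = robust_sd == 0
    if np.any(flat):
        mask[:, flat] = seq.data[:, flat] > med[flat][None, :]
    data = seq.data.copy()
    data[mask] = np.broadcast_to(med, data.shape)[mask]
    n_spikes = int(mask.sum())
    if n_spikes:
        logger.info("despike replaced %d channel values", n_spikes)
    return FrameSequence(seq.grid, data, dark=seq.dark)


def rolling_average(seq: FrameSequence, window: int = 180) -> Spectrum:
    """Average the final ``min(window, n)`` frames channel-wise.

    The instrument averages a rolling 180 s window to beat down shot noise;
    one acquisition yields one averaged spectrum.
    """
    if seq.n_frames == 0:
        raise ValueError("cannot average an empty frame sequence")
    if window < 1:
        raise ValueError("window must be >= 1")
    tail = seq.data[-min(window, seq.n_frames):]
    return Spectrum(seq.grid, tail.mean(axis=0))


def crop(s: Spectrum, low: float = CROP_LOW, high: float = CROP_HIGH) -> Spectrum:
    """Restrict a spectrum to the closed wavenumber interval [low, high]."""
    w = s.wavenumbers
    mask = (w >= low) & (w <= high)
    if not mask.any():
        raise ValueError(
            f"crop interval [{low}, {high}] does not overlap grid "
            f"[{s.grid.start}, {s.grid.stop}]"
        )
    kept = w[mask]
    new_grid = WavenumberGrid(float(kept[0]), float(kept[-1]), s.grid.step)
    return Spectrum(new_grid, s.intensities[mask])
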