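"""Band-pass filtering and windowed, peak-aligned spike waveform extraction.

Spike detection is deliberately out of scope: ground-truth spike times
shipped with (or simulated into) a recording are used directly.  Around
each event a 64-sample window is cut (20 samples left of the peak, 44 to
the right, the peak occupying the 20th sample in 1-based counting, i.e.
index 19 here), matching the benchmark datasets' convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.signal

from spikecompat.dataio import Recording

logger = logging.getLogger(__name__)

#: Total window length in samples.
WINDOW = 64
#: 0-based index of the aligned peak within the window (20th sample, 1-based).
PEAK_INDEX = 19
#: Samples kept left of the peak.
LEFT = 20
#: Samples kept right of the peak.
RIGHT = 44


@dataclass
class WaveformPool:
    """M peak-aligned 64-sample spike waveforms with ground-truth labels.

    Every row attains its maximum at column ``PEAK_INDEX`` (index 19,
    the 20th sample 1-based).  ``gt_labels`` holds the class (1..L) of
    each spike and ``spike_times`` the sample index of each peak in the
    source trace.
    """

    waveforms: np.ndarray
    gt_labels: np.ndarray
    spike_times: np.ndarray
    validate_alignment: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.waveforms = np.atleast_2d(np.asarray(self.waveforms, dtype=float))
        self.gt_labels = np.asarray(self.gt_labels).ravel().astype(np.int64)
        self.spike_times = np.asarray(self.spike_times).ravel().astype(np.int64)
        if self.waveforms.size == 0:
            self.waveforms = self.waveforms.reshape(0, WINDOW)
        if not (len(self.waveforms) == len(self.gt_labels) == len(self.spike_times)):
            raise ValueError(
                f"inconsistent pool: {len(self.waveforms)} waveforms, "
                f"{len(self.gt_labels)} labels, {len(self.spike_times)} times"
            )
        if self.validate_alignment and len(self.waveforms):
            peaks = np.argmax(self.waveforms, axis=1)
            if not np.all(peaks == PEAK_INDEX):
                bad = int(np.sum(peaks != PEAK_INDEX))
                raise ValueError(f"{bad} waveform(s) not peak-aligned at sample {PEAK_INDEX + 1} (1-based)")

    @property
    def M(self) -> int:
        return len(self.waveforms)

    @property
    def L(self) -> int:
        return len(np.unique(self.gt_labels)) if self.M else 0

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]


def bandpass_filter(
    recording: Recording,
    low_hz: float = 300.0,
    high_hz: float = 3000.0,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass filter of the voltage trace.

    Removes field potential (below ``low_hz``) and high-frequency noise.
    Applied forward-backward (``sosfiltfilt``) so spike peaks are not
    shifted in time.  Ground-truth times and labels pass through unchanged.
    """
    nyquist = recording.sampling_rate / 2.0
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"invalid band edges: need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyquist})"
        )
    sos = scipy.signal.butter(order, [low_hz, high_hz], btype="band", fs=recording.sampling_rate, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, recording.samples)
    return Recording(
        samples=filtered,
        sampling_rate=recording.sampling_rate,
        gt_times=None if recording.gt_times is None else recording.gt_times.copy(),
        gt_labels=None if recording.gt_labels is None else recording.gt_labels.copy(),
    )


def extract_waveforms(recording: Recording, *, peak: str = "max", max_realign: int = 8) -> WaveformPool:
    """Cut peak-aligned 64-sample windows around each ground-truth event.

    For each event time a provisional window is cut, the peak located
    within it, and the window re-cut so the peak sits at the 20th sample;
    the re-cut is iterated until stable (a larger sample can enter at the
    window edge).  Events whose final window would cross the trace bounds
    are dropped and counted in the log.

    Parameters
    ----------
    peak
        "max" aligns on the most positive sample (the benchmark templates
        are positive-peaked); "absmax" aligns on the largest magnitude,
        for negative-going data.
    """
    if peak not in ("max", "absmax"):
        raise ValueError(f"peak must be 'max' or 'absmax', got {peak!r}")
    if recording.gt_times is None:
        raise ValueError("recording has no ground-truth spike times")
    trace = recording.samples
    times = recording.gt_times
    labels = recording.gt_labels
    if times.size == 0:
        return WaveformPool(
            waveforms=np.empty((0, WINDOW)),
            gt_labels=np.empty(0, dtype=np.int64),
            spike_times=np.empty(0, dtype=np.int64),
        )

    def _peak_of(window: np.ndarray) -> int:
        return int(np.argmax(np.abs(window) if peak == "absmax" else window))

    rows, kept_labels, kept_times = [], [], []
    dropped = 0
    for i, t in enumerate(times):
        p = int(t)  # provisional peak position
        ok = False
        for _ in range(max_realign):
            start = p - PEAK_INDEX
            if start < 0 or start + WINDOW > len(trace):
                break
            window = trace[start : start + WINDOW]
            shift = _peak_of(window) - PEAK_INDEX
            if shift == 0:
                ok = True
                break
            p += shift
        if not ok:
            dropped += 1
            continue
        rows.append(trace[p - PEAK_INDEX : p - PEAK_INDEX + WINDOW])
        kept_labels.append(labels[i] if labels is not None else 1)
        kept_times.append(p)
    if dropped:
        logger.warning("extract_waveforms: dropped %d/%d events (window out of bounds or unstable peak)", dropped, len(times))
    if not rows:
        raise ValueError(f"all {len(times)} events fell outside the trace bounds")
    return WaveformPool(
        waveforms=np.asarray(rows),
        gt_labels=np.asarray(kept_labels, dtype=np.int64),
        spike_times=np.asarray(kept_times, dtype=np.int64),
        # the pool invariant (positive max at the 20th sample) only holds for
        # positive-peak alignment; absmax-aligned troughs are valid pools too
        validate_alignment=(peak == "max"),
    )
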