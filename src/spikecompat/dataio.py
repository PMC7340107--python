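"""Reading and writing ground-truthed recording containers and score tables.

Benchmark recordings in the Quiroga dialect are MAT v5 files holding a
single-channel voltage trace plus ground-truth spike times and class
labels.  The public files are not schema-stable (spike times appear under
several variable names, sometimes wrapped in one level of cell nesting),
so the reader probes a configurable name list.  A second entry mode reads
"waveform containers" where spike snippets are stored pre-extracted
(the dialect of the real temporal-lobe files such as times_CSC4).

Evaluation results are persisted as CSV tables (one per metric family)
plus a JSON summary so runs are diffable and bit-reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.io

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from spikecompat.preprocess import WaveformPool
    from spikecompat.validate import ScoreTable

logger = logging.getLogger(__name__)

#: Default sampling rate (Hz) assumed when a container does not store one.
DEFAULT_SAMPLING_RATE = 24000.0

#: Variable names probed, in order, for each field of a recording container.
TRACE_NAMES: tuple[str, ...] = ("data", "samples", "trace")
TIME_NAMES: tuple[str, ...] = ("spike_times", "spiketimes", "gt_times", "index")
CLASS_NAMES: tuple[str, ...] = ("spike_class", "spike_classes", "gt_labels")
RATE_NAMES: tuple[str, ...] = ("sampling_rate", "sr", "samplingInterval")
WAVEFORM_NAMES: tuple[str, ...] = ("spikes", "waveforms")
CLUSTER_CLASS_NAMES: tuple[str, ...] = ("cluster_class",)


class UnrecognizedContainerError(ValueError):
    """Raised when a MAT container does not expose the expected variables."""


class SchemaError(ValueError):
    """Raised when a persisted score table does not match the expected schema."""


@dataclass
class Recording:
    """A single-channel extracellular voltage trace with optional ground truth.

    Parameters
    ----------
    samples
        Voltage trace, arbitrary units.
    sampling_rate
        Sampling rate in Hz.
    gt_times
        Strictly increasing 0-based sample indices of spike events, or None.
    gt_labels
        Integer class (1..L) per event, same length as ``gt_times``, or None.
    """

    samples: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    gt_times: Optional[np.ndarray] = None
    gt_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.gt_times is not None:
            self.gt_times = np.asarray(self.gt_times).ravel().astype(np.int64)
            if self.gt_times.size and np.any(np.diff(self.gt_times) <= 0):
                raise ValueError("ground-truth spike times must be strictly increasing")
        if self.gt_labels is not None:
            if self.gt_times is None:
                raise ValueError("gt_labels given without gt_times")
            self.gt_labels = np.asarray(self.gt_labels).ravel().astype(np.int64)
            if len(self.gt_labels) != len(self.gt_times):
                raise ValueError(
                    f"gt_labels length {len(self.gt_labels)} != gt_times length {len(self.gt_times)}"
                )
            if self.gt_labels.size and self.gt_labels.min() < 1:
                raise ValueError("gt_labels must be integers >= 1")

    @property
    def n_events(self) -> int:
        return 0 if self.gt_times is None else len(self.gt_times)

    @property
    def n_classes(self) -> int:
        if self.gt_labels is None or self.gt_labels.size == 0:
            return 0
        return len(np.unique(self.gt_labels))


def _unwrap(value: np.ndarray) -> np.ndarray:
    """Unwrap MATLAB cell nesting and flatten to 1-D.

    A 1x1 cell is transparent; a cell array of several entries is
    concatenated in order (the public files store the class vector as the
    first cell, and the reader truncates to the event count).
    """
    arr = np.asarray(value)
    while arr.dtype == object:
        flat = arr.ravel()
        if flat.size == 0:
            return np.asarray([])
        if flat.size == 1:
            arr = np.asarray(flat[0])
        else:
            return np.concatenate([_unwrap(x) for x in flat])
    return arr.ravel()


def _probe(mat: dict, names: Sequence[str]) -> Optional[np.ndarray]:
    for name in names:
        if name in mat:
            return _unwrap(mat[name])
    return None


def read_quiroga_dataset(
    path,
    *,
    trace_names: Sequence[str] = TRACE_NAMES,
    time_names: Sequence[str] = TIME_NAMES,
    class_names: Sequence[str] = CLASS_NAMES,
    sampling_rate: Optional[float] = None,
) -> Recording:
    """Read a Quiroga-dialect MAT v5 recording container.

    Spike times stored in the file are taken to be sample indices.  When the
    container stores no sampling rate and none is supplied, 24 kHz is assumed.

    Raises
    ------
    UnrecognizedContainerError
        If no voltage trace variable is found; the message names the
        variables that *were* found so the caller can extend the name lists.
    """
    mat = scipy.io.loadmat(str(path))
    found = [k for k in mat if not k.startswith("__")]
    trace = _probe(mat, trace_names)
    if trace is None:
        raise UnrecognizedContainerError(
            f"unrecognized container layout in {path!s}: no voltage trace among "
            f"variables {found}; expected one of {list(trace_names)}"
        )
    times = _probe(mat, time_names)
    labels = _probe(mat, class_names)
    rate = sampling_rate
    if rate is None:
        stored = _probe(mat, RATE_NAMES)
        rate = float(stored[0]) if stored is not None and stored.size else DEFAULT_SAMPLING_RATE
    if times is not None and labels is not None and times.size and labels.size:
        # tolerate files where the class vector is longer (overlap bookkeeping)
        labels = labels[: times.size]
    rec = Recording(
        samples=trace.astype(float),
        sampling_rate=rate,
        gt_times=None if times is None else np.round(times).astype(np.int64),
        gt_labels=None if (labels is None or times is None) else labels,
    )
    logger.info("read %s: %d samples, %d events, %d classes", path, len(rec.samples), rec.n_events, rec.n_classes)
    return rec


def write_quiroga_dataset(recording: Recording, path) -> Path:
    """Write a Recording as a Quiroga-dialect MAT v5 container (round-trips)."""
    path = Path(path)
    out = {
        "data": recording.samples[None, :],
        "sampling_rate": np.asarray([[recording.sampling_rate]]),
    }
    if recording.gt_times is not None:
        out["spike_times"] = recording.gt_times[None, :].astype(float)
        if recording.gt_labels is not None:
            out["spike_class"] = recording.gt_labels[None, :].astype(float)
    scipy.io.savemat(str(path), out)
    return path


def read_waveform_container(path, *, keep_unsorted: bool = False) -> "WaveformPool":
    """Read a container of pre-extracted spike waveforms (times_CSC4 dialect).

    Expects an M x n_samples ``spikes`` matrix and an M x 2 ``cluster_class``
    matrix whose first column is the class label and second column the spike
    time.  Label 0 marks unsorted spikes in the public files; those rows are
    dropped by default (``keep_unsorted=True`` keeps them as class L+1).
    """
    from spikecompat.preprocess import WaveformPool

    mat = scipy.io.loadmat(str(path))
    found = [k for k in mat if not k.startswith("__")]
    waveforms = None
    for name in WAVEFORM_NAMES:
        if name in mat:
            waveforms = np.atleast_2d(np.asarray(mat[name], dtype=float))
            break
    cc = None
    for name in CLUSTER_CLASS_NAMES:
        if name in mat:
            cc = np.atleast_2d(np.asarray(mat[name], dtype=float))
            break
    if waveforms is None or cc is None:
        raise UnrecognizedContainerError(
            f"unrecognized waveform container layout in {path!s}: found {found}; "
            f"expected {list(WAVEFORM_NAMES)} and {list(CLUSTER_CLASS_NAMES)}"
        )
    labels = np.round(cc[:, 0]).astype(np.int64)
    times = cc[:, 1]
    keep = np.ones(len(labels), dtype=bool)
    if np.any(labels < 1):
        if keep_unsorted:
            labels = labels.copy()
            labels[labels < 1] = labels.max() + 1
        else:
            keep = labels >= 1
            warnings.warn(
                f"dropping {int((~keep).sum())} unsorted (class-0) waveforms", stacklevel=2
            )
    order = np.argsort(times[keep], kind="stable")
    return WaveformPool(
        waveforms=waveforms[keep][order],
        gt_labels=labels[keep][order],
        spike_times=np.arange(int(keep.sum()), dtype=np.int64),
        validate_alignment=False,
    )


# ---------------------------------------------------------------------------
# Score table persistence

_EXTERNAL = ("rand", "jaccard", "accuracy")
_INTERNAL = ("DB", "BH", "TrW")

_SCORE_COLUMNS = ["algorithm", "featureset", "criterion", "raw", "normalized", "reference", "flag"]
_CONSISTENCY_COLUMNS = ["algorithm", "rmse", "inverted", "n_feature_sets", "category"]
_NIIVAR_COLUMNS = ["algorithm", "featureset", "variance"]


def write_score_table(table: "ScoreTable", path) -> Path:
    """Persist a ScoreTable to a directory: external.csv, internal.csv,
    consistency.csv, nii_variance.csv and summary.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scores = table.scores
    ext = scores[scores["criterion"].isin(_EXTERNAL)] if len(scores) else scores
    internal = scores[scores["criterion"].isin(_INTERNAL)] if len(scores) else scores
    ext.to_csv(path / "external.csv", index=False)
    internal.to_csv(path / "internal.csv", index=False)
    table.consistency.to_csv(path / "consistency.csv", index=False)
    table.nii_variance.to_csv(path / "nii_variance.csv", index=False)
    with open(path / "summary.json", "w") as fh:
        json.dump({"schema": 1, "metadata": table.metadata}, fh, indent=2, sort_keys=True, default=str)
    return path


def read_score_table(path) -> "ScoreTable":
    """Read a ScoreTable written by :func:`write_score_table`."""
    from spikecompat.validate import ScoreTable

    path = Path(path)
    required = ["external.csv", "internal.csv", "consistency.csv", "nii_variance.csv", "summary.json"]
    missing = [f for f in required if not (path / f).exists()]
    if missing:
        raise SchemaError(f"score table at {path!s} is missing {missing}")

    def _read(name: str, columns: list[str]) -> pd.DataFrame:
        df = pd.read_csv(path / name)
        if list(df.columns) != columns:
            raise SchemaError(f"{name}: expected columns {columns}, found {list(df.columns)}")
        if "flag" in columns:
            df["flag"] = df["flag"].fillna("").astype(str) if len(df) else df["flag"]
        return df

    ext = _read("external.csv", _SCORE_COLUMNS)
    internal = _read("internal.csv", _SCORE_COLUMNS)
    frames = [f for f in (ext, internal) if len(f)]
    scores = pd.concat(frames, ignore_index=True) if frames else ext
    consistency = _read("consistency.csv", _CONSISTENCY_COLUMNS)
    nii_variance = _read("nii_variance.csv", _NIIVAR_COLUMNS)
    with open(path / "summary.json") as fh:
        summary = json.load(fh)
    return ScoreTable(
        scores=scores,
        consistency=consistency,
        nii_variance=nii_variance,
        metadata=summary.get("metadata", {}),
    )
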