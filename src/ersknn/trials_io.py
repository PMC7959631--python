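"""Labelled trial containers and the on-disk trial archive.

The central container is :class:`TrialSet`: an epoched multichannel
recording stored as a ``trials x channels x samples`` tensor with aligned
integer class labels, a sampling rate, and channel/class name tables.

The archive format is deliberately simple and language-neutral: a single
file holding one JSON manifest line (UTF-8, terminated by ``\\n``) followed
by the raw numeric payload — the data tensor as little-endian float64 in C
order, then the labels as little-endian int64.  The manifest records the
shapes, names, sampling metadata and a SHA-256 digest of the payload so a
reader can verify integrity before trusting the numbers.  Two writes of the
same TrialSet are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

ARCHIVE_VERSION = "ersknn-archive-1"


class ArchiveError(ValueError):
    """Raised when an archive fails validation on read or write."""


@dataclass
class TrialSet:
    """Epoched multichannel trials with per-trial class labels.

    Parameters
    ----------
    data
        Real-valued array of shape ``(n_trials, n_channels, n_samples)``.
        Units are microvolts for real recordings, arbitrary for synthetic.
    labels
        0-based integer class label per trial, indexing ``class_names``.
    fs
        Sampling rate in Hz; must be positive.
    class_names
        Display name per class index.
    channel_names
        Ordered channel labels; defaults to ``ch00, ch01, ...``.
    t0
        Epoch start time in seconds relative to the cue (metadata only).
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    class_names: list[str] = field(default_factory=list)
    channel_names: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (trials, channels, samples); got shape {self.data.shape}"
            )
        if self.labels.ndim != 1 or self.labels.shape[0] != self.data.shape[0]:
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"trial count {self.data.shape[0]}"
            )
        if not self.class_names:
            n_cls = int(self.labels.max()) + 1 if self.labels.size else 0
            self.class_names = [f"class{i}" for i in range(n_cls)]
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise ValueError(
                "labels must be 0-based indices into class_names; "
                f"got range [{self.labels.min()}, {self.labels.max()}] "
                f"for {len(self.class_names)} classes"
            )
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"channel_names length {len(self.channel_names)} does not match "
                f"channel count {self.data.shape[1]}"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive; got {self.fs}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def classes_present(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_counts(self) -> np.ndarray:
        """Trial count per class index (length = number of named classes)."""
        return np.bincount(self.labels, minlength=len(self.class_names))


@dataclass
class ArchiveManifest:
    """Header metadata for the on-disk trial archive."""

    version: str
    shape: tuple[int, int, int]
    class_names: list[str]
    channel_names: list[str]
    fs: float
    t0: float
    checksum: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "shape": list(self.shape),
                "class_names": self.class_names,
                "channel_names": self.channel_names,
                "fs": self.fs,
                "t0": self.t0,
                "dtype": "<f8",
                "label_dtype": "<i8",
                "checksum": self.checksum,
            },
            sort_keys=True,
        )


def _payload_bytes(tset: TrialSet) -> bytes:
    data = np.ascontiguousarray(tset.data, dtype="<f8")
    labels = np.ascontiguousarray(tset.labels, dtype="<i8")
    return data.tobytes() + labels.tobytes()


def write_archive(tset: TrialSet, path: str | Path) -> None:
    """Serialise a TrialSet to a single archive file.

    Refuses degenerate (0-trial) sets: an empty archive is almost always an
    upstream bug, not a dataset.
    """
    if tset.n_trials == 0:
        raise ArchiveError("refusing to write degenerate archive: 0 trials")
    payload = _payload_bytes(tset)
    manifest = ArchiveManifest(
        version=ARCHIVE_VERSION,
        shape=tset.data.shape,
        class_names=list(tset.class_names),
        channel_names=list(tset.channel_names),
        fs=float(tset.fs),
        t0=float(tset.t0),
        checksum=hashlib.sha256(payload).hexdigest(),
    )
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(manifest.to_json().encode("utf-8"))
        fh.write(b"\n")
        fh.write(payload)


def read_archive(path: str | Path) -> TrialSet:
    """Read a TrialSet back from an archive file, verifying the checksum."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"archive not found: {path}")
    with open(path, "rb") as fh:
        header = fh.readline()
        payload = fh.read()
    try:
        meta = json.loads(header.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ArchiveError(f"manifest line does not parse: {exc}") from exc
    version = meta.get("version")
    if version != ARCHIVE_VERSION:
        raise ArchiveError(
            f"version mismatch: file has {version!r}, reader expects {ARCHIVE_VERSION!r}"
        )
    digest = hashlib.sha256(payload).hexdigest()
    if digest != meta["checksum"]:
        raise ArchiveError(
            f"checksum failure: payload digest {digest[:12]}... does not match "
            f"manifest checksum {meta['checksum'][:12]}..."
        )
    n_tr, n_ch, n_s = (int(v) for v in meta["shape"])
    n_data_bytes = n_tr * n_ch * n_s * 8
    expected = n_data_bytes + n_tr * 8
    if len(payload) != expected:
        raise ArchiveError(
            f"shape inconsistency: manifest shape {meta['shape']} implies "
            f"{expected} payload bytes, file has {len(payload)}"
        )
    data = np.frombuffer(payload[:n_data_bytes], dtype="<f8").reshape(n_tr, n_ch, n_s)
    labels = np.frombuffer(payload[n_data_bytes:], dtype="<i8")
    try:
        return TrialSet(
            data=data.copy(),
            labels=labels.copy(),
            fs=float(meta["fs"]),
            class_names=list(meta["class_names"]),
            channel_names=list(meta["channel_names"]),
            t0=float(meta["t0"]),
        )
    except ValueError as exc:
        raise ArchiveError(f"archive content violates TrialSet invariants: {exc}") from exc


def select_window(tset: TrialSet, start_s: float, end_s: float) -> TrialSet:
    """Crop every epoch to the half-open time window ``[start_s, end_s)``.

    Times are in seconds relative to the epoch start.  Sample index
    ``i = floor(t * fs)``, so composing two crops equals one crop with the
    intersected window and no boundary sample is counted twice.
    """
    if not (0.0 <= start_s < end_s):
        raise ValueError(f"need 0 <= start_s < end_s; got [{start_s}, {end_s})")
    if end_s > tset.duration_s + 0.5 / tset.fs:
        raise ValueError(
            f"window end {end_s}s outside epoch of duration {tset.duration_s}s"
        )
    i0 = int(np.floor(start_s * tset.fs))
    i1 = int(np.floor(end_s * tset.fs))
    i1 = min(i1, tset.n_samples)
    return replace(
        tset,
        data=tset.data[:, :, i0:i1].copy(),
        labels=tset.labels.copy(),
        t0=tset.t0 + start_s,
        class_names=list(tset.class_names),
        channel_names=list(tset.channel_names),
    )


def export_csv(tset: TrialSet, directory: str | Path) -> None:
    """Plain-text export for inspection: one CSV per trial plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(tset.n_trials):
        np.savetxt(
            directory / f"trial{i:04d}.csv",
            tset.data[i].T,
            delimiter=",",
            header=",".join(tset.channel_names),
            comments="",
        )
    manifest = {
        "fs": tset.fs,
        "t0": tset.t0,
        "class_names": tset.class_names,
        "labels": tset.labels.tolist(),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
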