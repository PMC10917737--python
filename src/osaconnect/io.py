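"""Reading, writing and epoching of multichannel EEG recordings.

Two on-disk forms are supported: EDF (the format polysomnography systems
ship) and a plain-text columnar format used for small fixtures and for
synthetic cohorts.  Amplitudes are kept in microvolts throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Recording",
    "Epoch",
    "ChannelNotFoundError",
    "read_edf",
    "write_edf",
    "read_columnar",
    "write_columnar",
    "make_epochs",
]

GROUP_LABELS = ("OSA", "HEALTHY", "UNKNOWN")

#: the four ISRUC EEG derivations used throughout
DEFAULT_CHANNELS = ("F4-A1", "F3-A2", "O1-A2", "O2-A1")


class ChannelNotFoundError(KeyError):
    """A requested channel label is absent from a recording or file."""


def _canon(label: str) -> str:
    """Canonical form of a channel label: case and separator insensitive."""
    return "".join(ch for ch in label.upper() if ch.isalnum())


@dataclass
class Recording:
    """A multichannel sampled signal with channel labels and sampling rate.

    Parameters
    ----------
    channel_labels : list of str
        Unique channel names, one per data row (e.g. ``"F4-A1"``).
    fs : float
        Sampling rate in Hz; must be positive.
    data : ndarray, shape (n_channels, n_samples)
        Signal amplitudes in microvolts.
    subject_id : str
        Identifier of the subject the recording belongs to.
    group_label : {"OSA", "HEALTHY", "UNKNOWN"}
        Clinical group assignment.
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    subject_id: str = ""
    group_label: str = "UNKNOWN"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN or Inf samples")
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"group_label must be one of {GROUP_LABELS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def select(self, wanted: Sequence[str]) -> "Recording":
        """Return a copy holding ``wanted`` channels in the requested order.

        Matching is case-insensitive and tolerant of separator variants
        ("F4-A1" == "F4_A1" == "f4a1").
        """
        canon = {_canon(lbl): i for i, lbl in enumerate(self.channel_labels)}
        rows = []
        for w in wanted:
            key = _canon(w)
            if key not in canon:
                raise ChannelNotFoundError(
                    f"channel {w!r} not found; available: {self.channel_labels}"
                )
            rows.append(canon[key])
        return Recording(
            channel_labels=[str(w) for w in wanted],
            fs=self.fs,
            data=self.data[rows].copy(),
            subject_id=self.subject_id,
            group_label=self.group_label,
        )


@dataclass
class Epoch:
    """A fixed-length, non-overlapping analysis window of a recording."""

    subject_id: str
    index: int
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("epoch index must be >= 0")


def make_epochs(rec: Recording, epoch_seconds: float) -> list[Epoch]:
    """Cut a recording into contiguous non-overlapping fixed-length epochs.

    Trailing samples that do not fill a whole epoch are discarded.
    Concatenating the returned epochs reproduces the truncated recording
    exactly.
    """
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    n_per = int(round(rec.fs * epoch_seconds))
    n_ep = rec.n_samples // n_per
    if n_ep == 0:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s is shorter than one "
            f"{epoch_seconds:.0f} s epoch"
        )
    return [
        Epoch(rec.subject_id, i, rec.data[:, i * n_per : (i + 1) * n_per].copy())
        for i in range(n_ep)
    ]


# ---------------------------------------------------------------------------
# columnar text format
# ---------------------------------------------------------------------------

def write_columnar(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a TSV table with ``# key=value`` metadata lines.

    The format is lossless at full floating precision: one header row of
    channel labels, one column per channel, sampling rate in a ``# fs=``
    comment.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write(f"# group={rec.group_label}\n")
        fh.write("\t".join(rec.channel_labels) + "\n")
        for row in rec.data.T:
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")
    return path


def read_columnar(path: str | Path) -> Recording:
    """Read a recording from the columnar text format.

    Raises
    ------
    FileNotFoundError
        Missing file.
    ValueError
        Ragged rows, non-numeric cells, or a missing ``# fs=`` line.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    labels: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            cells = line.split("\t")
            if labels is None:
                labels = [c.strip() for c in cells]
                continue
            if len(cells) != len(labels):
                raise ValueError(
                    f"{path.name}:{lineno}: ragged row with {len(cells)} values "
                    f"in a {len(labels)}-channel table"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-numeric cell ({exc})")
    if labels is None or not rows:
        raise ValueError(f"{path.name}: no data rows")
    if "fs" not in meta:
        raise ValueError(f"{path.name}: missing '# fs=<Hz>' metadata line")
    return Recording(
        channel_labels=labels,
        fs=float(meta["fs"]),
        data=np.array(rows, dtype=float).T,
        subject_id=meta.get("subject_id", path.stem),
        group_label=meta.get("group", "UNKNOWN"),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _read_edf_channel_rates(path: Path) -> dict[str, float]:
    """Per-channel sampling rates straight from the EDF header.

    EDF permits a different rate per signal; reading the header directly lets
    us *reject* mixed-rate selections instead of silently resampling.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise ValueError(f"{path.name}: truncated EDF header")
        record_dur = float(header[244:252].decode("ascii").strip() or 1.0)
        ns = int(header[252:256].decode("ascii").strip())
        sig = fh.read(256 * ns)
    labels = [
        sig[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    rates = {}
    for i in range(ns):
        nspr = int(sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
        rates[labels[i]] = nspr / record_dur
    return rates


def read_edf(
    path: str | Path,
    wanted_channels: Sequence[str] = DEFAULT_CHANNELS,
    subject_id: str | None = None,
    group_label: str = "UNKNOWN",
) -> Recording:
    """Read selected channels of an EDF file into a :class:`Recording`.

    Channel matching is case-insensitive and tolerant of separator variants.
    Selections mixing channels recorded at different sampling rates are
    rejected rather than resampled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    rates = _read_edf_channel_rates(path)
    canon_rates = {_canon(k): (k, v) for k, v in rates.items()}
    picked_rates = []
    for w in wanted_channels:
        key = _canon(w)
        if key not in canon_rates:
            raise ChannelNotFoundError(
                f"channel {w!r} not found in {path.name}; "
                f"available: {sorted(rates)}"
            )
        picked_rates.append(canon_rates[key][1])
    if len(set(picked_rates)) > 1:
        raise ValueError(
            f"selected channels have mixed sampling rates {picked_rates}; "
            "resampling is not performed"
        )

    import mne  # heavy import, keep local

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    canon_names = {_canon(n): n for n in raw.ch_names}
    picks = [canon_names[_canon(w)] for w in wanted_channels]
    data = raw.get_data(picks=picks, units="uV")
    rec = Recording(
        channel_labels=[str(w) for w in wanted_channels],
        fs=float(picked_rates[0]),
        data=np.asarray(data, dtype=float),
        subject_id=subject_id if subject_id is not None else path.stem,
        group_label=group_label,
    )
    return rec


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a 16-bit EDF file (test-fixture writer).

    One data record per second; the recording is truncated to a whole number
    of seconds and the sampling rate must be an integer.  Physical range is
    taken per channel from the data, so the quantization step of channel *i*
    is ``(max_i - min_i) / 65535`` microvolts.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF fixture writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = rec.n_samples // fs
    if n_rec == 0:
        raise ValueError("recording shorter than one second")
    data = rec.data[:, : n_rec * fs]
    nch = rec.n_channels

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    def f(x: object, width: int) -> bytes:
        s = str(x)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join(
        [
            f("0", 8),
            f(rec.subject_id or "X", 80),
            f("osaconnect fixture", 80),
            f("01.01.24", 8),
            f("00.00.00", 8),
            f(256 * (1 + nch), 8),
            f("", 44),
            f(n_rec, 8),
            f(1, 8),
            f(nch, 4),
        ]
    )
    fields: list[bytes] = []
    for spec_fn, width in [
        (lambda i: rec.channel_labels[i], 16),
        (lambda i: "", 80),
        (lambda i: "uV", 8),
        (lambda i: f"{pmin[i]:.6g}"[:8], 8),
        (lambda i: f"{pmax[i]:.6g}"[:8], 8),
        (lambda i: dmin, 8),
        (lambda i: dmax, 8),
        (lambda i: "", 80),
        (lambda i: fs, 8),
        (lambda i: "", 32),
    ]:
        for i in range(nch):
            fields.append(f(spec_fn(i), width))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        for r in range(n_rec):
            for i in range(nch):
                fh.write(digital[i, r * fs : (r + 1) * fs].tobytes())
    return path


def edf_quantization_step(rec: Recording) -> np.ndarray:
    """Per-channel quantization step the EDF fixture writer will apply."""
    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    rng = np.where(pmax - pmin <= 0, 1.0, pmax - pmin)
    return rng / 65535.0
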