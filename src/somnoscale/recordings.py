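"""Data model for iEEG epochs and channels, file I/O, and the region taxonomy.

An :class:`Epoch` is one 60-second multichannel intracranial EEG segment with
a vigilance-state label (W, N2, N3 or R) and per-channel anatomical metadata.
Channels map into a fixed taxonomy of 38 brain regions grouped into six lobes;
the taxonomy ships with the package as a TSV resource.

Supported on-disk formats:

* EDF (European Data Format), read-only, with a key:value sidecar file that
  carries the state label and the channel -> (patient, region) mapping which
  EDF labels alone cannot encode;
* a columnar text format (TSV, one column per channel) with a structured
  metadata sidecar, read/write — this is the round-trippable format the
  synthetic generators emit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four vigilance-state labels used throughout the package.
STATES = ("W", "N2", "N3", "R")

#: The six lobes of the packaged taxonomy.
LOBES = (
    "Occipital",
    "Parietal",
    "Insular",
    "Medial frontal",
    "Lateral frontal",
    "Temporal",
)


class RecordingError(ValueError):
    """Raised for malformed inputs: bad files, inconsistent metadata."""


@dataclass(frozen=True)
class ChannelInfo:
    """Anatomical metadata for a single iEEG channel.

    ``region_id`` is 1..38 per the packaged taxonomy, or ``None`` for
    channels that could not be matched to a region (such channels are kept in
    epochs but excluded from region-level aggregation).
    """

    channel_id: str
    patient_id: str = ""
    region_id: int | None = None
    region_name: str | None = None
    lobe: str | None = None

    def __post_init__(self):
        if self.region_id is not None:
            tax = load_taxonomy()
            if self.region_id not in tax.index:
                raise RecordingError(
                    f"region_id {self.region_id} outside 1..38 "
                    f"(channel {self.channel_id!r})"
                )
            row = tax.loc[self.region_id]
            # fill or validate derived fields against the taxonomy
            for fld, expected in (("region_name", row["region_name"]),
                                  ("lobe", row["lobe"])):
                got = getattr(self, fld)
                if got is None:
                    object.__setattr__(self, fld, expected)
                elif got != expected:
                    raise RecordingError(
                        f"channel {self.channel_id!r}: {fld}={got!r} "
                        f"inconsistent with region_id {self.region_id} "
                        f"({expected!r})"
                    )


@dataclass
class Epoch:
    """One fixed-length multichannel signal segment.

    ``samples`` is channel-major: shape ``(n_channels, N)`` with
    ``N = round(fs * duration_s)`` samples per channel.
    """

    samples: np.ndarray
    fs: float = 200.0
    state: str = "W"
    channels: list[ChannelInfo] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.state not in STATES:
            raise RecordingError(
                f"state {self.state!r} not one of {STATES}; labels are not coerced"
            )
        if not np.all(np.isfinite(self.samples)):
            raise RecordingError("non-finite samples in epoch")
        if not self.channels:
            self.channels = [
                ChannelInfo(channel_id=f"ch{i}")
                for i in range(self.samples.shape[0])
            ]
        if len(self.channels) != self.samples.shape[0]:
            raise RecordingError(
                f"{len(self.channels)} channel metadata entries for "
                f"{self.samples.shape[0]} signal rows"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


_TAXONOMY_CACHE: pd.DataFrame | None = None


def load_taxonomy() -> pd.DataFrame:
    """Load the packaged 38-region taxonomy.

    Returns a DataFrame indexed by ``region_id`` with columns
    ``region_name``, ``lobe`` and per-state channel counts
    ``n_channels_W/N2/N3/R``.
    """
    global _TAXONOMY_CACHE
    if _TAXONOMY_CACHE is None:
        with resources.files("somnoscale.data").joinpath("regions.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
        df = df.set_index("region_id")
        assert len(df) == 38, "packaged taxonomy must have exactly 38 regions"
        _TAXONOMY_CACHE = df
    return _TAXONOMY_CACHE


def region_lookup(region_id: int) -> tuple[str, str]:
    """Return ``(region_name, lobe)`` for a region id in 1..38."""
    tax = load_taxonomy()
    if region_id not in tax.index:
        raise RecordingError(f"region_id {region_id} outside 1..38")
    row = tax.loc[region_id]
    return str(row["region_name"]), str(row["lobe"])


def zscore(epoch: Epoch) -> Epoch:
    """Normalize each channel to zero mean and unit standard deviation.

    Raises on constant channels (zero variance), identifying the offender.
    """
    x = epoch.samples
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        names = [epoch.channels[i].channel_id for i in flat]
        raise RecordingError(f"constant channel(s), cannot z-score: {names}")
    return replace(epoch, samples=(x - mu) / sd, channels=list(epoch.channels))


# ---------------------------------------------------------------------------
# sidecar metadata
# ---------------------------------------------------------------------------

def _parse_sidecar(path: str | Path) -> dict:
    """Parse the key:value sidecar format.

    Scalar lines are ``key: value``. Channel lines live under a ``channels:``
    header, one per line: ``  <label>: <patient_id>,<region_id>`` where
    region_id may be empty for unmapped channels.
    """
    meta: dict = {"channels": {}}
    in_channels = False
    for raw in Path(path).read_text().splitlines():
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        if raw.strip() == "channels:":
            in_channels = True
            continue
        key, _, value = raw.partition(":")
        if in_channels and raw.startswith((" ", "\t")):
            patient, _, rid = value.strip().partition(",")
            meta["channels"][key.strip()] = (
                patient.strip(),
                int(rid) if rid.strip() else None,
            )
        else:
            in_channels = False
            meta[key.strip()] = value.strip()
    return meta


def _write_sidecar(path: str | Path, fs: float, state: str,
                   duration_s: float, channels: list[ChannelInfo]) -> None:
    lines = [f"fs: {fs!r}", f"state: {state}", f"duration_s: {duration_s!r}",
             "channels:"]
    for ch in channels:
        rid = "" if ch.region_id is None else str(ch.region_id)
        lines.append(f"  {ch.channel_id}: {ch.patient_id},{rid}")
    Path(path).write_text("\n".join(lines) + "\n")


def _channels_from_sidecar(labels: list[str], meta: dict) -> list[ChannelInfo]:
    have_map = bool(meta["channels"])
    out = []
    for lab in labels:
        if lab in meta["channels"]:
            patient, rid = meta["channels"][lab]
            out.append(ChannelInfo(channel_id=lab, patient_id=patient,
                                   region_id=rid))
        else:
            if have_map:
                logger.warning("channel %r not in sidecar; carried unmapped", lab)
            out.append(ChannelInfo(channel_id=lab))
    return out


def _slice_epochs(data: np.ndarray, fs: float, state: str,
                  channels: list[ChannelInfo],
                  duration_s: float = 60.0) -> list[Epoch]:
    """Cut a long record into non-overlapping fixed-length epochs.

    Blocks are aligned to record start; a shorter trailing block is dropped
    with a warning.
    """
    n_per = int(round(fs * duration_s))
    n_blocks = data.shape[1] // n_per
    rem = data.shape[1] - n_blocks * n_per
    if rem:
        logger.warning("dropping %d trailing samples (< one %g s epoch)",
                       rem, duration_s)
    if n_blocks == 0:
        warnings.warn(
            f"record shorter than one {duration_s:g} s epoch; no epochs produced",
            stacklevel=3,
        )
    return [
        Epoch(samples=data[:, b * n_per:(b + 1) * n_per].copy(), fs=fs,
              state=state, channels=list(channels))
        for b in range(n_blocks)
    ]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def read_edf(path: str | Path, state: str,
             sidecar: str | Path | None = None,
             duration_s: float = 60.0) -> list[Epoch]:
    """Read an EDF file and slice it into non-overlapping epochs.

    Parameters
    ----------
    path : EDF file.
    state : vigilance-state label for every produced epoch (W/N2/N3/R).
    sidecar : optional metadata file mapping channel labels to
        (patient_id, region_id); unmatched channels are carried with
        ``region_id=None``.
    duration_s : epoch length; trailing shorter blocks are dropped.
    """
    import mne

    if state not in STATES:
        raise RecordingError(f"state {state!r} not one of {STATES}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises several types for bad files
        raise RecordingError(f"unreadable EDF file {path}: {exc}") from exc

    # mne resamples heterogeneous-rate EDF channels silently on preload;
    # detect the original rates from the private EDF header to refuse them.
    orig = getattr(raw, "_raw_extras", [{}])[0]
    n_samps = orig.get("n_samps")
    if n_samps is not None and len(set(np.asarray(n_samps).tolist())) > 1:
        rates = {
            raw.ch_names[i]: float(n_samps[i] / orig["record_length"][0])
            for i in range(len(raw.ch_names))
        }
        raise RecordingError(
            f"heterogeneous sampling rates across channels: {rates}"
        )

    fs = float(raw.info["sfreq"])
    data = raw.get_data()  # volts; scale irrelevant downstream (z-scoring)
    meta = _parse_sidecar(sidecar) if sidecar is not None else {"channels": {}}
    channels = _channels_from_sidecar(list(raw.ch_names), meta)
    return _slice_epochs(np.asarray(data, float), fs, state, channels,
                         duration_s)


# ---------------------------------------------------------------------------
# columnar text format
# ---------------------------------------------------------------------------

def write_columnar(epoch: Epoch, data_path: str | Path,
                   metadata_path: str | Path, float_fmt: str = "%.10g") -> None:
    """Write an epoch as TSV (one column per channel) plus metadata sidecar."""
    labels = [ch.channel_id for ch in epoch.channels]
    header = "\t".join(labels)
    np.savetxt(data_path, epoch.samples.T, delimiter="\t", fmt=float_fmt,
               header=header, comments="")
    _write_sidecar(metadata_path, epoch.fs, epoch.state, epoch.duration_s,
                   epoch.channels)


def read_columnar(data_path: str | Path,
                  metadata_path: str | Path) -> list[Epoch]:
    """Read the columnar TSV + sidecar pair written by :func:`write_columnar`.

    Long records are sliced into epochs of the sidecar's ``duration_s``.
    """
    meta = _parse_sidecar(metadata_path)
    try:
        fs = float(meta["fs"])
        state = meta["state"]
        duration_s = float(meta.get("duration_s", 60.0))
    except KeyError as exc:
        raise RecordingError(f"sidecar missing required key: {exc}") from exc

    with open(data_path) as fh:
        labels = fh.readline().rstrip("\n").split("\t")
    try:
        data = np.loadtxt(data_path, delimiter="\t", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise RecordingError(f"non-numeric cell in {data_path}: {exc}") from exc
    data = data.T  # to channel-major

    if meta["channels"] and len(meta["channels"]) != data.shape[0]:
        raise RecordingError(
            f"metadata lists {len(meta['channels'])} channels but file has "
            f"{data.shape[0]} columns"
        )
    if len(labels) != data.shape[0]:
        raise RecordingError(
            f"header has {len(labels)} labels for {data.shape[0]} columns"
        )
    channels = _channels_from_sidecar(labels, meta)
    if not np.all(np.isfinite(data)):
        raise RecordingError(f"non-finite samples in {data_path}")
    return _slice_epochs(data, fs, state, channels, duration_s)
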