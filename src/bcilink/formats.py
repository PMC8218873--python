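"""Flat binary broadband format and frame-stream serialization.

Broadband file layout (little-endian throughout):

* magic bytes ``BBND``
* uint32: JSON header length in bytes
* JSON header: ``n_channels``, ``n_samples``, ``rate``, ``lsb_uv``,
  ``start_time``, optional ``seed`` / ``provenance``
* payload: int16 samples, interleaved channel-major per frame (sample 0 of
  every channel, then sample 1 of every channel, ...), scaled so that
  ``voltage_uv = value * lsb_uv``.

Frame-stream file layout: magic ``BWDF``, uint32 JSON header length, the
link spec as JSON, then the frame payloads as uint16 codes (frame-major,
``n_frames x n_channels``); 12-bit codes are stored one per 16-bit word.

Ground truth and receiver logs travel as JSON sidecars next to the binary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .link import FrameStream, LinkSpec
from .receiver import ReceiverLog
from .signals import BroadbandRecording, SpikeTruth

__all__ = [
    "BroadbandFormatError",
    "MagicError",
    "TruncatedFileError",
    "HeaderMismatchError",
    "write_broadband",
    "read_broadband",
    "write_frames",
    "read_frames",
    "write_truth",
    "read_truth",
    "write_receiver_log",
    "read_receiver_log",
]

BROADBAND_MAGIC = b"BBND"
FRAMES_MAGIC = b"BWDF"


class BroadbandFormatError(ValueError):
    """Base class for file-format errors."""


class MagicError(BroadbandFormatError):
    """The file does not start with the expected magic bytes."""


class TruncatedFileError(BroadbandFormatError):
    """The payload is shorter than the header declares."""


class HeaderMismatchError(BroadbandFormatError):
    """Header fields are inconsistent with the payload."""


def _write_with_header(path: Path, magic: bytes, header: dict,
                       payload: np.ndarray) -> None:
    blob = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(magic)
        fh.write(np.array(len(blob), dtype="<u4").tobytes())
        fh.write(blob)
        fh.write(np.ascontiguousarray(payload).astype(payload.dtype.newbyteorder("<")).tobytes())


def _read_with_header(path: Path, magic: bytes) -> tuple[dict, bytes]:
    raw = Path(path).read_bytes()
    if raw[:4] != magic:
        raise MagicError(f"{path}: expected magic {magic!r}, found {raw[:4]!r}")
    n = int(np.frombuffer(raw[4:8], dtype="<u4")[0])
    if len(raw) < 8 + n:
        raise TruncatedFileError(f"{path}: header truncated")
    header = json.loads(raw[8:8 + n].decode())
    return header, raw[8 + n:]


def write_broadband(path: str | Path, recording: BroadbandRecording,
                    lsb_uv: float = 0.25, seed: int | None = None,
                    provenance: dict | None = None) -> None:
    """Quantize to the 16-bit grid at ``lsb_uv`` and write the binary file."""
    q = np.clip(np.round(recording.data / lsb_uv), -32768, 32767).astype(np.int16)
    header = {
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "rate": recording.rate,
        "lsb_uv": lsb_uv,
        "start_time": recording.start_time,
        "channel_ids": recording.channel_ids,
    }
    if seed is not None:
        header["seed"] = seed
    if provenance:
        header["provenance"] = provenance
    _write_with_header(Path(path), BROADBAND_MAGIC, header, q.T)  # sample-major


def read_broadband(path: str | Path) -> BroadbandRecording:
    header, payload = _read_with_header(Path(path), BROADBAND_MAGIC)
    n_ch, n_s = header["n_channels"], header["n_samples"]
    expected = n_ch * n_s * 2
    if len(payload) != expected:
        raise TruncatedFileError(
            f"{path}: expected {expected} payload bytes, found {len(payload)}"
        )
    data = np.frombuffer(payload, dtype="<i2").reshape(n_s, n_ch).T
    if data.shape[0] != len(header.get("channel_ids", range(n_ch))):
        raise HeaderMismatchError(f"{path}: channel_ids inconsistent with payload")
    return BroadbandRecording(
        data=data.astype(np.float64) * header["lsb_uv"],
        rate=header["rate"],
        channel_ids=list(header.get("channel_ids", range(n_ch))),
        start_time=header.get("start_time", 0.0),
    )


def write_frames(path: str | Path, frames: FrameStream) -> None:
    header = dataclasses.asdict(frames.spec)
    header["n_frames"] = frames.n_frames
    _write_with_header(Path(path), FRAMES_MAGIC, header,
                       frames.payloads.astype(np.uint16))


def read_frames(path: str | Path) -> FrameStream:
    header, payload = _read_with_header(Path(path), FRAMES_MAGIC)
    n_frames = header.pop("n_frames")
    spec = LinkSpec(**header)
    expected = n_frames * spec.n_channels * 2
    if len(payload) != expected:
        raise TruncatedFileError(
            f"{path}: expected {expected} payload bytes, found {len(payload)}"
        )
    payloads = np.frombuffer(payload, dtype="<u2").reshape(n_frames, spec.n_channels)
    return FrameStream(payloads=payloads.copy(), spec=spec)


def write_truth(path: str | Path, truth: list[SpikeTruth]) -> None:
    doc = [
        {
            "unit_id": t.unit_id,
            "channel": t.channel,
            "spike_times": t.spike_times.tolist(),
            "template": t.template.tolist(),
        }
        for t in truth
    ]
    Path(path).write_text(json.dumps(doc))


def read_truth(path: str | Path) -> list[SpikeTruth]:
    doc = json.loads(Path(path).read_text())
    return [
        SpikeTruth(
            unit_id=d["unit_id"], channel=d["channel"],
            spike_times=np.asarray(d["spike_times"], dtype=float),
            template=np.asarray(d["template"], dtype=float),
        )
        for d in doc
    ]


def write_receiver_log(path: str | Path, log: ReceiverLog) -> None:
    """Compact form: frame count, rate and the concealed-frame indices.

    Per-frame antenna attribution is dropped; every integrity statistic
    consumes only the concealed mask.
    """
    Path(path).write_text(json.dumps(log.to_dict()))


def read_receiver_log(path: str | Path) -> ReceiverLog:
    doc = json.loads(Path(path).read_text())
    status = np.zeros(doc["n_frames"], dtype=np.int8)
    status[np.asarray(doc["concealed_indices"], dtype=int)] = -1
    return ReceiverLog(status=status, frame_rate=doc["frame_rate"])
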