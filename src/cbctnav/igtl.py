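"""Minimal image-guided-therapy message protocol (version-1 subset).

Implements the two message types the workflow needs — TRANSFORM (the
calibration result) and POINT (entry/target transfer) — in the standard
open wire format for image-guided-therapy systems: a 58-byte big-endian
header (version, type name, device name, timestamp, body size, CRC-64)
followed by a typed body.  The CRC is the non-reflected 64-bit ECMA-182
checksum of the body.
"""

from __future__ import annotations

import struct

import numpy as np

from .geometry import RigidTransform

__all__ = [
    "ProtocolError",
    "CrcMismatchError",
    "TruncatedMessageError",
    "UnknownMessageTypeError",
    "crc64",
    "encode_transform_message",
    "decode_transform_message",
    "encode_point_message",
    "decode_point_message",
]


class ProtocolError(Exception):
    """Base class for message encode/decode failures."""


class CrcMismatchError(ProtocolError):
    """Body checksum does not match the header CRC."""


class TruncatedMessageError(ProtocolError):
    """Message shorter than the header's body_size promises."""


class UnknownMessageTypeError(ProtocolError):
    """Header type name is not a supported message type."""


HEADER_STRUCT = struct.Struct(">H12s20sQQQ")  # 58 bytes
HEADER_SIZE = HEADER_STRUCT.size
PROTOCOL_VERSION = 1

_CRC64_POLY = 0x42F0E1EBA9EA3693  # ECMA-182


def _build_crc_table() -> list[int]:
    table = []
    for byte in range(256):
        crc = byte << 56
        for _ in range(8):
            if crc & (1 << 63):
                crc = ((crc << 1) ^ _CRC64_POLY) & 0xFFFFFFFFFFFFFFFF
            else:
                crc = (crc << 1) & 0xFFFFFFFFFFFFFFFF
        table.append(crc)
    return table


_CRC_TABLE = _build_crc_table()


def crc64(data: bytes) -> int:
    """Non-reflected CRC-64/ECMA-182, init 0, no final xor."""
    crc = 0
    for b in data:
        crc = (_CRC_TABLE[((crc >> 56) ^ b) & 0xFF] ^ (crc << 8)) & 0xFFFFFFFFFFFFFFFF
    return crc


def _pack_name(name: str, width: int) -> bytes:
    raw = name.encode("ascii")
    if len(raw) > width:
        raise ValueError(f"name {name!r} exceeds {width} bytes")
    return raw.ljust(width, b"\x00")


def _encode(type_name: str, device_name: str, timestamp: int, body: bytes) -> bytes:
    header = HEADER_STRUCT.pack(
        PROTOCOL_VERSION,
        _pack_name(type_name, 12),
        _pack_name(device_name, 20),
        timestamp,
        len(body),
        crc64(body),
    )
    return header + body


def _decode_header(message: bytes) -> tuple[str, str, int, bytes]:
    if len(message) < HEADER_SIZE:
        raise TruncatedMessageError(
            f"message of {len(message)} bytes is shorter than the {HEADER_SIZE}-byte header"
        )
    version, type_raw, device_raw, timestamp, body_size, crc = HEADER_STRUCT.unpack(
        message[:HEADER_SIZE]
    )
    if version != PROTOCOL_VERSION:
        raise UnknownMessageTypeError(f"unsupported protocol version {version}")
    body = message[HEADER_SIZE:]
    if len(body) < body_size:
        raise TruncatedMessageError(
            f"header promises {body_size} body bytes, got {len(body)}"
        )
    body = body[:body_size]
    if crc64(body) != crc:
        raise CrcMismatchError("body CRC-64 does not match the header checksum")
    type_name = type_raw.rstrip(b"\x00").decode("ascii")
    device_name = device_raw.rstrip(b"\x00").decode("ascii")
    return type_name, device_name, timestamp, body


def encode_transform_message(
    transform: RigidTransform,
    device_name: str = "calibration",
    timestamp: int = 0,
) -> bytes:
    """Serialise a rigid transform as a TRANSFORM message.

    Body: 12 big-endian float32 — the three rotation columns, then the
    translation (mm).  Raises on non-rigid input (RigidTransform itself
    enforces orthonormality and det +1).
    """
    R, t = transform.rotation, transform.translation
    values = [*R[:, 0], *R[:, 1], *R[:, 2], *t]
    body = struct.pack(">12f", *values)
    return _encode("TRANSFORM", device_name, timestamp, body)


def decode_transform_message(message: bytes) -> tuple[RigidTransform, dict]:
    """Validate and parse a TRANSFORM message.

    Returns the transform and a metadata dict (device name, timestamp).
    The rotation is re-orthonormalised against float32 rounding before
    the rigidity check.
    """
    type_name, device_name, timestamp, body = _decode_header(message)
    if type_name != "TRANSFORM":
        raise UnknownMessageTypeError(f"expected TRANSFORM, got {type_name!r}")
    if len(body) != 48:
        raise TruncatedMessageError(f"TRANSFORM body must be 48 bytes, got {len(body)}")
    vals = struct.unpack(">12f", body)
    R = np.array(vals[:9], float).reshape(3, 3, order="F")  # columns were sent
    t = np.array(vals[9:], float)
    U, _, Vt = np.linalg.svd(R)
    R_ortho = U @ Vt
    if np.linalg.det(R_ortho) < 0 or np.max(np.abs(R_ortho - R)) > 1e-5:
        raise ProtocolError("TRANSFORM body does not hold a proper rotation")
    return RigidTransform(R_ortho, t), {"device_name": device_name, "timestamp": timestamp}


# POINT element: name[64] group[32] rgba[4] xyz[3*f32] diameter[f32] owner[20]
_POINT_ELEMENT = struct.Struct(">64s32s4B3ff20s")


def encode_point_message(
    points: np.ndarray,
    device_name: str = "targets",
    names: list[str] | None = None,
    timestamp: int = 0,
) -> bytes:
    """Serialise points (n, 3) mm as a POINT message."""
    pts = np.asarray(points, float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    names = names if names is not None else [f"PT_{i}" for i in range(pts.shape[0])]
    if len(names) != pts.shape[0]:
        raise ValueError("one name per point required")
    body = b"".join(
        _POINT_ELEMENT.pack(
            _pack_name(name, 64), _pack_name("", 32),
            255, 0, 0, 255,
            float(p[0]), float(p[1]), float(p[2]),
            0.0, _pack_name("", 20),
        )
        for name, p in zip(names, pts)
    )
    return _encode("POINT", device_name, timestamp, body)


def decode_point_message(message: bytes) -> tuple[np.ndarray, dict]:
    """Validate and parse a POINT message; returns (n, 3) points + metadata."""
    type_name, device_name, timestamp, body = _decode_header(message)
    if type_name != "POINT":
        raise UnknownMessageTypeError(f"expected POINT, got {type_name!r}")
    if len(body) % _POINT_ELEMENT.size != 0:
        raise TruncatedMessageError(
            f"POINT body of {len(body)} bytes is not a multiple of "
            f"{_POINT_ELEMENT.size}"
        )
    pts, names = [], []
    for off in range(0, len(body), _POINT_ELEMENT.size):
        fields = _POINT_ELEMENT.unpack(body[off:off + _POINT_ELEMENT.size])
        names.append(fields[0].rstrip(b"\x00").decode("ascii"))
        pts.append(fields[6:9])
    return (np.array(pts, float),
            {"device_name": device_name, "timestamp": timestamp, "names": names})
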