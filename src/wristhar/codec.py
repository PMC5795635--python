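"""Bit-exact quantization and packing of 9-axis IMU samples.

The wearable streams inertial data over a single BLE characteristic, whose
notifiable payload is capped at 20 bytes, while an uncompressed 9-axis
sample is nine 4-byte floats (36 bytes).  The codec therefore converts each
physical value to a fixed-point integer by decimal shifting (multiply by
10^digits, truncate the remaining fraction) and packs it in sign-magnitude
form:

* accelerometer and magnetometer axes: 3 retained decimals, open interval
  (-4, 4) physical -> integers in (-4000, 4000), 1 sign bit + 12 magnitude
  bits = 13 bits per axis;
* gyroscope axes: 1 retained decimal, (-2000, 2000) deg/s -> integers in
  (-20000, 20000), 1 sign bit + 15 magnitude bits = 16 bits per axis.

Two layouts exist.  ``COMPACT`` carries accelerometer + gyroscope only
(3*13 + 3*16 = 87 payload bits, 11 serialized bytes) and is the canonical
wire format; ``FULL`` appends the magnetometer (126 bits, 16 bytes), still
within one characteristic.  Field order is ax, ay, az, gx, gy, gz
(, mx, my, mz), packed MSB-first, sign bit (1 = negative) before the
magnitude, with trailing zero bits padding to a whole byte.  The byte-exact
layout is documented in FORMAT.md.
"""

from __future__ import annotations

import enum
import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACCEL_FULL_SCALE = 4.0     # g
GYRO_FULL_SCALE = 2000.0   # deg/s
MAG_FULL_SCALE = 4.0       # gauss
ACCEL_DIGITS = 3
GYRO_DIGITS = 1
MAG_DIGITS = 3
NOMINAL_RATE_HZ = 60.0
UNCOMPRESSED_SAMPLE_BYTES = 9 * 4  # nine float32 values

AXIS_NAMES = ("ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz")
CSV_COLUMNS = ("t",) + AXIS_NAMES

STREAM_MAGIC = b"WIMU"


class CodecError(ValueError):
    """Base class for codec failures."""


class MalformedPacketError(CodecError):
    """Packet bytes do not match the declared layout."""


class DecodeError(CodecError):
    """A decoded field is outside its legal range."""


@dataclass(frozen=True)
class ImuSample:
    """One timestamped 9-axis reading in physical units.

    ``t`` is seconds since stream start; accelerations in g, angular rates
    in deg/s, magnetic field in gauss.
    """

    t: float
    ax: float
    ay: float
    az: float
    gx: float
    gy: float
    gz: float
    mx: float = 0.0
    my: float = 0.0
    mz: float = 0.0

    def axes(self) -> tuple[float, ...]:
        return (self.ax, self.ay, self.az, self.gx, self.gy, self.gz,
                self.mx, self.my, self.mz)


@dataclass(frozen=True)
class QuantizedSample:
    """Nine signed fixed-point integers (decimal-shifted sample)."""

    ax: int
    ay: int
    az: int
    gx: int
    gy: int
    gz: int
    mx: int = 0
    my: int = 0
    mz: int = 0

    def axes(self) -> tuple[int, ...]:
        return (self.ax, self.ay, self.az, self.gx, self.gy, self.gz,
                self.mx, self.my, self.mz)


@dataclass(frozen=True)
class FieldSpec:
    name: str
    bits: int        # total, including the sign bit
    digits: int      # retained decimals
    full_scale: float

    @property
    def magnitude_bits(self) -> int:
        return self.bits - 1

    @property
    def bound(self) -> int:
        """Exclusive integer bound: |q| < bound for in-range samples."""
        return int(round(self.full_scale * 10 ** self.digits))


_ACCEL_FIELDS = tuple(
    FieldSpec(n, 13, ACCEL_DIGITS, ACCEL_FULL_SCALE) for n in ("ax", "ay", "az")
)
_GYRO_FIELDS = tuple(
    FieldSpec(n, 16, GYRO_DIGITS, GYRO_FULL_SCALE) for n in ("gx", "gy", "gz")
)
_MAG_FIELDS = tuple(
    FieldSpec(n, 13, MAG_DIGITS, MAG_FULL_SCALE) for n in ("mx", "my", "mz")
)


class PacketLayout(enum.Enum):
    """Wire layout variants; value doubles as the stream-file layout tag."""

    COMPACT = 0
    FULL = 1

    @property
    def fields(self) -> tuple[FieldSpec, ...]:
        if self is PacketLayout.COMPACT:
            return _ACCEL_FIELDS + _GYRO_FIELDS
        return _ACCEL_FIELDS + _GYRO_FIELDS + _MAG_FIELDS

    @property
    def payload_bits(self) -> int:
        return sum(f.bits for f in self.fields)

    @property
    def num_bytes(self) -> int:
        return (self.payload_bits + 7) // 8


@dataclass(frozen=True)
class Packet:
    """Raw serialized bytes plus the layout they were packed with."""

    raw: bytes
    layout: PacketLayout

    def __post_init__(self) -> None:
        if len(self.raw) != self.layout.num_bytes:
            raise MalformedPacketError(
                f"{self.layout.name} packet must be {self.layout.num_bytes} "
                f"bytes, got {len(self.raw)}"
            )


def quantize(value: float, digits: int, full_scale: float | None = None) -> int:
    """Decimal-shift ``value`` and truncate (never round) the fraction.

    Returns ``sign(value) * floor(|value| * 10**digits)``.  Zero is always
    non-negative (canonical encoding).  If ``full_scale`` is given, values
    at or beyond it are clamped to the largest in-range integer with a
    logged warning: the sensors are configured with open full-scale
    intervals, and a live stream must survive a transient spike.
    """
    scaled = abs(value) * 10 ** digits
    # Snap values a few ulp below an integer so that quantizing a previously
    # dequantized value reproduces the same integer (decode/encode stability).
    nearest = round(scaled)
    magnitude = int(nearest) if abs(scaled - nearest) < 1e-9 else int(scaled)
    if full_scale is not None:
        bound = int(round(full_scale * 10 ** digits))
        if magnitude >= bound:
            logger.warning(
                "value %g at or beyond full scale %g; clamped", value, full_scale
            )
            magnitude = bound - 1
    return -magnitude if value < 0 and magnitude != 0 else magnitude


def dequantize(q: int, digits: int) -> float:
    """Inverse decimal shift: ``q / 10**digits``."""
    return q / 10 ** digits


def quantize_sample(s: ImuSample, layout: PacketLayout = PacketLayout.FULL) -> QuantizedSample:
    values = {}
    lookup = dict(zip(AXIS_NAMES, s.axes()))
    for f in PacketLayout.FULL.fields:
        if f in layout.fields or layout is PacketLayout.FULL:
            values[f.name] = quantize(lookup[f.name], f.digits, f.full_scale)
    if layout is PacketLayout.COMPACT:
        for f in _MAG_FIELDS:
            values[f.name] = 0
    return QuantizedSample(**values)


def encode_sample(s: ImuSample, layout: PacketLayout = PacketLayout.COMPACT) -> Packet:
    """Quantize and pack one sample into its wire representation."""
    q = quantize_sample(s)
    return encode_quantized(q, layout)


def encode_quantized(q: QuantizedSample, layout: PacketLayout = PacketLayout.COMPACT) -> Packet:
    lookup = dict(zip(AXIS_NAMES, q.axes()))
    acc = 0
    for f in layout.fields:
        v = lookup[f.name]
        if abs(v) >= 1 << f.magnitude_bits:
            raise CodecError(
                f"field {f.name}: integer {v} does not fit {f.magnitude_bits} magnitude bits"
            )
        sign = 1 if v < 0 else 0  # canonical zero: positive sign bit
        acc = (acc << f.bits) | (sign << f.magnitude_bits) | abs(v)
    pad = layout.num_bytes * 8 - layout.payload_bits
    acc <<= pad  # trailing zero padding
    return Packet(acc.to_bytes(layout.num_bytes, "big"), layout)


def decode_quantized(p: Packet) -> QuantizedSample:
    layout = p.layout
    acc = int.from_bytes(p.raw, "big")
    pad = layout.num_bytes * 8 - layout.payload_bits
    if acc & ((1 << pad) - 1):
        logger.warning("nonzero padding bits in %s packet", layout.name)
    acc >>= pad
    values = {}
    shift = layout.payload_bits
    for f in layout.fields:
        shift -= f.bits
        word = (acc >> shift) & ((1 << f.bits) - 1)
        sign = word >> f.magnitude_bits
        magnitude = word & ((1 << f.magnitude_bits) - 1)
        if magnitude >= f.bound:
            raise DecodeError(
                f"field {f.name}: magnitude {magnitude} outside bound {f.bound}"
            )
        if sign and magnitude == 0:
            logger.warning("negative zero in field %s; canonicalized", f.name)
        values[f.name] = -magnitude if sign else magnitude
    return QuantizedSample(**values)


def decode_packet(p: Packet, t: float = 0.0) -> ImuSample:
    """Decode a packet to physical units at quantized precision.

    ``t`` is supplied by the stream reassembler; packets themselves carry
    no timestamp.
    """
    q = decode_quantized(p)
    lookup = dict(zip(AXIS_NAMES, q.axes()))
    values = {}
    for f in PacketLayout.FULL.fields:
        values[f.name] = dequantize(lookup[f.name], f.digits)
    return ImuSample(t=t, **values)


# ---------------------------------------------------------------------------
# Stream files

def write_packet_stream(samples: Iterable[ImuSample], path: str | Path,
                        layout: PacketLayout = PacketLayout.COMPACT) -> int:
    """Write a binary packet stream: 4-byte magic, 1-byte layout tag, packets."""
    n = 0
    with open(path, "wb") as fh:
        fh.write(STREAM_MAGIC)
        fh.write(struct.pack("B", layout.value))
        for s in samples:
            fh.write(encode_sample(s, layout).raw)
            n += 1
    return n


def read_packet_stream(path: str | Path, rate: float = NOMINAL_RATE_HZ) -> list[ImuSample]:
    """Read a binary packet stream; timestamps are reassembled at ``rate``."""
    data = Path(path).read_bytes()
    if len(data) < 5 or data[:4] != STREAM_MAGIC:
        raise MalformedPacketError("bad stream header")
    try:
        layout = PacketLayout(data[4])
    except ValueError as exc:
        raise MalformedPacketError(f"unknown layout tag {data[4]}") from exc
    body = data[5:]
    size = layout.num_bytes
    if len(body) % size:
        raise MalformedPacketError(
            f"stream body length {len(body)} is not a multiple of packet size {size}"
        )
    return [
        decode_packet(Packet(body[i * size:(i + 1) * size], layout), t=i / rate)
        for i in range(len(body) // size)
    ]


def read_csv_stream(path: str | Path) -> pd.DataFrame:
    """Read a raw CSV stream with mandatory header t,ax,...,mz."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CodecError(f"CSV stream missing columns: {missing}")
    return df[list(CSV_COLUMNS)]


def write_csv_stream(df: pd.DataFrame, path: str | Path) -> None:
    df = df[list(CSV_COLUMNS)]
    df.to_csv(path, index=False)


def samples_from_frame(df: pd.DataFrame) -> list[ImuSample]:
    return [ImuSample(*row) for row in df[list(CSV_COLUMNS)].itertuples(index=False)]


def frame_from_samples(samples: Sequence[ImuSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.t,) + s.axes() for s in samples], columns=list(CSV_COLUMNS)
    )


def quantize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized quantize+dequantize of a whole stream (codec fidelity check)."""
    out = df.copy()
    for f in PacketLayout.FULL.fields:
        v = df[f.name].to_numpy()
        scaled = np.abs(v) * 10 ** f.digits
        nearest = np.round(scaled)
        mag = np.where(np.abs(scaled - nearest) < 1e-9, nearest, np.floor(scaled))
        mag = np.minimum(mag, f.bound - 1)
        out[f.name] = np.sign(v) * mag / 10 ** f.digits
    return out
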