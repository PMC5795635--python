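# Wire and stream formats

## Packet payload

Each packet encodes one 9-axis IMU sample. Every field is sign-magnitude:
1 sign bit (1 = negative) followed by the unsigned magnitude, packed
MSB-first with no gaps. Zero always carries a positive sign bit (negative
zero is forbidden). Trailing bits of the last byte are zero padding.

Physical values are decimal-shifted fixed point: the stored integer is
`sign(v) * floor(|v| * 10^digits)` (truncation, never rounding).

| Field order | Bits | Sign + magnitude | Digits | Integer range (open) | Physical range (open) |
|-------------|------|------------------|--------|----------------------|-----------------------|
| ax, ay, az  | 13   | 1 + 12           | 3      | (−4000, 4000)        | (−4, 4) g             |
| gx, gy, gz  | 16   | 1 + 15           | 1      | (−20000, 20000)      | (−2000, 2000) °/s     |
| mx, my, mz (FULL only) | 13 | 1 + 12    | 3      | (−4000, 4000)        | (−4, 4) gauss         |

Layouts:

* `COMPACT` (tag 0): ax ay az gx gy gz → 3·13 + 3·16 = **87 payload bits**,
  serialized in **11 bytes** (1 padding bit).
* `FULL` (tag 1): adds mx my mz → **126 payload bits**, **16 bytes**
  (2 padding bits).

Both fit a single 20-byte BLE characteristic value. An uncompressed sample
(nine 4-byte floats) would be 36 bytes.

Decoders must reject packets of the wrong byte length, reject magnitudes at
or beyond the integer bound, and warn on nonzero padding or negative zero.

## Binary packet stream file

```
offset 0: 4-byte magic "WIMU"
offset 4: 1-byte layout tag (0 = COMPACT, 1 = FULL)
offset 5: packets back to back, fixed length per the layout
```

Timestamps are not stored; readers reassemble `t = i / rate` at the nominal
60 Hz rate.

## CSV raw stream

Header row is mandatory, columns exactly:

```
t,ax,ay,az,gx,gy,gz,mx,my,mz
```

`t` in seconds since stream start, strictly increasing; accelerations in g,
angular rates in °/s, magnetic field in gauss.

## Ground-truth intervals (simulator output)

Tab-separated, one labelled segment per line, end-exclusive sample indices:

```
start_sample	end_sample	label
```
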