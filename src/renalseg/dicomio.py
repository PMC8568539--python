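"""Minimal single-frame CT DICOM reader/writer.

Supports exactly the subset needed for plain axial CT series: Part-10 files
with the Explicit VR Little Endian transfer syntax, uncompressed 16-bit
monochrome pixel data, and the handful of geometry/rescale tags the
pipeline consumes. This is deliberately not a general DICOM implementation;
anything outside that subset raises a clear error.
"""

from __future__ import annotations

import os
import struct

import numpy as np

__all__ = ["read_dicom_file", "write_dicom_file", "DicomError"]

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
_MAGIC = b"DICM"

# tag -> (VR, attribute name)
TAGS = {
    (0x0008, 0x0060): ("CS", "Modality"),
    (0x0020, 0x000E): ("UI", "SeriesInstanceUID"),
    (0x0020, 0x0013): ("IS", "InstanceNumber"),
    (0x0020, 0x1041): ("DS", "SliceLocation"),
    (0x0028, 0x0002): ("US", "SamplesPerPixel"),
    (0x0028, 0x0010): ("US", "Rows"),
    (0x0028, 0x0011): ("US", "Columns"),
    (0x0028, 0x0030): ("DS", "PixelSpacing"),
    (0x0018, 0x0050): ("DS", "SliceThickness"),
    (0x0028, 0x0100): ("US", "BitsAllocated"),
    (0x0028, 0x0101): ("US", "BitsStored"),
    (0x0028, 0x0102): ("US", "HighBit"),
    (0x0028, 0x0103): ("US", "PixelRepresentation"),
    (0x0028, 0x1052): ("DS", "RescaleIntercept"),
    (0x0028, 0x1053): ("DS", "RescaleSlope"),
    (0x7FE0, 0x0010): ("OW", "PixelData"),
}
_NAME_TO_TAG = {name: tag for tag, (_, name) in TAGS.items()}

# VRs whose explicit encoding uses a 2-byte reserved field + 4-byte length
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}


class DicomError(ValueError):
    pass


def _encode_element(tag, vr: str, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in ("OB", "UN") else b" "
    group, elem = tag
    head = struct.pack("<HH", group, elem) + vr.encode()
    if vr.encode() in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def write_dicom_file(path, pixels_hu: np.ndarray, *,
                     pixel_spacing_mm=(0.625, 0.625),
                     slice_thickness_mm: float = 1.0,
                     slice_location_mm: float = 0.0,
                     instance_number: int = 1,
                     series_uid: str = "1.2.826.0.1.3680043.9999.1",
                     rescale_slope: float = 1.0,
                     rescale_intercept: float = -1024.0) -> None:
    """Write one CT slice; HU are stored via the inverse rescale mapping."""
    pixels_hu = np.asarray(pixels_hu, dtype=np.float64)
    stored = np.round((pixels_hu - rescale_intercept) / rescale_slope)
    if stored.min() < -32768 or stored.max() > 32767:
        raise DicomError("stored pixel values exceed int16 range")
    stored = stored.astype("<i2")

    def ds(*vals):
        return "\\".join(f"{v:g}" for v in vals).encode()

    body = b"".join([
        _encode_element((0x0008, 0x0060), "CS", b"CT"),
        _encode_element((0x0020, 0x000E), "UI", series_uid.encode()),
        _encode_element((0x0020, 0x0013), "IS", str(instance_number).encode()),
        _encode_element((0x0020, 0x1041), "DS", ds(slice_location_mm)),
        _encode_element((0x0028, 0x0002), "US", struct.pack("<H", 1)),
        _encode_element((0x0028, 0x0010), "US", struct.pack("<H", stored.shape[0])),
        _encode_element((0x0028, 0x0011), "US", struct.pack("<H", stored.shape[1])),
        _encode_element((0x0028, 0x0030), "DS", ds(*pixel_spacing_mm)),
        _encode_element((0x0018, 0x0050), "DS", ds(slice_thickness_mm)),
        _encode_element((0x0028, 0x0100), "US", struct.pack("<H", 16)),
        _encode_element((0x0028, 0x0101), "US", struct.pack("<H", 16)),
        _encode_element((0x0028, 0x0102), "US", struct.pack("<H", 15)),
        _encode_element((0x0028, 0x0103), "US", struct.pack("<H", 1)),
        _encode_element((0x0028, 0x1052), "DS", ds(rescale_intercept)),
        _encode_element((0x0028, 0x1053), "DS", ds(rescale_slope)),
        _encode_element((0x7FE0, 0x0010), "OW", stored.tobytes()),
    ])

    meta = b"".join([
        _encode_element((0x0002, 0x0010), "UI", EXPLICIT_VR_LE.encode()),
    ])
    meta = _encode_element((0x0002, 0x0000), "UL", struct.pack("<I", len(meta))) + meta

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + _MAGIC + meta + body)


def _parse_elements(buf: bytes, offset: int):
    n = len(buf)
    while offset < n:
        group, elem = struct.unpack_from("<HH", buf, offset)
        vr = buf[offset + 4:offset + 6]
        if not vr.isalpha() or not vr.isupper():
            raise DicomError(
                f"implicit-VR or malformed element at offset {offset}; only "
                "Explicit VR Little Endian is supported")
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, offset + 8)
            start = offset + 12
        else:
            (length,) = struct.unpack_from("<H", buf, offset + 6)
            start = offset + 8
        if length == 0xFFFFFFFF:
            raise DicomError("undefined-length elements are not supported")
        yield (group, elem), vr.decode(), buf[start:start + length]
        offset = start + length


def _decode(vr: str, raw: bytes):
    if vr in ("CS", "UI", "IS", "DS"):
        text = raw.decode("ascii").strip("\x00 ")
        if vr == "IS":
            return int(text)
        if vr == "DS":
            vals = [float(v) for v in text.split("\\")]
            return vals[0] if len(vals) == 1 else vals
        return text
    if vr == "US":
        vals = struct.unpack(f"<{len(raw) // 2}H", raw)
        return vals[0] if len(vals) == 1 else list(vals)
    if vr in ("OW", "OB"):
        return raw
    return raw


def read_dicom_file(path) -> dict:
    """Parse one file into a dict of attribute name -> value, plus ``pixels``
    (the raw stored values as a signed/unsigned int16 array, NOT yet in HU)."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != _MAGIC:
        raise DicomError(f"{path}: not a Part-10 DICOM file (missing DICM magic)")
    # file meta group (always explicit LE)
    attrs = {}
    transfer_syntax = None
    offset = 132
    for tag, vr, raw in _parse_elements(buf, 132):
        if tag[0] != 0x0002:
            break
        if tag == (0x0002, 0x0010):
            transfer_syntax = raw.decode("ascii").strip("\x00 ")
        if tag == (0x0002, 0x0000):
            (meta_len,) = struct.unpack("<I", raw)
            offset = 132 + 12 + meta_len
    if transfer_syntax != EXPLICIT_VR_LE:
        raise DicomError(
            f"{path}: unsupported transfer syntax {transfer_syntax!r}; only "
            f"{EXPLICIT_VR_LE} (Explicit VR Little Endian) is supported")

    for tag, vr, raw in _parse_elements(buf, offset):
        if tag in TAGS:
            attrs[TAGS[tag][1]] = _decode(vr, raw)

    for required in ("RescaleSlope", "RescaleIntercept"):
        if required not in attrs:
            tag = _NAME_TO_TAG[required]
            raise DicomError(
                f"{path}: missing tag ({tag[0]:04X},{tag[1]:04X}) {required}")
    for required in ("Rows", "Columns", "PixelData"):
        if required not in attrs:
            raise DicomError(f"{path}: missing {required}")
    if attrs.get("BitsAllocated", 16) != 16:
        raise DicomError(f"{path}: only 16-bit pixel data is supported")

    dtype = "<i2" if attrs.get("PixelRepresentation", 0) == 1 else "<u2"
    pixels = np.frombuffer(attrs.pop("PixelData"), dtype=dtype)
    rows, cols = attrs["Rows"], attrs["Columns"]
    if pixels.size != rows * cols:
        raise DicomError(f"{path}: pixel data size does not match Rows x Columns")
    attrs["pixels"] = pixels.reshape(rows, cols)
    return attrs


def list_series_files(directory) -> list[str]:
    files = sorted(
        os.path.join(directory, f) for f in os.listdir(directory)
        if f.lower().endswith((".dcm", ".dicom")))
    if not files:
        raise DicomError(f"no DICOM files (*.dcm) found in {directory}")
    return files
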