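"""Minimal EDF byte-writer for synthetic test fixtures.

Only used to generate tiny synthetic EDF files at test time so the mne-based
reader can be exercised without clinical data or a third-party EDF export
dependency. Writes the plain 16-bit EDF layout: a 256-byte global header,
256 bytes of per-signal header fields, then little-endian int16 data records.
Not a general-purpose exporter.
"""

from pathlib import Path

import numpy as np

PHYS_MIN, PHYS_MAX = -2000.0, 2000.0
DIG_MIN, DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {value!r} wider than {width}")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, data: np.ndarray, fs: float, channel_ids) -> None:
    """Write a channels-by-samples microvolt matrix as a synthetic EDF file."""
    data = np.asarray(data, dtype=float)
    n_sig, n_samp = data.shape
    spr = int(round(fs))  # 1-s data records
    n_rec = n_samp // spr
    if n_rec < 1:
        raise ValueError("need at least one full 1-s data record")
    data = data[:, : n_rec * spr]
    header_bytes = 256 * (1 + n_sig)

    hdr = b"".join(
        [
            _field("0", 8),
            _field("synthetic test subject", 80),
            _field("synthetic test recording", 80),
            _field("01.01.20", 8),
            _field("00.00.00", 8),
            _field(header_bytes, 8),
            _field("", 44),
            _field(n_rec, 8),
            _field(1, 8),
            _field(n_sig, 4),
        ]
    )

    def sig_fields(values, width):
        return b"".join(_field(v, width) for v in values)

    hdr += sig_fields(channel_ids, 16)
    hdr += sig_fields([""] * n_sig, 80)
    hdr += sig_fields(["uV"] * n_sig, 8)
    hdr += sig_fields([PHYS_MIN] * n_sig, 8)
    hdr += sig_fields([PHYS_MAX] * n_sig, 8)
    hdr += sig_fields([DIG_MIN] * n_sig, 8)
    hdr += sig_fields([DIG_MAX] * n_sig, 8)
    hdr += sig_fields([""] * n_sig, 80)
    hdr += sig_fields([spr] * n_sig, 8)
    hdr += sig_fields([""] * n_sig, 32)
    assert len(hdr) == header_bytes

    scale = (DIG_MAX - DIG_MIN) / (PHYS_MAX - PHYS_MIN)
    digital = np.clip(
        np.round((data - PHYS_MIN) * scale + DIG_MIN), DIG_MIN, DIG_MAX
    ).astype("<i2")
    with Path(path).open("wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
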