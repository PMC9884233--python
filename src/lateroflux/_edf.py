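"""Minimal EDF (European Data Format) writer.

Writes continuous multichannel signals as standard 16-bit EDF so that the
recordings round-trip through any EDF reader (mne is used for reading).
Only what the EGG path needs: equal-rate channels, one physical unit,
amplitude quantized to the 16-bit digital range.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, channels: np.ndarray, fs: float,
              labels: Sequence[str] | None = None, unit: str = "uV") -> None:
    """Write ``channels`` (n_channels x n_samples) at rate ``fs`` to EDF.

    The record duration is chosen so samples-per-record is integral; trailing
    samples that do not fill a whole record are dropped (EDF is record-based).
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    n_ch, n_samp = channels.shape
    if labels is None:
        labels = [f"CH{i + 1}" for i in range(n_ch)]

    # pick a record duration giving an integral number of samples per record
    record_dur = 1.0
    spr = fs * record_dur
    while abs(spr - round(spr)) > 1e-9:
        record_dur *= 2.0
        spr = fs * record_dur
        if record_dur > 64:
            raise ValueError(f"cannot express fs={fs} as samples per EDF record")
    spr = int(round(spr))
    n_rec = n_samp // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record")

    phys_min = np.floor(channels.min(axis=1))
    phys_max = np.ceil(channels.max(axis=1))
    flat = phys_max <= phys_min
    phys_max[flat] = phys_min[flat] + 1.0

    header_bytes = 256 + 256 * n_ch
    now = datetime(2000, 1, 1)
    head = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(header_bytes), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad(f"{record_dur:g}", 8),
        _pad(str(n_ch), 4),
    ])

    sig = b"".join([
        b"".join(_pad(str(lb), 16) for lb in labels),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(unit, 8) for _ in range(n_ch)),
        b"".join(_pad(f"{v:g}", 8) for v in phys_min),
        b"".join(_pad(f"{v:g}", 8) for v in phys_max),
        b"".join(_pad(str(_DIG_MIN), 8) for _ in range(n_ch)),
        b"".join(_pad(str(_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(str(spr), 8) for _ in range(n_ch)),
        b"".join(_pad("", 32) for _ in range(n_ch)),
    ])

    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    dig = np.round((channels - phys_min[:, None]) / gain[:, None] + _DIG_MIN)
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(head + sig)
        for r in range(n_rec):
            fh.write(dig[:, r * spr:(r + 1) * spr].tobytes())
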