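"""Minimal EDF writer for synthetic test fixtures.

Writes a valid EDF (European Data Format) file — 256-byte ASCII header plus
per-signal header arrays and int16 little-endian data records — purely so the
package's EDF *reader* can be exercised without shipping binary files. All
files produced here are synthetic test data, created at test time in
temporary directories.
"""

from __future__ import annotations

import numpy as np

PHYS_MIN, PHYS_MAX = -1000.0, 1000.0
DIG_MIN, DIG_MAX = -32768, 32767


def write_edf(path, signals, fs_list, record_dur: float = 1.0,
              labels=None) -> None:
    """Write channel signals (physical units, |x| < 1000) to an EDF file.

    ``fs_list`` gives the per-signal sampling rate; unequal rates produce a
    (valid) EDF with heterogeneous samples-per-record.
    """
    ns = len(signals)
    labels = labels or [f"ch{i}" for i in range(ns)]
    n_records = int(len(signals[0]) / (fs_list[0] * record_dur))

    h = b"0".ljust(8)
    h += b"synthetic test subject".ljust(80)
    h += b"synthetic test recording".ljust(80)
    h += b"01.01.20" + b"00.00.00"
    h += str(256 * (ns + 1)).encode().ljust(8)
    h += b"".ljust(44)
    h += str(n_records).encode().ljust(8)
    h += str(record_dur).encode().ljust(8)
    h += str(ns).encode().ljust(4)
    h += b"".join(lab.encode().ljust(16) for lab in labels)
    h += b"".ljust(80) * ns
    h += b"uV".ljust(8) * ns
    h += str(int(PHYS_MIN)).encode().ljust(8) * ns
    h += str(int(PHYS_MAX)).encode().ljust(8) * ns
    h += str(DIG_MIN).encode().ljust(8) * ns
    h += str(DIG_MAX).encode().ljust(8) * ns
    h += b"".ljust(80) * ns
    h += b"".join(str(int(fs * record_dur)).encode().ljust(8)
                  for fs in fs_list)
    h += b"".ljust(32) * ns

    with open(path, "wb") as f:
        f.write(h)
        scale = DIG_MAX / PHYS_MAX
        for r in range(n_records):
            for sig, fs in zip(signals, fs_list):
                spr = int(fs * record_dur)
                chunk = np.asarray(sig[r * spr:(r + 1) * spr], float)
                dig = np.clip(np.round(chunk * scale), DIG_MIN,
                              DIG_MAX).astype("<i2")
                f.write(dig.tobytes())
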