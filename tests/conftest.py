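import struct

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_minimal_edf(path, signals, fs, record_dur=1.0):
    """Write a minimal valid EDF file (int16 data records).

    ``signals`` is a dict label -> 1-d float array; all must share ``fs``
    and a whole number of data records of ``record_dur`` seconds.
    """
    labels = list(signals)
    ns = len(labels)
    spr = int(round(fs * record_dur))
    n_samples = {len(v) for v in signals.values()}
    assert len(n_samples) == 1
    n_records = n_samples.pop() // spr

    def pad(s, n):
        return s.encode("ascii")[:n].ljust(n)

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate 01-JAN-2000", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8), pad("", 44),
        pad(str(n_records), 8), pad(f"{record_dur:g}", 8), pad(str(ns), 4),
    ])
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767
    fields = [
        b"".join(pad(lbl, 16) for lbl in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad("uV", 8) for _ in labels),
        b"".join(pad(f"{phys_min:g}", 8) for _ in labels),
        b"".join(pad(f"{phys_max:g}", 8) for _ in labels),
        b"".join(pad(str(dig_min), 8) for _ in labels),
        b"".join(pad(str(dig_max), 8) for _ in labels),
        b"".join(pad("", 80) for _ in labels),
        b"".join(pad(str(spr), 8) for _ in labels),
        b"".join(pad("", 32) for _ in labels),
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for rec in range(n_records):
            for lbl in labels:
                chunk = signals[lbl][rec * spr:(rec + 1) * spr]
                dig = np.clip(np.round((chunk - phys_min) * scale + dig_min),
                              dig_min, dig_max).astype("<i2")
                fh.write(struct.pack(f"<{spr}h", *dig))
    return path
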