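"""Minimal EDF writer for test fixtures (ingest is read-only in the package).

Writes a plain EDF: fixed 256-byte header, 256 bytes per signal, then
little-endian int16 data records. Only what the reader tests need.
"""

import numpy as np


def write_edf(path, signals, labels, fs, phys_range=1000.0):
    """Write equal-length signals (uV) sampled at ``fs`` to ``path``."""
    n_sig = len(signals)
    n_samp = len(signals[0])
    record_dur = 1.0
    spr = int(fs * record_dur)  # samples per record per signal
    n_rec = n_samp // spr
    assert n_rec * spr == n_samp, "test signals must fill whole records"

    def pad(s, n):
        s = str(s)[:n]
        return s + " " * (n - len(s))

    header = (
        pad("0", 8) + pad("test subject", 80) + pad("test recording", 80)
        + pad("01.01.20", 8) + pad("00.00.00", 8)
        + pad(256 * (1 + n_sig), 8) + pad("", 44)
        + pad(n_rec, 8) + pad(int(record_dur), 8) + pad(n_sig, 4)
    )
    fields = [
        [pad(lab, 16) for lab in labels],
        [pad("", 80)] * n_sig,
        [pad("uV", 8)] * n_sig,
        [pad(-phys_range, 8)] * n_sig,
        [pad(phys_range, 8)] * n_sig,
        [pad(-32767, 8)] * n_sig,
        [pad(32767, 8)] * n_sig,
        [pad("", 80)] * n_sig,
        [pad(spr, 8)] * n_sig,
        [pad("", 32)] * n_sig,
    ]
    for block in fields:
        header += "".join(block)

    scale = 32767.0 / phys_range
    digital = [np.clip(np.asarray(s) * scale, -32767, 32767).astype("<i2")
               for s in signals]
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        for r in range(n_rec):
            for d in digital:
                fh.write(d[r * spr:(r + 1) * spr].tobytes())
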