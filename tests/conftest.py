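import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def write_minimal_edf(path, data, fs):
    """Write a minimal, synthetic EDF file (1-second data records, int16).

    Test-only generator of a spec-conformant EDF header plus sample records,
    used to exercise the EDF reader without shipping binary fixtures.
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    spr = int(fs)  # samples per 1-second record
    n_rec = n_samp // spr

    def pad(s, n):
        return s.encode("ascii")[:n].ljust(n)

    header = bytearray()
    header += pad("0", 8)
    header += pad("X X X X", 80)
    header += pad("Startdate X X X X", 80)
    header += pad("01.01.20", 8)
    header += pad("00.00.00", 8)
    header += pad(str(256 * (1 + n_ch)), 8)
    header += pad("", 44)
    header += pad(str(n_rec), 8)
    header += pad("1", 8)
    header += pad(str(n_ch), 4)
    for i in range(n_ch):
        header += pad(f"EEG CH{i + 1}", 16)
    for _ in range(n_ch):
        header += pad("AgAgCl", 80)
    for _ in range(n_ch):
        header += pad("uV", 8)
    for _ in range(n_ch):
        header += pad("-1000", 8)
    for _ in range(n_ch):
        header += pad("1000", 8)
    for _ in range(n_ch):
        header += pad("-32768", 8)
    for _ in range(n_ch):
        header += pad("32767", 8)
    for _ in range(n_ch):
        header += pad("", 80)
    for _ in range(n_ch):
        header += pad(str(spr), 8)
    for _ in range(n_ch):
        header += pad("", 32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        dig = np.clip(data[:, : n_rec * spr] / 1000 * 32767, -32768, 32767).astype("<i2")
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(dig[c, r * spr : (r + 1) * spr].tobytes())
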