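"""Minimal synthetic EDF+ writer used only to exercise the EDF importer.

Writes a continuous EDF+ file (16-bit samples, one annotation channel
carrying cue events) from scratch; the data are synthetic sinusoids.  Not a
general-purpose exporter — just enough of the format for round-trip tests.
"""

import numpy as np


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    assert len(b) <= width, text
    return b + b" " * (width - len(b))


def write_edf(path, signals, channel_names, fs, annotations,
              phys_range=2000.0):
    """Write ``signals`` (channels x samples) plus annotation events.

    ``annotations`` is a list of ``(onset_seconds, description)``.  Samples
    are scaled into int16 with a symmetric physical range.
    """
    signals = np.asarray(signals, float)
    n_ch, n_samp = signals.shape
    record_dur = 1.0
    sps = int(fs * record_dur)            # samples per record per channel
    n_rec = n_samp // sps
    assert n_rec * sps == n_samp, "signal length must fill whole records"
    ann_bytes_per_rec = 60                # 30 two-byte "samples"

    ns = n_ch + 1
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate 01-JAN-2020 X X X", 80),
        _pad("01.01.20", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("EDF+C", 44),
        _pad(str(n_rec), 8),
        _pad(str(record_dur).rstrip("0").rstrip("."), 8),
        _pad(str(ns), 4),
    ])
    labels = [_pad(nm, 16) for nm in channel_names] + [_pad("EDF Annotations", 16)]
    transducer = [_pad("", 80)] * ns
    phys_dim = [_pad("uV", 8)] * n_ch + [_pad("", 8)]
    phys_min = [_pad(f"{-phys_range:g}", 8)] * n_ch + [_pad("-1", 8)]
    phys_max = [_pad(f"{phys_range:g}", 8)] * n_ch + [_pad("1", 8)]
    dig_min = [_pad("-32768", 8)] * n_ch + [_pad("-32768", 8)]
    dig_max = [_pad("32767", 8)] * n_ch + [_pad("32767", 8)]
    prefilter = [_pad("", 80)] * ns
    n_per_rec = [_pad(str(sps), 8)] * n_ch + [_pad(str(ann_bytes_per_rec // 2), 8)]
    reserved = [_pad("", 32)] * ns
    header += b"".join(labels + transducer + phys_dim + phys_min + phys_max
                       + dig_min + dig_max + prefilter + n_per_rec + reserved)

    scale = 32767.0 / phys_range
    digital = np.clip(np.round(signals * scale), -32768, 32767).astype("<i2")

    records = []
    for r in range(n_rec):
        for ch in range(n_ch):
            records.append(digital[ch, r * sps:(r + 1) * sps].tobytes())
        tal = f"+{r * record_dur:g}\x14\x14\x00".encode("ascii")
        for onset, desc in annotations:
            if r * record_dur <= onset < (r + 1) * record_dur:
                tal += f"+{onset:g}\x14{desc}\x14\x00".encode("ascii")
        assert len(tal) <= ann_bytes_per_rec, "annotation record overflow"
        records.append(tal + b"\x00" * (ann_bytes_per_rec - len(tal)))

    with open(path, "wb") as fh:
        fh.write(header)
        for chunk in records:
            fh.write(chunk)
    return path
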