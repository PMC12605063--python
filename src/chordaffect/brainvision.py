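"""BrainVision (.vhdr/.vmrk/.eeg) reader and writer.

Supports the documented subset: BINARY, MULTIPLEXED orientation,
IEEE_FLOAT_32 or INT_16 (+ per-channel resolution) encodings, with
Stimulus markers carrying ``stimulus_id|condition`` descriptions.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .synth_eeg import Event, RawRecording

__all__ = ["read_brainvision", "write_brainvision"]


def _parse_sections(text: str) -> dict[str, list[tuple[str, str]]]:
    sections: dict[str, list[tuple[str, str]]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        m = re.match(r"\[(.+)\]$", line)
        if m:
            current = m.group(1)
            sections.setdefault(current, [])
            continue
        if current is None or "=" not in line:
            continue
        key, value = line.split("=", 1)
        sections[current].append((key.strip(), value.strip()))
    return sections


def _lookup(items: list[tuple[str, str]], key: str, default=None):
    for k, v in items:
        if k.lower() == key.lower():
            return v
    return default


def write_brainvision(
    rec: RawRecording, base_path: str | Path, binary_format: str = "float32",
    resolution_uv: float = 0.1,
) -> tuple[Path, Path, Path]:
    """Write a recording as a .vhdr/.vmrk/.eeg triplet; returns the paths."""
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    if binary_format not in ("float32", "int16"):
        raise ValueError("binary_format must be 'float32' or 'int16'")

    fmt_name = "IEEE_FLOAT_32" if binary_format == "float32" else "INT_16"
    interval_us = 1e6 / rec.sfreq
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; generated by chordaffect",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={interval_us:g}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={fmt_name}",
        "",
        "[Channel Infos]",
    ]
    res = 1.0 if binary_format == "float32" else resolution_uv
    for i, ch in enumerate(rec.channel_names, start=1):
        lines.append(f"Ch{i}={ch},,{res:g},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for k, ev in enumerate(rec.events, start=2):
        desc = f"{ev.stimulus_id}|{ev.condition}"
        mlines.append(f"Mk{k}=Stimulus,{desc},{ev.sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    mux = np.ascontiguousarray(rec.data.T)  # samples x channels
    if binary_format == "float32":
        mux.astype("<f4").tofile(eeg)
    else:
        scaled = np.clip(np.round(mux / res), -32768, 32767).astype("<i2")
        scaled.tofile(eeg)
    return vhdr, vmrk, eeg


def read_brainvision(header_path: str | Path) -> RawRecording:
    """Read a BrainVision triplet into a recording in microvolts."""
    vhdr = Path(header_path)
    if not vhdr.exists():
        raise FileNotFoundError(f"header file not found: {vhdr}")
    sections = _parse_sections(vhdr.read_text(encoding="utf-8"))
    common = sections.get("Common Infos", [])
    binary = sections.get("Binary Infos", [])
    chan_items = sections.get("Channel Infos", [])

    data_format = _lookup(common, "DataFormat", "BINARY")
    if data_format.upper() != "BINARY":
        raise ValueError(f"unsupported DataFormat {data_format!r}; only BINARY is handled")
    orientation = _lookup(common, "DataOrientation", "MULTIPLEXED")
    if orientation.upper() != "MULTIPLEXED":
        raise ValueError(
            f"unsupported DataOrientation {orientation!r}; only MULTIPLEXED is handled"
        )
    n_channels = int(_lookup(common, "NumberOfChannels"))
    interval_us = float(_lookup(common, "SamplingInterval"))
    sfreq = 1e6 / interval_us

    binary_format = (_lookup(binary, "BinaryFormat") or "IEEE_FLOAT_32").upper()
    if binary_format not in ("IEEE_FLOAT_32", "INT_16"):
        raise ValueError(f"unsupported BinaryFormat {binary_format!r}")

    names, resolutions = [], []
    for key, value in chan_items:
        if not key.lower().startswith("ch"):
            continue
        parts = value.split(",")
        names.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))
    if len(names) != n_channels:
        raise ValueError(
            f"header declares {n_channels} channels but lists {len(names)}"
        )

    eeg_path = vhdr.parent / (_lookup(common, "DataFile") or vhdr.with_suffix(".eeg").name)
    vmrk_path = vhdr.parent / (_lookup(common, "MarkerFile") or vhdr.with_suffix(".vmrk").name)
    if not eeg_path.exists():
        raise FileNotFoundError(f"data file not found: {eeg_path}")

    dtype = "<f4" if binary_format == "IEEE_FLOAT_32" else "<i2"
    raw = np.fromfile(eeg_path, dtype=dtype)
    if raw.size % n_channels:
        raise ValueError("data file size is not a multiple of the channel count")
    data = raw.reshape(-1, n_channels).T.astype(float)
    data *= np.asarray(resolutions)[:, None]

    events: list[Event] = []
    if vmrk_path.exists():
        msec = _parse_sections(vmrk_path.read_text(encoding="utf-8"))
        for key, value in msec.get("Marker Infos", []):
            parts = value.split(",")
            if len(parts) < 3 or parts[0].strip() != "Stimulus":
                continue
            desc = parts[1]
            sid, _, cond = desc.partition("|")
            events.append(
                Event(sample=int(parts[2]) - 1, stimulus_id=sid, condition=cond or sid)
            )
    else:
        raise FileNotFoundError(f"marker file not found: {vmrk_path}")

    return RawRecording(
        data=data,
        sfreq=sfreq,
        channel_names=tuple(names),
        events=tuple(events),
    )
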