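"""Minimal fixed-width GRO coordinate I/O, including concatenated multi-frame
trajectories (the plain-text trajectory format used throughout this package).

Records follow the GROMACS layout: ``%5d%-5s%5s%5d%8.3f%8.3f%8.3f`` with
positions in nm and the (rectangular) box vector on the final line of each
frame.  Residue and atom numbers wrap at 100000 as in GROMACS itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


@dataclass
class GroFrame:
    """One frame of bead records: parallel arrays plus box and time (ps)."""

    resids: np.ndarray      # int
    resnames: np.ndarray    # str
    atomnames: np.ndarray   # str
    positions: np.ndarray   # (n, 3) float, nm
    box: tuple[float, float, float]
    time: float = 0.0


def format_frame(frame: GroFrame, title: str = "oxmembrane") -> str:
    n = len(frame.positions)
    lines = [f"{title} t= {frame.time:.3f}", f"{n:5d}"]
    for i in range(n):
        x, y, z = frame.positions[i]
        lines.append(
            f"{int(frame.resids[i]) % 100000:5d}{str(frame.resnames[i])[:5]:<5s}"
            f"{str(frame.atomnames[i])[:5]:>5s}{(i + 1) % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    bx, by, bz = frame.box
    lines.append(f"{bx:10.5f}{by:10.5f}{bz:10.5f}")
    return "\n".join(lines) + "\n"


def write_frames(frames: list[GroFrame], path=None, title: str = "oxmembrane") -> str:
    text = "".join(format_frame(f, title=title) for f in frames)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def parse_frames(text: str) -> list[GroFrame]:
    lines = text.splitlines()
    frames: list[GroFrame] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        title = lines[pos]
        n = int(lines[pos + 1])
        m = _TIME_RE.search(title)
        time = float(m.group(1)) if m else 0.0
        resids = np.empty(n, dtype=np.int64)
        resnames = np.empty(n, dtype=object)
        atomnames = np.empty(n, dtype=object)
        positions = np.empty((n, 3), dtype=float)
        for i in range(n):
            ln = lines[pos + 2 + i]
            resids[i] = int(ln[0:5])
            resnames[i] = ln[5:10].strip()
            atomnames[i] = ln[10:15].strip()
            positions[i] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
        box_fields = lines[pos + 2 + n].split()
        box = (float(box_fields[0]), float(box_fields[1]), float(box_fields[2]))
        frames.append(GroFrame(resids, np.asarray(resnames, dtype=str),
                               np.asarray(atomnames, dtype=str), positions, box, time))
        pos += 3 + n
    if not frames:
        raise ValueError("no GRO frames found in text")
    return frames


def read_frames(path) -> list[GroFrame]:
    with open(path) as fh:
        return parse_frames(fh.read())
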