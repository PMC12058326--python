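"""Minimal BVH (BioVision Hierarchy) motion-capture reader.

Parses the skeletal hierarchy and per-frame channel data and runs forward
kinematics to recover world-space joint positions, which is all the
decoding pipeline needs. Rotation channels are interpreted as intrinsic
Euler rotations applied in the order listed in the file (the BVH
convention); ``End Site`` blocks are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .containers import MotionRecording

_AXIS_OF = {"Xrotation": "X", "Yrotation": "Y", "Zrotation": "Z"}


@dataclass
class _Joint:
    name: str
    offset: np.ndarray
    channels: list[str]
    channel_start: int
    parent: int  # index into joint list, -1 for root
    children: list[int] = field(default_factory=list)


def _tokenize(text: str) -> list[str]:
    return text.replace("{", " { ").replace("}", " } ").split()


def read_bvh(path: str | Path) -> MotionRecording:
    """Read a BVH file into world-space joint positions per frame."""
    tokens = _tokenize(Path(path).read_text())
    pos = 0

    def expect(tok: str) -> None:
        nonlocal pos
        if tokens[pos].upper() != tok.upper():
            raise ValueError(f"BVH parse error: expected {tok!r}, got "
                             f"{tokens[pos]!r}")
        pos += 1

    expect("HIERARCHY")
    joints: list[_Joint] = []
    n_channels = 0

    def parse_joint(parent: int) -> None:
        nonlocal pos, n_channels
        kind = tokens[pos]  # ROOT / JOINT / End
        pos += 1
        if kind.upper() == "END":
            expect("Site")
            expect("{")
            expect("OFFSET")
            pos += 3
            expect("}")
            return
        name = tokens[pos]
        pos += 1
        expect("{")
        expect("OFFSET")
        offset = np.array([float(tokens[pos + i]) for i in range(3)])
        pos += 3
        expect("CHANNELS")
        n = int(tokens[pos])
        pos += 1
        channels = tokens[pos:pos + n]
        pos += n
        joint = _Joint(name, offset, channels, n_channels, parent)
        n_channels += n
        idx = len(joints)
        joints.append(joint)
        if parent >= 0:
            joints[parent].children.append(idx)
        while tokens[pos] != "}":
            parse_joint(idx)
        expect("}")

    parse_joint(-1)
    expect("MOTION")
    expect("Frames:")
    n_frames = int(tokens[pos])
    pos += 1
    expect("Frame")
    expect("Time:")
    frame_time = float(tokens[pos])
    pos += 1
    values = np.array([float(t) for t in tokens[pos:]], dtype=float)
    if values.size != n_frames * n_channels:
        raise ValueError(f"BVH motion block has {values.size} values, "
                         f"expected {n_frames * n_channels}")
    frames = values.reshape(n_frames, n_channels)

    positions = np.empty((n_frames, len(joints), 3))
    world_rot: list[np.ndarray] = [None] * len(joints)
    for t in range(n_frames):
        row = frames[t]
        for j, joint in enumerate(joints):
            local_t = joint.offset.copy()
            angles, order = [], ""
            for k, ch in enumerate(joint.channels):
                v = row[joint.channel_start + k]
                if ch.endswith("position"):
                    local_t["XYZ".index(ch[0].upper())] += v
                else:
                    order += _AXIS_OF[ch]
                    angles.append(v)
            rot = (Rotation.from_euler(order, angles, degrees=True).as_matrix()
                   if order else np.eye(3))
            if joint.parent < 0:
                positions[t, j] = local_t
                world_rot[j] = rot
            else:
                p = joint.parent
                positions[t, j] = positions[t, p] + world_rot[p] @ local_t
                world_rot[j] = world_rot[p] @ rot
    return MotionRecording(positions, 1.0 / frame_time,
                           [j.name for j in joints])
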