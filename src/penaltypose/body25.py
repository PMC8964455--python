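"""BODY_25 landmark catalogue.

Index layout of the 25-part skeleton emitted by common 2D pose estimators.
Each landmark is an (x, y, confidence) triplet; a full person is therefore a
flat vector of 75 floats.
"""

from __future__ import annotations

N_PARTS = 25
FLOATS_PER_PERSON = 3 * N_PARTS

PART_NAMES: tuple[str, ...] = (
    "Nose",        # 0
    "Neck",        # 1
    "RShoulder",   # 2
    "RElbow",      # 3
    "RWrist",      # 4
    "LShoulder",   # 5
    "LElbow",      # 6
    "LWrist",      # 7
    "MidHip",      # 8
    "RHip",        # 9
    "RKnee",       # 10
    "RAnkle",      # 11
    "LHip",        # 12
    "LKnee",       # 13
    "LAnkle",      # 14
    "REye",        # 15
    "LEye",        # 16
    "REar",        # 17
    "LEar",        # 18
    "LBigToe",     # 19
    "LSmallToe",   # 20
    "LHeel",       # 21
    "RBigToe",     # 22
    "RSmallToe",   # 23
    "RHeel",       # 24
)

PART_INDEX: dict[str, int] = {name: i for i, name in enumerate(PART_NAMES)}

NOSE = 0
NECK = 1
R_SHOULDER = 2
L_SHOULDER = 5
MID_HIP = 8
R_HIP = 9
R_ANKLE = 11
L_HIP = 12
L_ANKLE = 14
L_BIG_TOE = 19
L_SMALL_TOE = 20
L_HEEL = 21
R_BIG_TOE = 22
R_SMALL_TOE = 23
R_HEEL = 24
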