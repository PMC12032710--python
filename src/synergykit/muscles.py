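"""Muscle channel layout for the 30-electrode full-body montage.

Fourteen muscles are recorded bilaterally (left/right adjacent channels),
plus erector spinae (ES) and rectus abdominis (RA) as single trunk channels.
The channel order defined here is the fixed column order of every envelope
matrix in the package.
"""

from __future__ import annotations

# Bilateral muscles, in fixed order. Channel layout: <code>_L, <code>_R pairs,
# then ES, RA.
BILATERAL_MUSCLES = [
    "Pec",  # pectoralis major
    "Lat",  # latissimus dorsi
    "Tra",  # trapezius
    "Del",  # deltoideus
    "Bic",  # biceps brachii
    "Tri",  # triceps brachii
    "GM",   # gluteus medius
    "TF",   # tensor fasciae latae
    "RF",   # rectus femoris
    "VM",   # vastus medialis
    "BF",   # biceps femoris
    "TA",   # tibialis anterior
    "PL",   # peroneus longus
    "GA",   # gastrocnemius
]

SINGLE_MUSCLES = ["ES", "RA"]

CHANNEL_NAMES: list[str] = [
    f"{m}_{side}" for m in BILATERAL_MUSCLES for side in ("L", "R")
] + SINGLE_MUSCLES

N_CHANNELS = len(CHANNEL_NAMES)  # 30

# 16 response labels used by the support statistics (bilateral mean + ES, RA;
# RA last so it is the reference level under effect coding).
MUSCLE16_NAMES: list[str] = BILATERAL_MUSCLES + ["ES", "RA"]

UPPER_BODY = {"Pec", "Lat", "Tra", "Del", "Bic", "Tri"}
LOWER_LIMB = {"GM", "TF", "RF", "VM", "BF", "TA", "PL", "GA"}
TRUNK = {"ES", "RA"}


def muscle_group(channel: str) -> str:
    """Group ('upper_body' | 'lower_limb' | 'trunk') of a channel name."""
    base = channel.split("_")[0]
    if base in UPPER_BODY:
        return "upper_body"
    if base in LOWER_LIMB:
        return "lower_limb"
    if base in TRUNK:
        return "trunk"
    raise KeyError(f"unknown channel {channel!r}")


CHANNEL_GROUPS: list[str] = [muscle_group(c) for c in CHANNEL_NAMES]

# Trunk channels carry ECG contamination in raw recordings.
TRUNK_CHANNEL_INDICES: list[int] = [
    i for i, g in enumerate(CHANNEL_GROUPS) if g == "trunk"
]

GROUP_INDICES: dict[str, list[int]] = {
    g: [i for i, gg in enumerate(CHANNEL_GROUPS) if gg == g]
    for g in ("upper_body", "lower_limb", "trunk")
}
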