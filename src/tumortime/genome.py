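"""Autosomal chromosome-arm model used throughout the package.

The genome is abstracted to 39 autosomal arms; the heterochromatic short
arms of the acrocentric chromosomes (13p, 14p, 15p, 21p, 22p) are excluded
because they carry no timeable events.  Coordinates are arm-relative,
0-based half-open, in base pairs.  Arm lengths are approximate physical
lengths in megabases and sum to roughly 2,800 Mb.
"""

from __future__ import annotations

#: Approximate physical arm lengths in Mb.
ARM_LENGTHS_MB: dict[str, float] = {
    "1p": 125.0, "1q": 124.0,
    "2p": 93.0, "2q": 150.0,
    "3p": 91.0, "3q": 107.0,
    "4p": 50.0, "4q": 141.0,
    "5p": 48.0, "5q": 133.0,
    "6p": 61.0, "6q": 110.0,
    "7p": 60.0, "7q": 99.0,
    "8p": 45.0, "8q": 101.0,
    "9p": 49.0, "9q": 92.0,
    "10p": 40.0, "10q": 96.0,
    "11p": 53.0, "11q": 82.0,
    "12p": 36.0, "12q": 98.0,
    "13q": 98.0,
    "14q": 90.0,
    "15q": 83.0,
    "16p": 37.0, "16q": 54.0,
    "17p": 24.0, "17q": 57.0,
    "18p": 17.0, "18q": 61.0,
    "19p": 27.0, "19q": 32.0,
    "20p": 28.0, "20q": 35.0,
    "21q": 34.0,
    "22q": 35.0,
}

ARMS: tuple[str, ...] = tuple(ARM_LENGTHS_MB)
N_ARMS: int = len(ARMS)
GENOME_MB: float = float(sum(ARM_LENGTHS_MB.values()))

assert N_ARMS == 39


def arm_length_mb(arm: str) -> float:
    """Length of ``arm`` in megabases.

    Raises
    ------
    KeyError
        If ``arm`` is not one of the 39 modeled autosomal arms.
    """
    return ARM_LENGTHS_MB[arm]


def arm_length_bp(arm: str) -> int:
    """Length of ``arm`` in base pairs."""
    return int(ARM_LENGTHS_MB[arm] * 1e6)
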