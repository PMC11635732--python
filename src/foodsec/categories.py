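"""Ordered food-security severity categories shared by every scale.

Both the 10-item resource-constraint module (AFSSM) and the 6-item
physical food security instrument (PFS) map raw affirmative counts onto
the same four ordered severity levels; the cross-classifier combines two
such levels into one joint status.
"""

from __future__ import annotations

import enum


class Category(enum.IntEnum):
    """Severity level, strictly ordered High < Marginal < Low < VeryLow."""

    HIGH = 0
    MARGINAL = 1
    LOW = 2
    VERY_LOW = 3

    @property
    def label(self) -> str:
        return _LABELS[self]


_LABELS = {
    Category.HIGH: "high",
    Category.MARGINAL: "marginal",
    Category.LOW: "low",
    Category.VERY_LOW: "very_low",
}

#: Categories in increasing severity order.
CATEGORIES: tuple[Category, ...] = (
    Category.HIGH,
    Category.MARGINAL,
    Category.LOW,
    Category.VERY_LOW,
)

#: Display names for the joint (cross-classified) status.
JOINT_LABELS = {
    Category.HIGH: "HFS/H-PFS",
    Category.MARGINAL: "MFS/M-PFS",
    Category.LOW: "LFS/L-PFS",
    Category.VERY_LOW: "VLFS/VL-PFS",
}
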