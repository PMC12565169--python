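"""Wrist tissue labels.

Five anatomical structures classically involved in carpal tunnel syndrome are
contoured, plus an OTHER compartment for the remaining wrist interior:

* TCL  -- transverse carpal ligament
* MN   -- median nerve
* SFCT -- sheaths of the flexor carpi tendons
* SCF  -- subcutaneous fat of the wrist
* MTE  -- muscle of the thenar eminence

GCW (global contouring of the wrist) is not a label: it is the union region
encompassing all of the above, evaluated on the label mask at analysis time.
"""

from __future__ import annotations

from enum import IntEnum


class TissueClass(IntEnum):
    """Integer labels used in phantom masks (0 is background/air)."""

    TCL = 1
    MN = 2
    SFCT = 3
    SCF = 4
    MTE = 5
    OTHER = 6


#: The five manually contoured structures (everything but OTHER).
NAMED_STRUCTURES: tuple[TissueClass, ...] = (
    TissueClass.TCL,
    TissueClass.MN,
    TissueClass.SFCT,
    TissueClass.SCF,
    TissueClass.MTE,
)

#: Name of the derived union measurement.
GCW = "GCW"

#: Row order of the six reported measurements.
REPORTED_STRUCTURES: tuple[str, ...] = ("TCL", "MN", "SFCT", "SCF", "MTE", GCW)
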