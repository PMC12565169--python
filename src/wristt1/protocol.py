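"""Acquisition protocol for the multi-flip-angle spoiled gradient-echo series.

The defaults describe a 1.5 T axial wrist protocol: one spoiled gradient-echo
(SPGR) acquisition repeated at six increasing flip angles at each of three
slice levels (proximal, middle, distal), short TR so the signal-versus-angle
curve encodes T1.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ProtocolError(ValueError):
    """Invalid acquisition-protocol parameters."""


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Parameters of the variable-flip-angle SPGR series.

    Parameters
    ----------
    flip_angles_deg : tuple of float
        Nominal excitation flip angles in degrees, strictly increasing,
        each in the open interval (0, 90).
    tr_ms : float
        Repetition time in milliseconds.
    n_levels : int
        Number of axial slice levels acquired per subject.
    image_shape : tuple of int
        In-plane matrix size (rows, columns) of the rendered phantom.
    pixel_mm : tuple of float
        In-plane pixel spacing in millimetres.
    """

    flip_angles_deg: tuple[float, ...] = (2.0, 5.0, 7.0, 10.0, 12.0, 15.0)
    tr_ms: float = 5.81
    n_levels: int = 3
    image_shape: tuple[int, int] = (96, 80)
    pixel_mm: tuple[float, float] = (0.5, 0.6)

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.flip_angles_deg)
        object.__setattr__(self, "flip_angles_deg", angles)
        if len(angles) < 2:
            raise ProtocolError("at least two flip angles are required")
        if any(not (0.0 < a < 90.0) for a in angles):
            raise ProtocolError(f"flip angles must lie in (0, 90) deg, got {angles}")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ProtocolError(f"flip angles must be strictly increasing, got {angles}")
        if not self.tr_ms > 0:
            raise ProtocolError(f"tr_ms must be positive, got {self.tr_ms}")
        if self.n_levels < 1:
            raise ProtocolError(f"n_levels must be >= 1, got {self.n_levels}")
        if len(self.image_shape) != 2 or any(int(s) < 1 for s in self.image_shape):
            raise ProtocolError(f"image_shape must be two positive ints, got {self.image_shape}")
        object.__setattr__(self, "image_shape", (int(self.image_shape[0]), int(self.image_shape[1])))

    @property
    def n_angles(self) -> int:
        return len(self.flip_angles_deg)


DEFAULT_PROTOCOL = AcquisitionProtocol()
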