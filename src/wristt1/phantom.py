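"""Synthetic wrist phantoms with known per-tissue T1.

A subject is a set of per-tissue ground-truth values (T1, M0) drawn from
group-specific priors, plus demographics. Rendering draws a stylized axial
wrist — nested ellipses assigning each pixel a tissue label — and evaluates
the SPGR forward model per pixel at every (slice level, flip angle), then
corrupts the magnitude with Rician noise: |signal + sigma*g1 + i*sigma*g2|
with independent unit normals g1, g2.

The geometry is deliberately schematic: the downstream analysis consumes only
per-ROI mean signals, so anatomical realism contributes nothing to the
quantities under study. Slice levels differ by a small deterministic
contraction (the wrist narrows distally) so per-level ROI areas differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .priors import GroupT1Prior
from .protocol import AcquisitionProtocol
from .relaxometry import spgr_signal
from .tissues import NAMED_STRUCTURES, TissueClass


class GeometryError(ValueError):
    """Image too small to contain all six structures."""


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject."""

    subject_id: str
    group: str                      # "patient" | "control"
    cts: bool                       # carpal tunnel syndrome symptoms; controls always False
    age_years: float
    sex: str                        # "male" | "female"
    t1_ms: dict[str, float]         # per TissueClass name
    m0: dict[str, float]            # per TissueClass name, arbitrary units
    noise_sigma: float = 0.0        # Rician channel sigma, signal units

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"group must be 'patient' or 'control', got {self.group!r}")
        if self.group == "control" and self.cts:
            raise ValueError("controls cannot have CTS")
        for tissue in TissueClass:
            name = tissue.name
            if name not in self.t1_ms or self.t1_ms[name] <= 0:
                raise ValueError(f"t1_ms must be positive for every tissue (bad: {name})")
            if name not in self.m0 or self.m0[name] <= 0:
                raise ValueError(f"m0 must be positive for every tissue (bad: {name})")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomStudy:
    """Rendered image stack and label masks for one subject.

    ``images`` has shape (n_levels, n_angles, H, W); ``masks`` (n_levels, H, W).
    """

    subject_id: str
    images: np.ndarray
    masks: np.ndarray
    truth: SubjectTruth
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        nl, na = self.images.shape[:2]
        if nl != self.protocol.n_levels or na != self.protocol.n_angles:
            raise ValueError("image stack shape inconsistent with protocol")
        if np.any(self.images < 0):
            raise ValueError("magnitude images must be non-negative")


def sample_subject_truth(subject_id: str, group: str, cts: bool,
                         prior: GroupT1Prior, rng: np.random.Generator,
                         age_years: float | None = None, sex: str | None = None,
                         noise_sigma: float = 0.0,
                         m0_loc: float = 1000.0, m0_scale: float = 50.0) -> SubjectTruth:
    """Draw one subject's per-tissue (T1, M0) from the group/CTS priors.

    Deterministic given the generator state. Demographics default to draws
    from the group-specific summaries (patients 78 +/- 9 y, mostly male;
    controls 43 +/- 14 y) when not supplied.
    """
    if group == "control" and cts:
        raise ValueError("controls cannot have CTS")
    t1 = {t.name: float(prior.lookup(t.name, group, cts).sample(rng)) for t in TissueClass}
    m0 = {t.name: float(max(np.abs(rng.normal(m0_loc, m0_scale)), 1e-6)) for t in TissueClass}
    if age_years is None:
        loc, scale = (78.0, 9.0) if group == "patient" else (43.0, 14.0)
        age_years = float(np.clip(rng.normal(loc, scale), 18.0, 100.0))
    if sex is None:
        p_male = 32 / 36 if group == "patient" else 24 / 69
        sex = "male" if rng.random() < p_male else "female"
    return SubjectTruth(subject_id=subject_id, group=group, cts=cts,
                        age_years=age_years, sex=sex, t1_ms=t1, m0=m0,
                        noise_sigma=noise_sigma)


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def wrist_label_mask(shape: tuple[int, int], level: int = 0, n_levels: int = 3) -> np.ndarray:
    """Schematic axial wrist: integer tissue labels, 0 outside the wrist.

    The wrist is an ellipse ringed by subcutaneous fat; inside sit the
    transverse carpal ligament (a thin superficial band), the median nerve
    just beneath it, the flexor tendon sheaths centrally, and the thenar
    muscle laterally. The remaining interior is OTHER. Distal levels contract
    by 7% per level.
    """
    h, w = shape
    if min(h, w) < 32:
        raise GeometryError(f"image shape {shape} too small for the six-structure layout")
    shrink = 1.0 - 0.07 * (level % max(n_levels, 1))
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = 0.42 * h * shrink, 0.45 * w * shrink

    mask = np.zeros(shape, dtype=np.int16)
    wrist = _ellipse(shape, (cy, cx), (ay, ax))
    inner = _ellipse(shape, (cy, cx), (ay - 0.06 * h, ax - 0.06 * w))
    mask[wrist] = TissueClass.OTHER
    mask[wrist & ~inner] = TissueClass.SCF          # subcutaneous rim

    tcl = _ellipse(shape, (cy - 0.22 * ay, cx), (0.055 * h, 0.55 * ax))
    mask[tcl & inner] = TissueClass.TCL             # superficial band
    mn = _ellipse(shape, (cy - 0.02 * ay, cx + 0.12 * ax), (0.06 * h, 0.07 * w))
    mask[mn & inner] = TissueClass.MN
    sfct = _ellipse(shape, (cy + 0.30 * ay, cx), (0.14 * h, 0.28 * ax))
    mask[sfct & inner] = TissueClass.SFCT
    mte = _ellipse(shape, (cy + 0.15 * ay, cx - 0.55 * ax), (0.16 * h, 0.12 * w))
    mask[mte & inner] = TissueClass.MTE

    for tissue in TissueClass:
        if not np.any(mask == tissue):
            raise GeometryError(f"structure {tissue.name} empty at shape {shape}, level {level}")
    return mask


def render_phantom(truth: SubjectTruth, protocol: AcquisitionProtocol,
                   rng: np.random.Generator | int | None = None) -> PhantomStudy:
    """Render the multi-level, multi-flip-angle magnitude image stack."""
    rng = np.random.default_rng(rng)
    h, w = protocol.image_shape
    nl, na = protocol.n_levels, protocol.n_angles
    masks = np.stack([wrist_label_mask((h, w), level=lv, n_levels=nl) for lv in range(nl)])

    # per-pixel T1/M0 lookup tables (index = label; label 0 = background)
    t1_lut = np.ones(len(TissueClass) + 1)
    m0_lut = np.zeros(len(TissueClass) + 1)
    for tissue in TissueClass:
        t1_lut[tissue] = truth.t1_ms[tissue.name]
        m0_lut[tissue] = truth.m0[tissue.name]

    images = np.empty((nl, na, h, w), dtype=float)
    sigma = truth.noise_sigma
    for lv in range(nl):
        t1_img = t1_lut[masks[lv]]
        m0_img = m0_lut[masks[lv]]
        for ia, alpha in enumerate(protocol.flip_angles_deg):
            ideal = spgr_signal(m0_img, t1_img, protocol.tr_ms, alpha)
            if sigma > 0:
                g1 = rng.standard_normal((h, w))
                g2 = rng.standard_normal((h, w))
                images[lv, ia] = np.hypot(ideal + sigma * g1, sigma * g2)
            else:
                images[lv, ia] = ideal
    return PhantomStudy(subject_id=truth.subject_id, images=images, masks=masks,
                        truth=truth, protocol=protocol)


def peak_signal(truth: SubjectTruth, protocol: AcquisitionProtocol,
                tissue: str = "OTHER") -> float:
    """Largest in-protocol SPGR signal of a tissue; the noise-sigma reference."""
    return float(max(spgr_signal(truth.m0[tissue], truth.t1_ms[tissue],
                                 protocol.tr_ms, a) for a in protocol.flip_angles_deg))
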