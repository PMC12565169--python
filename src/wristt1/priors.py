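"""True-T1 priors for the synthetic cohort.

Published group summaries give only the median and interquartile range of
native T1 per structure, so the generating family is not identified. The
default is a normal distribution matched by quantiles — location = median,
scale = IQR / 1.349 (the IQR of a standard normal is 2 * 0.6745) — truncated
at zero since T1 is a relaxation time. A log-normal alternative matched the
same way on the log scale is available via ``family="lognormal"``.

The subcutaneous-fat (SCF) prior for patients is stratified by carpal tunnel
syndrome status, mirroring the reported subgroup split; every other tissue has
one patient prior and one control prior. The OTHER compartment (wrist interior
outside the five named structures) uses the global-wrist summary values, since
the global contour is dominated by un-named interior tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .tissues import TissueClass

#: IQR of the standard normal distribution: 2 * Phi^{-1}(0.75).
NORMAL_IQR = 1.3489795003921634


class PriorError(ValueError):
    """Invalid or missing prior configuration."""


@dataclass(frozen=True)
class PriorEntry:
    """Location/scale for one (tissue, group, CTS) cell, with the quartiles it came from."""

    location: float
    scale: float
    median: float
    q1: float
    q3: float
    family: str = "normal"

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray | float:
        """Draw T1 values (ms), strictly positive."""
        if self.family == "normal":
            if self.scale == 0.0:
                return np.full(size, self.location) if size is not None else self.location
            # truncate at 0 (T1 is a time) by rejection; cheap since the
            # truncated mass is tiny for every configured tissue
            draws = rng.normal(self.location, self.scale, size=size)
            out = np.atleast_1d(draws)
            bad = out <= 0
            while bad.any():
                out[bad] = rng.normal(self.location, self.scale, size=int(bad.sum()))
                bad = out <= 0
            return float(out[0]) if size is None else out
        if self.family == "lognormal":
            # quantile-matched on the log scale: exp(mu) = median, IQR ratio fixes sigma
            mu = np.log(self.median)
            sigma = np.log(self.q3 / self.q1) / NORMAL_IQR
            return rng.lognormal(mean=mu, sigma=sigma, size=size)
        raise PriorError(f"unknown prior family {self.family!r}")


def fit_prior_from_quartiles(median: float, q1: float, q3: float,
                             family: str = "normal") -> PriorEntry:
    """Build a prior entry from a published median and quartiles.

    The scale is (q3 - q1) / 1.349, the normal-quantile matching of the IQR;
    location is the median itself.

    Raises
    ------
    PriorError
        If the quartiles are not ordered ``0 < q1 < median < q3``.
    """
    if not (0 < q1 < median < q3):
        raise PriorError(
            f"quartiles must satisfy 0 < q1 < median < q3, got ({median}, {q1}, {q3})"
        )
    if family not in ("normal", "lognormal"):
        raise PriorError(f"unknown prior family {family!r}")
    scale = (q3 - q1) / NORMAL_IQR
    return PriorEntry(location=float(median), scale=float(scale),
                      median=float(median), q1=float(q1), q3=float(q3), family=family)


# Published per-structure native-T1 summaries, ms: median, (q1, q3).
# Patient SCF is stratified by CTS symptoms; OTHER reuses the global-wrist row.
_QUARTILES: dict[tuple[str, str, bool | None], tuple[float, float, float]] = {
    ("TCL", "patient", None): (829, 725, 928),
    ("TCL", "control", None): (994, 926, 1085),
    ("MN", "patient", None): (1234, 1130, 1333),
    ("MN", "control", None): (1406, 1289, 1528),
    ("SFCT", "patient", None): (1030, 924, 1122),
    ("SFCT", "control", None): (1175, 1104, 1287),
    ("SCF", "patient", True): (885, 762, 1080),
    ("SCF", "patient", False): (1041, 949, 1267),
    ("SCF", "control", None): (1165, 1014, 1295),
    ("MTE", "patient", None): (185, 143, 272),
    ("MTE", "control", None): (205, 165, 293),
    ("OTHER", "patient", None): (934, 865, 1025),
    ("OTHER", "control", None): (1111, 1029, 1174),
}

GROUPS = ("patient", "control")


class GroupT1Prior:
    """Per-(tissue, group, CTS-status) true-T1 priors for cohort simulation."""

    def __init__(self, entries: Mapping[tuple[str, str, bool | None], PriorEntry]):
        self.entries = dict(entries)
        self._validate()

    def _validate(self) -> None:
        for tissue in TissueClass:
            for group in GROUPS:
                try:
                    self.lookup(tissue.name, group, cts=(group == "patient"))
                    self.lookup(tissue.name, group, cts=False)
                except KeyError as exc:
                    raise PriorError(str(exc)) from exc

    def lookup(self, tissue: str, group: str, cts: bool) -> PriorEntry:
        """Resolve the prior for a tissue; CTS-stratified cells take precedence."""
        key_strat = (tissue, group, bool(cts))
        if key_strat in self.entries:
            return self.entries[key_strat]
        key = (tissue, group, None)
        if key in self.entries:
            return self.entries[key]
        raise KeyError(f"no prior configured for tissue={tissue!r}, group={group!r}, cts={cts}")

    @classmethod
    def from_quartile_table(cls, table: Mapping[tuple[str, str, bool | None],
                                                tuple[float, float, float]],
                            family: str = "normal") -> "GroupT1Prior":
        entries = {key: fit_prior_from_quartiles(*vals, family=family)
                   for key, vals in table.items()}
        return cls(entries)


def default_t1_prior(family: str = "normal") -> GroupT1Prior:
    """The cohort-default prior table (per-structure published medians/IQRs)."""
    return GroupT1Prior.from_quartile_table(_QUARTILES, family=family)


def quartile_table() -> dict[tuple[str, str, bool | None], tuple[float, float, float]]:
    """A copy of the default (median, q1, q3) table, for configs and docs."""
    return dict(_QUARTILES)
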