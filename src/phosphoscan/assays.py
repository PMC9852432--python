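"""Accessory quantitative assays: Cks1 priming spacing, reporter units,
doubling times.

Cks1, the CDK phosphoadaptor subunit, docks onto an already-phosphorylated
*threonine* (not serine) and delivers the kinase to CDK consensus sites 12
to 30 residues downstream, driving processive N-to-C multisite
phosphorylation.  :func:`candidate_priming_pairs` enumerates which site
pairs of a scheme satisfy that geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import PhosphositeScheme, Site

__all__ = ["PrimingRule", "candidate_priming_pairs", "beta_gal_units",
           "doubling_time", "AssayError"]


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class PrimingRule:
    """Spacing and residue requirements for Cks1-mediated priming.

    Defaults: the primed (downstream) site lies 12-30 residues C-terminal
    of the priming phosphosite, bounds inclusive, and only threonines can
    prime (Cks1 binds phosphothreonine, not phosphoserine).
    """

    min_spacing: int = 12
    max_spacing: int = 30
    priming_residues: tuple[str, ...] = ("T",)

    def __post_init__(self) -> None:
        if self.min_spacing > self.max_spacing:
            raise AssayError("min_spacing exceeds max_spacing")
        if not set(self.priming_residues) <= {"S", "T"}:
            raise AssayError("priming residues must be phosphoacceptors (S/T)")


def candidate_priming_pairs(
    scheme: PhosphositeScheme | tuple[Site, ...],
    rule: PrimingRule = PrimingRule(),
) -> list[tuple[str, str]]:
    """Ordered (primer, target) site pairs satisfying the priming rule.

    A pair ``(i, j)`` qualifies when site *i* is upstream of *j*, its
    wild-type residue is an allowed priming residue, and the spacing
    ``position(j) - position(i)`` (difference of phosphoacceptor residue
    indices) lies within ``[min_spacing, max_spacing]``.  Returns label
    pairs in N-to-C order of the primer, then the target.
    """
    sites = scheme.sites if isinstance(scheme, PhosphositeScheme) else tuple(scheme)
    pairs = []
    for i, primer in enumerate(sites):
        if primer.wt_residue not in rule.priming_residues:
            continue
        for target in sites[i + 1:]:
            spacing = target.position - primer.position
            if rule.min_spacing <= spacing <= rule.max_spacing:
                pairs.append((primer.label, target.label))
    return pairs


def beta_gal_units(
    od405: float, od600: float, volume_ml: float = 1.0, minutes: float = 1.0
) -> float:
    """Beta-galactosidase reporter activity: 1000*OD405/(OD600*mL*min)."""
    if od600 <= 0 or volume_ml <= 0 or minutes <= 0:
        raise AssayError("OD600, volume and reaction time must be positive")
    return 1000.0 * od405 / (od600 * volume_ml * minutes)


def doubling_time(
    times_h, od600, window: tuple[float, float] = (0.2, 0.5)
) -> float:
    """Doubling time (hours) from a growth curve.

    Fits log2(OD600) against time by OLS, restricted to points whose OD
    lies inside the absolute window (bounds inclusive; default 0.2-0.5,
    the exponential phase of a typical yeast culture), and returns
    ``1 / slope``.  A non-positive slope means the culture is not growing
    within the window; ``inf`` is returned to flag it.
    """
    t = np.asarray(times_h, dtype=float)
    od = np.asarray(od600, dtype=float)
    if t.shape != od.shape:
        raise AssayError("time and OD arrays must have matching shapes")
    lo, hi = window
    mask = (od >= lo) & (od <= hi)
    if mask.sum() < 2:
        raise AssayError(
            f"fewer than 2 points inside the OD window [{lo}, {hi}]"
        )
    slope = np.polyfit(t[mask], np.log2(od[mask]), 1)[0]
    if slope <= 0:
        return float("inf")  # non-growing
    return float(1.0 / slope)
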