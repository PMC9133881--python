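"""Small wet-lab-adjacent computations: phenotype calls and qPCR fold change.

The hairless-pig phenotype is defined on hair-follicle density: embryos with
fewer than one follicle per cm^2 are hairless, embryos with more than four
are normal, and densities in between are left indeterminate.  Relative qPCR
expression uses the standard 2^-ddCt method against a reference gene.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PhenotypeThresholds",
    "classify_phenotype",
    "ddct_relative_expression",
]


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Follicle-density cutoffs (follicles/cm^2), both exclusive."""

    hairless_max: float = 1.0
    normal_min: float = 4.0

    def __post_init__(self) -> None:
        if not self.hairless_max < self.normal_min:
            raise ValueError("hairless_max must be below normal_min")


def classify_phenotype(
    density: float, thresholds: PhenotypeThresholds = PhenotypeThresholds()
) -> str:
    """Classify an embryo as ``hairless``, ``normal`` or ``indeterminate``.

    Parameters
    ----------
    density:
        Hair-follicle density in follicles per cm^2; must be non-negative.
    """
    if density < 0:
        raise ValueError(f"follicle density must be >= 0, got {density}")
    if density < thresholds.hairless_max:
        return "hairless"
    if density > thresholds.normal_min:
        return "normal"
    return "indeterminate"


def ddct_relative_expression(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression fold change by the 2^-ddCt method.

    ddCt = (Ct_target,treated - Ct_ref,treated)
         - (Ct_target,control - Ct_ref,control); returns 2**-ddCt.
    Invariant to adding a constant to all four Ct values.
    """
    for ct in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not (ct == ct and abs(ct) != float("inf")):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0**-ddct
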