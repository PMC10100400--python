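"""Accurate-mass (level-3) annotation of aligned features.

Each (compound, adduct) pair's theoretical m/z is compared against the
feature centroids; every pair within the ppm tolerance is reported — level-3
identification by accurate mass alone is inherently ambiguous, so no
arbitration between candidate hits is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CompoundRecord
from .masses import Adduct, DEFAULT_NEGATIVE_ADDUCTS, adduct_mz, neutral_mass, ppm_error

__all__ = ["AnnotationHit", "annotate", "hits_to_frame"]


@dataclass(frozen=True)
class AnnotationHit:
    """One feature <-> (compound, adduct) accurate-mass match."""

    feature_mz: float
    compound: CompoundRecord
    adduct: Adduct
    theoretical_mz: float
    ppm_error: float
    level: str = "level3"

    @property
    def neutral_mass(self) -> float:
        """Monoisotopic neutral mass implied by the observed m/z and adduct."""
        return neutral_mass(self.feature_mz, self.adduct)


def annotate(
    feature_mzs: np.ndarray,
    compounds: list[CompoundRecord],
    adducts: tuple[Adduct, ...] = DEFAULT_NEGATIVE_ADDUCTS,
    tolerance_ppm: float = 5.0,
) -> list[AnnotationHit]:
    """Match feature centroids against a compound table within a ppm window.

    Returns every in-tolerance (feature, compound, adduct) combination,
    sorted by absolute ppm error (ties by feature m/z then compound id).
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    feature_mzs = np.asarray(feature_mzs, dtype=float)
    hits: list[AnnotationHit] = []
    for comp in compounds:
        for adduct in adducts:
            if comp.monoisotopic_mass + adduct.mass_shift <= 0:
                continue
            theo = adduct_mz(comp.monoisotopic_mass, adduct)
            err = (feature_mzs - theo) / theo * 1e6
            for idx in np.flatnonzero(np.abs(err) <= tolerance_ppm):
                hits.append(
                    AnnotationHit(
                        feature_mz=float(feature_mzs[idx]),
                        compound=comp,
                        adduct=adduct,
                        theoretical_mz=theo,
                        ppm_error=ppm_error(float(feature_mzs[idx]), theo),
                    )
                )
    hits.sort(key=lambda h: (abs(h.ppm_error), h.feature_mz, h.compound.compound_id))
    return hits


def hits_to_frame(hits: list[AnnotationHit]) -> pd.DataFrame:
    """Annotation hits as a flat table (the TSV export layout)."""
    return pd.DataFrame(
        {
            "feature_mz": [h.feature_mz for h in hits],
            "compound_id": [h.compound.compound_id for h in hits],
            "name": [h.compound.name for h in hits],
            "formula": [h.compound.formula for h in hits],
            "adduct": [h.adduct.name for h in hits],
            "theoretical_mz": [h.theoretical_mz for h in hits],
            "ppm_error": [h.ppm_error for h in hits],
            "neutral_mass": [h.neutral_mass for h in hits],
            "level": [h.level for h in hits],
        }
    )
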