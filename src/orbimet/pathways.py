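"""Local pathway-coverage mapping of annotated metabolite masses.

Replaces a web-service lookup with a reproducible local computation: a
query neutral monoisotopic mass matches a pathway member if it lies within
a ppm tolerance of the member's monoisotopic mass, and pathway coverage is
the matched fraction of the member list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DataError
from .annotation import AnnotationHit
from .masses import monoisotopic_mass

__all__ = [
    "PathwayDefinition",
    "PathwayMapResult",
    "load_pathways",
    "map_to_pathways",
    "ubiquitous_pathway_report",
]


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    member_ids: tuple[str, ...]
    member_masses: tuple[float, ...]

    def __post_init__(self):
        if not self.member_ids:
            raise DataError(f"pathway {self.pathway_id} has no members")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise DataError(f"pathway {self.pathway_id} has duplicate members")


@dataclass
class PathwayMapResult:
    pathway_id: str
    name: str
    matched_members: list[str]
    matched_masses: list[float]  # query masses that matched, aligned to members
    coverage: float


def load_pathways(
    table: pd.DataFrame, compound_masses: dict[str, float] | None = None
) -> list[PathwayDefinition]:
    """Build pathway definitions from a membership table.

    Member masses come from the table's ``formula`` column when present,
    otherwise from ``compound_masses`` (compound_id -> monoisotopic Da).
    """
    defs = []
    for pid, grp in table.groupby("pathway_id", sort=True):
        ids, masses = [], []
        for row in grp.itertuples():
            if "formula" in grp.columns and isinstance(row.formula, str):
                mass = monoisotopic_mass(row.formula)
            elif compound_masses and row.compound_id in compound_masses:
                mass = compound_masses[row.compound_id]
            else:
                raise DataError(
                    f"no mass available for pathway member {row.compound_id}"
                )
            ids.append(row.compound_id)
            masses.append(mass)
        defs.append(
            PathwayDefinition(pid, grp["pathway_name"].iloc[0], tuple(ids), tuple(masses))
        )
    return defs


def map_to_pathways(
    masses: np.ndarray,
    pathways: list[PathwayDefinition],
    tolerance_ppm: float = 2.0,
) -> list[PathwayMapResult]:
    """Match neutral masses to pathway members; sort by coverage descending.

    A member is matched if *any* query mass is within ``tolerance_ppm`` of
    its monoisotopic mass; coverage = matched members / all members.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    masses = np.asarray(masses, dtype=float)
    results = []
    for pw in pathways:
        matched_ids, matched_masses = [], []
        for cid, m in zip(pw.member_ids, pw.member_masses):
            if masses.size:
                err = np.abs(masses - m) / m * 1e6
                j = int(np.argmin(err))
                if err[j] <= tolerance_ppm:
                    matched_ids.append(cid)
                    matched_masses.append(float(masses[j]))
        results.append(
            PathwayMapResult(
                pw.pathway_id,
                pw.name,
                matched_ids,
                matched_masses,
                len(matched_ids) / len(pw.member_ids),
            )
        )
    results.sort(key=lambda r: (-r.coverage, r.pathway_id))
    return results


def ubiquitous_pathway_report(
    ubiquitous_mzs: np.ndarray,
    hits: list[AnnotationHit],
    pathways: list[PathwayDefinition],
    tolerance_ppm: float = 2.0,
    region_means: pd.DataFrame | None = None,
) -> tuple[list[PathwayMapResult], pd.DataFrame]:
    """Pathway coverage of the annotated ubiquitous features.

    Joins the annotation hits restricted to ubiquitous feature m/z values,
    maps their implied neutral masses onto the pathway definitions, and
    returns (coverage results, per-member table).  ``region_means`` may
    supply per-region mean TIC-normalized intensities indexed by feature
    m/z, which are carried into the member table.
    """
    ubiquitous_mzs = np.asarray(ubiquitous_mzs, dtype=float)
    ubi_hits = [h for h in hits if np.any(np.isclose(ubiquitous_mzs, h.feature_mz))]
    masses = np.array([h.neutral_mass for h in ubi_hits])
    results = map_to_pathways(masses, pathways, tolerance_ppm)

    rows = []
    for res in results:
        for cid, qmass in zip(res.matched_members, res.matched_masses):
            for h in ubi_hits:
                if abs(h.neutral_mass - qmass) < 1e-9:
                    row = {
                        "pathway_id": res.pathway_id,
                        "pathway_name": res.name,
                        "compound_id": cid,
                        "annotated_name": h.compound.name,
                        "feature_mz": h.feature_mz,
                        "adduct": h.adduct.name,
                        "neutral_mass": h.neutral_mass,
                        "coverage": res.coverage,
                    }
                    if region_means is not None:
                        match = region_means.index[
                            np.isclose(region_means.index.to_numpy(), h.feature_mz)
                        ]
                        if len(match):
                            for col in region_means.columns:
                                row[col] = region_means.loc[match[0], col]
                    rows.append(row)
    return results, pd.DataFrame(rows)
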