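"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .masses import monoisotopic_mass

REGIONS = ("necrotic", "viable", "non_cancerous")

#: Instrument acquisition window, Da (negative mode depth profiling).
INSTRUMENT_MZ_RANGE = (75.0, 1125.0)


class DataError(ValueError):
    """A value violates a pipeline data contract."""


class ParseError(ValueError):
    """A file could not be parsed into a valid object."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one depth-profile acquisition site."""

    patient_id: str
    region: str
    site_index: int
    polarity: str = "negative"

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise DataError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.polarity != "negative":
            raise DataError("only negative polarity is supported")

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id}_{self.region}_s{self.site_index}"


@dataclass
class DepthProfileSpectrum:
    """One site's summed-scan peak list: parallel m/z / intensity arrays.

    m/z is strictly increasing and intensities are non-negative after
    :meth:`validate`; constructors in this package always validate.
    """

    mz: np.ndarray
    intensity: np.ndarray
    meta: SampleMeta

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)

    def validate(self, mz_range: tuple[float, float] | None = INSTRUMENT_MZ_RANGE) -> None:
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise DataError("mz and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise DataError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise DataError("intensities must be non-negative")
        if mz_range is not None and self.mz.size:
            lo, hi = mz_range
            if self.mz[0] < lo or self.mz[-1] > hi:
                raise DataError(
                    f"peaks outside m/z range [{lo}, {hi}]: "
                    f"[{self.mz[0]:.4f}, {self.mz[-1]:.4f}]"
                )

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def base_peak_intensity(self) -> float:
        if self.mz.size == 0:
            raise DataError("empty spectrum has no base peak")
        return float(self.intensity.max())


@dataclass(frozen=True)
class CompoundRecord:
    """One small-molecule library entry; mass is consistent with the formula."""

    compound_id: str
    name: str
    formula: str
    monoisotopic_mass: float

    @classmethod
    def from_formula(cls, compound_id: str, name: str, formula: str) -> "CompoundRecord":
        return cls(compound_id, name, formula, monoisotopic_mass(formula))

    def check_mass(self, tol_da: float = 1e-3) -> None:
        expected = monoisotopic_mass(self.formula)
        if abs(expected - self.monoisotopic_mass) > tol_da:
            raise DataError(
                f"compound {self.compound_id} ({self.name}): stated mass "
                f"{self.monoisotopic_mass:.5f} differs from formula mass "
                f"{expected:.5f} by more than {tol_da} Da"
            )


@dataclass
class FeatureMatrix:
    """Samples x aligned-features intensity matrix with explicit missingness.

    ``values`` holds NaN wherever ``missing_mask`` is True; observed cells are
    finite and non-negative until scaling transforms are applied.
    ``transform_log`` is append-only and records the processing history.
    """

    sample_ids: list[str]
    sample_meta: list[SampleMeta]
    feature_centroids: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray
    transform_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.feature_centroids = np.asarray(self.feature_centroids, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)

    # -- shape -----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return int(self.feature_centroids.size)

    def validate(self) -> None:
        n, p = self.n_samples, self.n_features
        if self.values.shape != (n, p) or self.missing_mask.shape != (n, p):
            raise DataError(
                f"shape mismatch: values {self.values.shape}, mask "
                f"{self.missing_mask.shape}, expected ({n}, {p})"
            )
        if len(self.sample_meta) != n:
            raise DataError("sample_meta length differs from sample_ids")
        if p > 1 and np.any(np.diff(self.feature_centroids) <= 0):
            raise DataError("feature centroids must be strictly increasing")
        observed = self.values[~self.missing_mask]
        if not np.all(np.isfinite(observed)):
            raise DataError("observed values must be finite")

    # -- helpers ---------------------------------------------------------
    def missing_fraction(self) -> np.ndarray:
        """Per-feature fraction of missing cells."""
        return self.missing_mask.mean(axis=0)

    def regions(self) -> np.ndarray:
        return np.array([m.region for m in self.sample_meta])

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            list(self.sample_ids),
            list(self.sample_meta),
            self.feature_centroids.copy(),
            self.values.copy(),
            self.missing_mask.copy(),
            list(self.transform_log),
        )

    def take_features(self, index: np.ndarray, log_entry: str | None = None) -> "FeatureMatrix":
        """New matrix restricted to the given feature indices (order preserved)."""
        out = FeatureMatrix(
            list(self.sample_ids),
            list(self.sample_meta),
            self.feature_centroids[index],
            self.values[:, index],
            self.missing_mask[:, index],
            list(self.transform_log),
        )
        if log_entry:
            out.transform_log.append(log_entry)
        return out

    def take_samples(self, index: np.ndarray) -> "FeatureMatrix":
        """New matrix restricted to the given sample indices (order preserved)."""
        index = np.asarray(index)
        return FeatureMatrix(
            [self.sample_ids[i] for i in index],
            [self.sample_meta[i] for i in index],
            self.feature_centroids.copy(),
            self.values[index],
            self.missing_mask[index],
            list(self.transform_log),
        )

    def with_values(
        self,
        values: np.ndarray,
        log_entry: str,
        missing_mask: np.ndarray | None = None,
    ) -> "FeatureMatrix":
        out = replace(
            self,
            values=np.asarray(values, dtype=float),
            missing_mask=(
                self.missing_mask.copy() if missing_mask is None else missing_mask
            ),
            sample_ids=list(self.sample_ids),
            sample_meta=list(self.sample_meta),
            feature_centroids=self.feature_centroids.copy(),
            transform_log=list(self.transform_log) + [log_entry],
        )
        return out
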