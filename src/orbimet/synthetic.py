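"""Synthetic depth-profile cohorts with known ground truth.

The generator emulates the design of an OrbiSIMS depth-profiling study of
histologically distinct tissue regions: ``n_patients`` patients, a fixed set
of regions per patient, and ``sites_per_region`` depth-profile sites per
region, each yielding one summed peak list in negative mode over a fixed
m/z window.

Statistical model
-----------------
Each cohort draws a set of library compounds; every compound is assigned a
single negative-mode adduct and contributes one peak per spectrum at the
adduct's theoretical m/z perturbed by Gaussian ppm jitter.  Intensities are
log-normal: log-intensity = compound baseline + patient random effect +
region effect + noise.  Region effects are expressed in Cohen's-d units of
the total within-group log-intensity standard deviation, so the configured
``effect_size`` is directly the standardized group-mean difference the
downstream statistics should recover.  Missingness is detection-limited by
default (low-intensity cells are preferentially censored) with a
completely-at-random alternative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    INSTRUMENT_MZ_RANGE,
    REGIONS,
    CompoundRecord,
    DataError,
    DepthProfileSpectrum,
    SampleMeta,
)
from .io import bundled_compound_table, write_compound_table
from .masses import Adduct, DEFAULT_NEGATIVE_ADDUCTS, adduct_mz

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_cohort", "sum_scans"]

#: minimum ppm separation enforced between generated adduct m/z values, so
#: that alignment at the usual 5 ppm window cannot merge distinct compounds.
_MIN_SEPARATION_PPM = 25.0


class ConfigError(ValueError):
    """A SyntheticConfig field is out of its documented range."""


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters for :func:`generate_cohort`.

    Defaults mirror the emulated study: 4 patients x 3 regions x 5 sites,
    80 summed scans per profile, negative mode m/z 75-1125.
    """

    n_patients: int = 4
    regions: tuple[str, ...] = REGIONS
    sites_per_region: int = 5
    n_scans: int = 80
    mz_range: tuple[float, float] = INSTRUMENT_MZ_RANGE
    n_background_compounds: int = 150
    n_discriminative_compounds: int = 10
    effect_size: float = 2.0
    mass_jitter_ppm: float = 1.0
    missing_rate: float = 0.10
    intensity_cv: float = 0.4
    baseline_range: tuple[float, float] = (1e5, 1e6)
    between_patient_sd: float = 0.15
    missing_mechanism: str = "intensity"  # or "random"
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if len(self.regions) < 1 or any(r not in REGIONS for r in self.regions):
            raise ConfigError(f"regions must be drawn from {REGIONS}")
        if len(set(self.regions)) != len(self.regions):
            raise ConfigError("regions must be unique")
        if self.sites_per_region < 2:
            raise ConfigError("sites_per_region must be >= 2")
        if self.n_scans < 1:
            raise ConfigError("n_scans must be >= 1")
        lo, hi = self.mz_range
        if not (INSTRUMENT_MZ_RANGE[0] <= lo < hi <= INSTRUMENT_MZ_RANGE[1]):
            raise ConfigError(
                f"mz_range must lie within the instrument range {INSTRUMENT_MZ_RANGE}"
            )
        if self.n_background_compounds < 0:
            raise ConfigError("n_background_compounds must be >= 0")
        if self.n_discriminative_compounds < 0:
            raise ConfigError("n_discriminative_compounds must be >= 0")
        if self.mass_jitter_ppm < 0:
            raise ConfigError("mass_jitter_ppm must be >= 0")
        if not 0 <= self.missing_rate <= 0.5:
            raise ConfigError("missing_rate must be in [0, 0.5]")
        if self.intensity_cv <= 0:
            raise ConfigError("intensity_cv must be > 0")
        if not 0 < self.baseline_range[0] < self.baseline_range[1]:
            raise ConfigError("baseline_range must be an increasing positive pair")
        if self.between_patient_sd < 0:
            raise ConfigError("between_patient_sd must be >= 0")
        if self.missing_mechanism not in ("intensity", "random"):
            raise ConfigError("missing_mechanism must be 'intensity' or 'random'")

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        """All unordered region pairs, in region-list order."""
        return list(itertools.combinations(self.regions, 2))


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic cohort.

    ``compound_assignments`` maps each theoretical feature m/z to its
    generating compound and adduct; ``effect_table`` holds one row per
    spiked (compound, contrast) with the signed standardized log-fold
    effect; ``missing_mask_truth`` marks the censored cells.
    """

    compound_assignments: pd.DataFrame  # theoretical_mz, compound_id, adduct
    effect_table: pd.DataFrame  # compound_id, region_a, region_b, direction, effect_size
    missing_mask_truth: pd.DataFrame  # samples x theoretical m/z (bool)

    def spiked_mzs(self) -> np.ndarray:
        spiked = set(self.effect_table["compound_id"])
        sel = self.compound_assignments["compound_id"].isin(spiked)
        return self.compound_assignments.loc[sel, "theoretical_mz"].to_numpy()

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.compound_assignments.to_csv(
            outdir / "truth_assignments.tsv", sep="\t", index=False
        )
        self.effect_table.to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)
        self.missing_mask_truth.to_csv(outdir / "truth_missing.tsv", sep="\t")


def _select_compounds(
    rng: np.random.Generator,
    library: list[CompoundRecord],
    n_needed: int,
    mz_range: tuple[float, float],
) -> tuple[list[CompoundRecord], list[Adduct], np.ndarray]:
    """Draw compounds and adducts whose m/z are in range and well separated."""
    order = rng.permutation(len(library))
    chosen: list[CompoundRecord] = []
    adducts: list[Adduct] = []
    mzs: list[float] = []
    for idx in order:
        rec = library[idx]
        # adduct drawn at random; fall back to the other type on collision
        for adduct in rng.permutation(len(DEFAULT_NEGATIVE_ADDUCTS)):
            add = DEFAULT_NEGATIVE_ADDUCTS[adduct]
            if rec.monoisotopic_mass + add.mass_shift <= 0:
                continue
            mz = adduct_mz(rec.monoisotopic_mass, add)
            if not (mz_range[0] <= mz <= mz_range[1]):
                continue
            if all(abs(mz - m) / m * 1e6 > _MIN_SEPARATION_PPM for m in mzs):
                chosen.append(rec)
                adducts.append(add)
                mzs.append(mz)
                break
        if len(chosen) == n_needed:
            break
    if len(chosen) < n_needed:
        raise ConfigError(
            f"compound library supports at most {len(chosen)} well-separated "
            f"features in m/z range {mz_range}; {n_needed} requested"
        )
    return chosen, adducts, np.array(mzs)


def generate_cohort(
    config: SyntheticConfig,
    library: list[CompoundRecord] | None = None,
) -> tuple[list[DepthProfileSpectrum], SyntheticTruth, list[CompoundRecord]]:
    """Generate a reproducible depth-profile cohort plus its ground truth.

    Returns one spectrum per patient x region x site, the :class:`SyntheticTruth`,
    and the compound table actually used (a subset of the library).
    """
    config.validate()
    if library is None:
        library = bundled_compound_table()
    rng = np.random.default_rng(config.seed)

    contrasts = config.contrasts
    n_disc_total = config.n_discriminative_compounds * len(contrasts)
    n_total = config.n_background_compounds + n_disc_total
    compounds, adducts, theo_mz = _select_compounds(rng, library, n_total, config.mz_range)

    # spiked compounds: the first n_disc_total of the shuffled selection
    sigma_noise = math.sqrt(math.log1p(config.intensity_cv**2))
    sigma_within = math.hypot(sigma_noise, config.between_patient_sd)
    effect_rows = []
    effect_shift = np.zeros((len(config.regions), n_total))  # log-scale shifts
    region_index = {r: i for i, r in enumerate(config.regions)}
    for ci, (ra, rb) in enumerate(contrasts):
        for j in range(config.n_discriminative_compounds):
            comp_idx = ci * config.n_discriminative_compounds + j
            direction = 1 if rng.random() < 0.5 else -1
            # +- d/2 sigma on each arm -> standardized difference = effect_size
            half = 0.5 * direction * config.effect_size * sigma_within
            effect_shift[region_index[ra], comp_idx] += half
            effect_shift[region_index[rb], comp_idx] -= half
            effect_rows.append(
                {
                    "compound_id": compounds[comp_idx].compound_id,
                    "region_a": ra,
                    "region_b": rb,
                    "direction": direction,
                    "effect_size": config.effect_size,
                }
            )

    baseline = rng.uniform(
        math.log(config.baseline_range[0]),
        math.log(config.baseline_range[1]),
        size=n_total,
    )
    patient_ids = [f"P{p+1}" for p in range(config.n_patients)]
    patient_effect = rng.normal(
        0.0, config.between_patient_sd, size=(config.n_patients, n_total)
    )

    metas: list[SampleMeta] = []
    log_intensity = []
    for p, pid in enumerate(patient_ids):
        for region in config.regions:
            for s in range(config.sites_per_region):
                metas.append(SampleMeta(pid, region, s + 1))
                mu = (
                    baseline
                    + patient_effect[p]
                    + effect_shift[region_index[region]]
                )
                log_intensity.append(mu + rng.normal(0.0, sigma_noise, size=n_total))
    log_intensity = np.array(log_intensity)  # (n_samples, n_total)
    intensity = np.exp(log_intensity)

    # missingness
    n_samples = len(metas)
    if config.missing_rate == 0:
        missing = np.zeros((n_samples, n_total), dtype=bool)
    elif config.missing_mechanism == "random":
        missing = rng.random((n_samples, n_total)) < config.missing_rate
    else:
        z = (log_intensity - log_intensity.mean()) / max(log_intensity.std(), 1e-12)
        weight = 1.0 / (1.0 + np.exp(z))  # low intensity -> high weight
        prob = np.clip(config.missing_rate * weight / weight.mean(), 0.0, 0.95)
        missing = rng.random((n_samples, n_total)) < prob

    # per-spectrum m/z jitter, then emit sorted validated spectra
    spectra: list[DepthProfileSpectrum] = []
    for i, meta in enumerate(metas):
        keep = ~missing[i]
        jitter = rng.normal(0.0, config.mass_jitter_ppm * 1e-6, size=n_total)
        mz = theo_mz * (1.0 + jitter)
        mz_i, int_i = mz[keep], intensity[i, keep]
        order = np.argsort(mz_i)
        spec = DepthProfileSpectrum(mz_i[order], int_i[order], meta)
        spec.validate(mz_range=None)
        spectra.append(spec)

    feature_order = np.argsort(theo_mz)
    assignments = pd.DataFrame(
        {
            "theoretical_mz": theo_mz[feature_order],
            "compound_id": [compounds[i].compound_id for i in feature_order],
            "adduct": [adducts[i].name for i in feature_order],
        }
    )
    missing_df = pd.DataFrame(
        missing[:, feature_order],
        index=[m.sample_id for m in metas],
        columns=[f"{m:.6f}" for m in theo_mz[feature_order]],
    )
    truth = SyntheticTruth(assignments, pd.DataFrame(effect_rows), missing_df)
    return spectra, truth, compounds


def sum_scans(
    scan_stack: list[tuple[np.ndarray, np.ndarray]] | list[DepthProfileSpectrum],
    meta: SampleMeta | None = None,
) -> DepthProfileSpectrum:
    """Sum a stack of per-scan peak lists into one depth-profile spectrum.

    Intensities are summed per identical m/z key; the result has one peak
    per distinct m/z across the stack.
    """
    if not scan_stack:
        raise DataError("cannot sum an empty scan stack")
    mzs, ints = [], []
    for scan in scan_stack:
        if isinstance(scan, DepthProfileSpectrum):
            if meta is None:
                meta = scan.meta
            mzs.append(scan.mz)
            ints.append(scan.intensity)
        else:
            m, i = scan
            mzs.append(np.asarray(m, dtype=float))
            ints.append(np.asarray(i, dtype=float))
    if meta is None:
        raise DataError("meta is required when summing bare peak lists")
    mz_all = np.concatenate(mzs)
    int_all = np.concatenate(ints)
    uniq, inverse = np.unique(mz_all, return_inverse=True)
    summed = np.zeros_like(uniq)
    np.add.at(summed, inverse, int_all)
    spec = DepthProfileSpectrum(uniq, summed, meta)
    spec.validate(mz_range=None)
    return spec


def write_cohort(
    spectra: list[DepthProfileSpectrum],
    truth: SyntheticTruth,
    compounds: list[CompoundRecord],
    outdir: str | Path,
) -> None:
    """Write a cohort in the pipeline's exchange formats (peak lists + tables)."""
    from .io import write_peaklist, write_sample_table

    outdir = Path(outdir)
    (outdir / "peaklists").mkdir(parents=True, exist_ok=True)
    for spec in spectra:
        write_peaklist(spec, outdir / "peaklists" / f"{spec.meta.sample_id}.tsv")
    write_sample_table([s.meta for s in spectra], outdir / "samples.tsv")
    write_compound_table(compounds, outdir / "compounds.tsv")
    truth.write(outdir)
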