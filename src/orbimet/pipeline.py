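"""End-to-end orchestration: simulate/load -> preprocess -> model -> stats
-> annotate -> pathways, with checkpointed intermediates and a run manifest.

A single global seed fans out to per-stage seeds (SHA-256 of
``"{seed}:{stage}"``), so each stage is independently reproducible and the
whole run is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .annotation import annotate, hits_to_frame
from .chemometrics import fit_oplsda, fit_pca, permutation_test
from .containers import REGIONS, CompoundRecord, DataError, DepthProfileSpectrum
from .io import (
    bundled_compound_table,
    bundled_pathway_table,
    read_compound_table,
    read_peaklist,
    read_sample_table,
)
from .pathways import load_pathways, ubiquitous_pathway_report
from .preprocess import preprocess
from .stats import feature_stats_table
from .synthetic import SyntheticConfig, write_cohort, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "load_cohort_dir"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis, at their workflow defaults:
    0.1% peak threshold, 5 ppm alignment, 20% missing cutoff, k=5 imputation,
    VIP >= 1, alpha 0.05, 5 ppm annotation, 2 ppm pathway mapping."""

    # preprocessing
    threshold_fraction: float = 0.001
    window_ppm: float = 5.0
    max_missing_fraction: float = 0.20
    knn_k: int = 5
    background_blacklist: tuple[float, ...] = ()
    background_tolerance_ppm: float = 5.0
    # modelling
    contrast: tuple[str, str] = ("necrotic", "viable")
    n_orthogonal: int = 1
    n_permutations: int = 999
    pca_components: int = 2
    # feature selection
    vip_threshold: float = 1.0
    alpha: float = 0.05
    ubiquitous_predicate: str = "high_vip"
    # annotation / pathways
    annotation_tolerance_ppm: float = 5.0
    pathway_tolerance_ppm: float = 2.0
    # inputs
    compound_table: str | None = None  # defaults to the bundled library
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def validate(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise DataError("threshold_fraction must be in (0, 1)")
        for name in ("window_ppm", "background_tolerance_ppm",
                     "annotation_tolerance_ppm", "pathway_tolerance_ppm"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be > 0")
        if not 0 <= self.max_missing_fraction <= 1:
            raise DataError("max_missing_fraction must be in [0, 1]")
        if self.knn_k < 1:
            raise DataError("knn_k must be >= 1")
        if self.n_orthogonal < 0:
            raise DataError("n_orthogonal must be >= 0")
        if self.n_permutations < 1:
            raise DataError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise DataError("alpha must be in (0, 1)")
        if len(self.contrast) != 2 or any(r not in REGIONS for r in self.contrast):
            raise DataError(f"contrast must be two of {REGIONS}")
        self.synthetic.validate()

    # -- (de)serialization ----------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn_raw = raw.pop("synthetic", {})
        for key in ("regions", "mz_range", "baseline_range"):
            if key in syn_raw:
                syn_raw[key] = tuple(syn_raw[key])
        syn = SyntheticConfig(**syn_raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw, synthetic=syn)
        if isinstance(cfg.contrast, list):
            cfg.contrast = tuple(cfg.contrast)
        if isinstance(cfg.background_blacklist, list):
            cfg.background_blacklist = tuple(cfg.background_blacklist)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrast"] = list(self.contrast)
        d["background_blacklist"] = list(self.background_blacklist)
        d["synthetic"]["regions"] = list(self.synthetic.regions)
        d["synthetic"]["mz_range"] = list(self.synthetic.mz_range)
        d["synthetic"]["baseline_range"] = list(self.synthetic.baseline_range)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_cohort_dir(indir: str | Path) -> tuple[list[DepthProfileSpectrum], list[CompoundRecord] | None]:
    """Load a cohort written in the exchange layout (samples.tsv + peaklists/)."""
    indir = Path(indir)
    metas = read_sample_table(indir / "samples.tsv")
    spectra = [
        read_peaklist(indir / "peaklists" / f"{m.sample_id}.tsv", m) for m in metas
    ]
    compounds = None
    if (indir / "compounds.tsv").exists():
        compounds = read_compound_table(indir / "compounds.tsv")
    return spectra, compounds


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    spectra: list[DepthProfileSpectrum] | None = None,
    compounds: list[CompoundRecord] | None = None,
) -> Path:
    """Execute the full analysis; returns the run directory.

    Without input ``spectra`` a synthetic cohort is generated from
    ``config.synthetic`` (with a stage-derived seed) and written alongside
    the results.  Every stage writes its checkpoint; a ``manifest.json``
    records parameters, package version and SHA-256 hashes of all outputs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .io import write_feature_matrix  # local to keep module import light

    simulated = spectra is None
    if simulated:
        syn = dataclasses.replace(config.synthetic, seed=stage_seed(config.seed, "simulate"))
        spectra, truth, compounds = generate_cohort(syn)
        write_cohort(spectra, truth, compounds, outdir / "cohort")
        logger.info("simulated cohort: %d spectra", len(spectra))
    if compounds is None:
        compounds = (
            read_compound_table(config.compound_table)
            if config.compound_table
            else bundled_compound_table()
        )

    # --- preprocess ----------------------------------------------------
    result = preprocess(
        spectra,
        threshold_fraction=config.threshold_fraction,
        window_ppm=config.window_ppm,
        max_missing_fraction=config.max_missing_fraction,
        k=config.knn_k,
        background_blacklist=config.background_blacklist,
        background_tolerance_ppm=config.background_tolerance_ppm,
    )
    checkpoints = outdir / "checkpoints"
    checkpoints.mkdir(exist_ok=True)
    for name in ("filtered", "imputed", "tic", "scaled"):
        write_feature_matrix(getattr(result, name), checkpoints / f"{name}.csv")

    # --- modelling ------------------------------------------------------
    regions = result.tic.regions()
    in_contrast = np.isin(regions, config.contrast)
    if in_contrast.sum() < 6:
        raise DataError(
            f"contrast {config.contrast} selects only {int(in_contrast.sum())} samples"
        )
    tic_sub = result.tic.take_samples(np.flatnonzero(in_contrast))
    labels = tic_sub.regions()
    # order labels so the first contrast region is the +1 class
    order = np.argsort(labels != config.contrast[0], kind="stable")
    tic_sub = tic_sub.take_samples(order)
    labels = tic_sub.regions()

    model = fit_oplsda(tic_sub, labels, n_orthogonal=config.n_orthogonal, scale="pareto")
    null_q2, observed_q2, perm_p = permutation_test(
        tic_sub,
        labels,
        n_permutations=config.n_permutations,
        seed=stage_seed(config.seed, "permutation"),
        n_orthogonal=config.n_orthogonal,
        scale="pareto",
    )
    model.permutation_Q2 = null_q2
    model.permutation_p = perm_p
    pca = fit_pca(result.scaled, n_components=config.pca_components)

    modeldir = outdir / "model"
    modeldir.mkdir(exist_ok=True)
    _write_tsv(modeldir / "scores.tsv",
               {"sample_id": tic_sub.sample_ids, "region": labels,
                "t_predictive": model.predictive_scores,
                **{f"t_orth{a+1}": model.orthogonal_scores[:, a]
                   for a in range(model.n_orthogonal)}})
    _write_tsv(modeldir / "loadings.tsv",
               {"feature_mz": tic_sub.feature_centroids,
                "w_predictive": model.predictive_weights,
                "p_predictive": model.predictive_loadings,
                "vip": model.vip,
                "splot_cov": model.splot_cov,
                "splot_corr": model.splot_corr})
    summary = {
        "opls_da": {
            "classes": list(model.classes),
            "n_orthogonal": model.n_orthogonal,
            "R2X": model.R2X,
            "R2Y": model.R2Y,
            "Q2": model.Q2,
            "permutation_p": perm_p,
            "n_permutations": config.n_permutations,
        },
        "pca": {
            "n_components": int(pca.scores.shape[1]),
            "R2X_cumulative": pca.explained_R2X.tolist(),
            "Q2": pca.Q2,
        },
    }
    (modeldir / "summary.json").write_text(json.dumps(summary, indent=2))

    # --- univariate stats ----------------------------------------------
    table = feature_stats_table(
        tic_sub,
        model,
        labels,
        vip_threshold=config.vip_threshold,
        alpha=config.alpha,
        ubiquitous_predicate=config.ubiquitous_predicate,
    )
    table.to_csv(outdir / "feature_stats.tsv", sep="\t", index=False)

    # --- annotation -----------------------------------------------------
    hits = annotate(
        result.tic.feature_centroids,
        compounds,
        tolerance_ppm=config.annotation_tolerance_ppm,
    )
    hits_to_frame(hits).to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    # --- pathways -------------------------------------------------------
    pathway_defs = load_pathways(bundled_pathway_table())
    ubiquitous_mz = table.loc[table["ubiquitous"], "feature_mz"].to_numpy()
    mean_cols = [c for c in table.columns if c.startswith("mean_")]
    region_means = table.set_index("feature_mz")[mean_cols]
    coverage, members = ubiquitous_pathway_report(
        ubiquitous_mz, hits, pathway_defs,
        tolerance_ppm=config.pathway_tolerance_ppm,
        region_means=region_means,
    )
    members.to_csv(outdir / "pathway_members.tsv", sep="\t", index=False)
    _write_tsv(outdir / "pathway_coverage.tsv",
               {"pathway_id": [r.pathway_id for r in coverage],
                "pathway_name": [r.name for r in coverage],
                "n_matched": [len(r.matched_members) for r in coverage],
                "coverage": [r.coverage for r in coverage]})
    (outdir / "pathway_report.json").write_text(json.dumps(
        [{"pathway_id": r.pathway_id, "pathway_name": r.name,
          "matched_members": r.matched_members, "coverage": r.coverage}
         for r in coverage], indent=2))

    # --- manifest -------------------------------------------------------
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package": "orbimet",
        "version": __version__,
        "seed": config.seed,
        "simulated_input": simulated,
        "parameters": config.to_dict(),
        "n_samples": len(spectra),
        "n_features": int(result.tic.n_features),
        "results": {
            "oplsda_Q2": model.Q2,
            "permutation_p": perm_p,
            "n_discriminative": int(table["discriminative"].sum()),
            "n_ubiquitous": int(table["ubiquitous"].sum()),
            "n_annotated_features": int(hits_to_frame(hits)["feature_mz"].nunique()),
        },
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _write_tsv(path: Path, columns: dict) -> None:
    import pandas as pd

    pd.DataFrame(columns).to_csv(path, sep="\t", index=False)
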