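"""Readers and writers for the pipeline's plain-text exchange formats.

Formats
-------
peak list        two numeric columns (m/z, intensity), TSV or CSV, optional
                 header — the shape of a SurfaceLab depth-profile .TXT export
metadata         TSV: sample_id, patient_id, region, site
compound table   TSV: compound_id, name, formula[, monoisotopic_mass]
pathway table    TSV: pathway_id, pathway_name, compound_id[, formula]
feature matrix   CSV, one header row of feature centroid m/z; missing cells
                 are written as *empty fields*, never zeros — "not detected"
                 is distinct from a measured zero until imputation.
"""

from __future__ import annotations

import csv
import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CompoundRecord,
    DataError,
    DepthProfileSpectrum,
    FeatureMatrix,
    ParseError,
    SampleMeta,
)

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "read_sample_table",
    "write_sample_table",
    "read_compound_table",
    "write_compound_table",
    "read_pathway_table",
    "read_feature_matrix",
    "write_feature_matrix",
    "bundled_compound_table",
    "bundled_pathway_table",
]


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_peaklist(path: str | Path, meta: SampleMeta) -> DepthProfileSpectrum:
    """Read a two-column (m/z, intensity) text file into a validated spectrum.

    Rows are sorted ascending by m/z and duplicate m/z rows are summed.
    A single header line is tolerated; any other non-numeric row is an error.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    mz: list[float] = []
    inten: list[float] = []
    delim = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delim is None:
            delim = _sniff_delimiter(line)
        parts = [p for p in line.split(delim) if p != ""]
        try:
            m, i = float(parts[0]), float(parts[1])
        except (ValueError, IndexError):
            if lineno == 1:  # header row
                continue
            raise ParseError(f"{path}:{lineno}: expected two numeric columns, got {raw!r}")
        if i < 0:
            raise ParseError(f"{path}:{lineno}: negative intensity {i}")
        mz.append(m)
        inten.append(i)
    if not mz:
        raise ParseError(f"{path}: no peaks found")
    mz_arr = np.array(mz)
    int_arr = np.array(inten)
    order = np.argsort(mz_arr, kind="stable")
    mz_arr, int_arr = mz_arr[order], int_arr[order]
    # sum duplicate m/z keys
    uniq, inverse = np.unique(mz_arr, return_inverse=True)
    summed = np.zeros_like(uniq)
    np.add.at(summed, inverse, int_arr)
    spec = DepthProfileSpectrum(uniq, summed, meta)
    spec.validate(mz_range=None)
    return spec


def write_peaklist(spectrum: DepthProfileSpectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("mz\tintensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{float(m)!r}\t{float(i)!r}\n")


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "region", "site"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: metadata table needs columns {sorted(required)}")
    return [
        SampleMeta(row.patient_id, row.region, int(row.site))
        for row in df.itertuples()
    ]


def write_sample_table(meta: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "patient_id": [m.patient_id for m in meta],
            "region": [m.region for m in meta],
            "site": [m.site_index for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Read a compound TSV; missing masses are computed from the formula and
    provided masses are validated against it (1e-3 Da)."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "name": str, "formula": str})
    required = {"compound_id", "name", "formula"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: compound table needs columns {sorted(required)}")
    records: list[CompoundRecord] = []
    for row in df.itertuples():
        try:
            if "monoisotopic_mass" in df.columns and np.isfinite(row.monoisotopic_mass):
                rec = CompoundRecord(
                    row.compound_id, row.name, row.formula, float(row.monoisotopic_mass)
                )
                rec.check_mass()
            else:
                rec = CompoundRecord.from_formula(row.compound_id, row.name, row.formula)
        except ValueError as exc:
            raise ParseError(f"compound {row.compound_id} ({row.name}): {exc}") from exc
        records.append(rec)
    return records


def write_compound_table(records: list[CompoundRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "name": [r.name for r in records],
            "formula": [r.formula for r in records],
            "monoisotopic_mass": [r.monoisotopic_mass for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.7f")


def read_pathway_table(path: str | Path) -> pd.DataFrame:
    """Pathway membership: one row per (pathway, compound)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pathway_id", "pathway_name", "compound_id"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: pathway table needs columns {sorted(required)}")
    return df


# ---------------------------------------------------------------------------
# feature matrix CSV


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    matrix.validate()
    all_missing = matrix.missing_mask.all(axis=0)
    if all_missing.any():
        bad = matrix.feature_centroids[all_missing]
        raise DataError(f"refusing to write all-missing feature columns at m/z {bad}")
    path = Path(path)
    with path.open("w", newline="") as fh:
        if matrix.transform_log:
            fh.write("# transforms: " + ";".join(matrix.transform_log) + "\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["sample_id", "patient_id", "region", "site"]
            + [repr(float(c)) for c in matrix.feature_centroids]
        )
        for i, meta in enumerate(matrix.sample_meta):
            row: list[str] = [matrix.sample_ids[i], meta.patient_id, meta.region, str(meta.site_index)]
            for j in range(matrix.n_features):
                row.append(
                    "" if matrix.missing_mask[i, j] else repr(float(matrix.values[i, j]))
                )
            writer.writerow(row)


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    transform_log: list[str] = []
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# transforms:"):
            logged = first.split(":", 1)[1].strip()
            transform_log = logged.split(";") if logged else []
            header_line = fh.readline()
        else:
            header_line = first
        reader = csv.reader([header_line] + fh.readlines())
        rows = list(reader)
    header = rows[0]
    if header[:4] != ["sample_id", "patient_id", "region", "site"]:
        raise ParseError(f"{path}: unexpected feature-matrix header {header[:4]}")
    centroids = np.array([float(c) for c in header[4:]])
    ids, metas, vals, mask = [], [], [], []
    for row in rows[1:]:
        if len(row) != len(header):
            raise ParseError(f"{path}: row for {row[0]!r} has {len(row)} fields, expected {len(header)}")
        ids.append(row[0])
        metas.append(SampleMeta(row[1], row[2], int(row[3])))
        vals.append([np.nan if cell == "" else float(cell) for cell in row[4:]])
        mask.append([cell == "" for cell in row[4:]])
    matrix = FeatureMatrix(
        ids, metas, centroids, np.array(vals, dtype=float), np.array(mask), transform_log
    )
    matrix.validate()
    return matrix


# ---------------------------------------------------------------------------
# bundled reference tables


def _data_path(name: str):
    return importlib.resources.files("orbimet").joinpath("data", name)


def bundled_compound_table() -> list[CompoundRecord]:
    """The packaged small-molecule library (~200 metabolite formulae)."""
    with importlib.resources.as_file(_data_path("compounds.tsv")) as p:
        return read_compound_table(p)


def bundled_pathway_table() -> pd.DataFrame:
    """The packaged pathway-membership table (4 metabolic pathways)."""
    with importlib.resources.as_file(_data_path("pathways.tsv")) as p:
        return read_pathway_table(p)
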