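"""Delimited-text readers and writers for the pipeline's tables.

All formats are plain text with headers: chromatograms as two-column TSV
(rt, intensity), MRM transition tables as CSV (precursor_mz, product_mz,
intensity), and the study manifest as YAML listing per-sample file paths
and truth labels.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .chromatogram import Chromatogram

__all__ = [
    "read_chromatogram",
    "write_chromatogram",
    "read_transitions",
    "write_transitions",
    "write_study",
]


def read_chromatogram(path: str | Path, sample_id: str | None = None) -> Chromatogram:
    df = pd.read_csv(path, sep="\t")
    if not {"rt", "intensity"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'rt' and 'intensity'")
    return Chromatogram(
        rt=df["rt"].to_numpy(float),
        intensity=df["intensity"].to_numpy(float),
        sample_id=sample_id if sample_id is not None else Path(path).stem,
    )


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"rt": chrom.rt, "intensity": chrom.intensity}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_transitions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"precursor_mz", "product_mz", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if "sample_id" in df.columns:
        df["sample_id"] = df["sample_id"].fillna("").astype(str)
    return df


def write_transitions(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_study(study, outdir: str | Path) -> Path:
    """Write a simulated study to ``outdir`` and return the manifest path.

    Layout: one chromatogram TSV and one MRM CSV per sample, shared CSVs
    for the molecular tables, and ``manifest.yaml`` tying sample ids to
    files and ground-truth labels.
    """
    outdir = Path(outdir)
    (outdir / "chromatograms").mkdir(parents=True, exist_ok=True)
    (outdir / "mrm").mkdir(exist_ok=True)

    entries = []
    for sid in study.samples["sample_id"]:
        cpath = outdir / "chromatograms" / f"{sid}.tsv"
        mpath = outdir / "mrm" / f"{sid}.csv"
        write_chromatogram(study.chromatograms[sid], cpath)
        write_transitions(study.mrm_runs[sid], mpath)
        truth = study.truths[sid]
        entries.append(
            {
                "sample_id": sid,
                "chromatogram": str(cpath.relative_to(outdir)),
                "mrm": str(mpath.relative_to(outdir)),
                "truth": {
                    "degradation_degree": int(truth.degradation_degree),
                    "planted_alkylcom": sorted(truth.planted_alkylcom_chain_lengths),
                    "true_16s_copies_per_g": float(truth.true_16s_copies_per_g),
                    "true_relabund": float(truth.true_relabund),
                    "true_fpkm": {k: float(v) for k, v in truth.true_fpkm.items()},
                },
            }
        )

    study.samples.to_csv(outdir / "samples.csv", index=False)
    study.qpcr.to_csv(outdir / "qpcr.csv", index=False)
    study.feature_counts.to_csv(outdir / "feature_counts.csv", index_label="sample_id")
    study.mag_counts.to_csv(outdir / "mag_counts.csv", index_label="sample_id")
    study.mag_lengths.to_csv(outdir / "mag_lengths.csv", index_label="mag")
    study.gene_counts.to_csv(outdir / "gene_counts.csv", index_label="sample_id")
    study.gene_lengths.to_csv(outdir / "gene_lengths.csv", index_label="gene")
    study.total_mapped.to_csv(outdir / "total_mapped.csv", index_label="sample_id")

    manifest = outdir / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump(
            {
                "n_samples": len(study),
                "target_features": list(study.target_features),
                "samples": entries,
            },
            fh, sort_keys=False,
        )
    return manifest
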