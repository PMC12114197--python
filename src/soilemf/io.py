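"""Reading and writing the pipeline's on-disk formats.

Count tables are TSV with the taxon id in the first column, one column per
sample, and an optional trailing ``taxonomy`` column; indicator matrices are
CSV with plot ids in the first column and one column per indicator;
metadata is a two-column ``sample,treatment`` CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .containers import AbundanceTable, validate_indicator_matrix
from .synthetic import ExperimentDesign, SyntheticDataset


def read_indicator_csv(path) -> pd.DataFrame:
    x = pd.read_csv(path, index_col=0)
    return validate_indicator_matrix(x)


def write_indicator_csv(x: pd.DataFrame, path) -> None:
    x.to_csv(path, index_label="plot")


def read_metadata_csv(path) -> pd.Series:
    meta = pd.read_csv(path)
    if not {"sample", "treatment"} <= set(meta.columns):
        raise ValueError("metadata CSV needs 'sample' and 'treatment' columns")
    return meta.set_index("sample")["treatment"]


def write_metadata_csv(metadata: pd.Series, path) -> None:
    metadata.rename("treatment").rename_axis("sample").to_csv(path)


def read_abundance_tsv(
    path,
    kingdom: str = "bacteria",
    metadata: pd.Series | None = None,
    orientation: str = "auto",
) -> AbundanceTable:
    """Parse a count TSV into an :class:`AbundanceTable`.

    ``orientation`` is ``taxa_by_samples`` (the format this package writes),
    ``samples_by_taxa``, or ``auto``. Auto-detection matches row/column ids
    against ``metadata`` sample ids; without metadata, the written
    orientation (taxa x samples) is assumed.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy = None
    if "taxonomy" in raw.columns:
        taxonomy = raw["taxonomy"].to_dict()
        raw = raw.drop(columns="taxonomy")
    raw = raw.apply(pd.to_numeric)

    if orientation == "auto":
        if metadata is None:
            orientation = "taxa_by_samples"
        else:
            samples = set(metadata.index)
            cols_match = set(raw.columns) <= samples
            rows_match = set(raw.index) <= samples
            if cols_match == rows_match:
                raise ValueError(
                    "ambiguous count-table orientation; pass orientation="
                    "'taxa_by_samples' or 'samples_by_taxa'"
                )
            orientation = "taxa_by_samples" if cols_match else "samples_by_taxa"
    if orientation == "taxa_by_samples":
        counts = raw.T
    elif orientation == "samples_by_taxa":
        counts = raw
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    counts.index.name = "sample"
    counts.columns.name = None
    return AbundanceTable(counts, kingdom=kingdom, taxonomy=taxonomy)


def write_abundance_tsv(table: AbundanceTable, path) -> None:
    """Write taxa x samples TSV with an optional taxonomy column."""
    out = table.counts.T.rename_axis("taxon")
    if table.taxonomy is not None:
        out = out.assign(taxonomy=[table.taxonomy.get(t, "") for t in out.index])
    out.to_csv(path, sep="\t")


def _design_echo(design: ExperimentDesign) -> dict:
    return {
        "seed": design.seed,
        "treatment_labels": list(design.treatment_labels),
        "replicates": design.replicates,
        "sequencing_depth": design.sequencing_depth,
        "taxa_counts": dict(design.taxa_counts),
        "indicators": list(design.indicator_baselines),
        "blocks": {
            k: [
                {"size": b.size, "sign": b.sign, "magnitude": b.magnitude}
                for b in blocks
            ]
            for k, blocks in design.blocks.items()
        },
    }


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write a synthetic dataset: indicator CSV, count TSVs, metadata CSV,
    and a YAML sidecar echoing the design and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "indicators": outdir / "indicators.csv",
        "bacteria": outdir / "bacteria_counts.tsv",
        "fungi": outdir / "fungi_counts.tsv",
        "metadata": outdir / "metadata.csv",
        "design": outdir / "design.yaml",
    }
    write_indicator_csv(dataset.indicators, paths["indicators"])
    write_abundance_tsv(dataset.bacteria, paths["bacteria"])
    write_abundance_tsv(dataset.fungi, paths["fungi"])
    write_metadata_csv(dataset.metadata, paths["metadata"])
    with open(paths["design"], "w") as fh:
        yaml.safe_dump(_design_echo(dataset.truth), fh, sort_keys=True)
    return paths


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
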