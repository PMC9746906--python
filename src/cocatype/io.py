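"""Readers and writers for the pipeline's plain-text interchange formats.

All matrices travel as TSV with the feature id in the first column and
sample ids in the header; mutation records travel as a MAF-like TSV; gene
sets as GMT; configs as YAML; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

MAF_COLUMNS = {
    "sample": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chromosome": "Chromosome",
    "position": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "context": "context",
}


def _provenance_line(provenance: dict | None) -> str:
    if not provenance:
        return ""
    fields = " ".join(f"{k}={v}" for k, v in provenance.items())
    return f"# {fields}\n"


def write_matrix_tsv(
    matrix: pd.DataFrame,
    path: str | Path,
    feature_name: str = "feature",
    provenance: dict | None = None,
) -> None:
    Path(path).write_text(
        _provenance_line(provenance) + matrix.rename_axis(feature_name).to_csv(sep="\t")
    )


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_maf(records: pd.DataFrame, path: str | Path) -> None:
    records.rename(columns=MAF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_maf(path: str | Path) -> pd.DataFrame:
    inverse = {v: k for k, v in MAF_COLUMNS.items()}
    df = pd.read_csv(path, sep="\t", dtype={"Reference_Allele": str, "Tumor_Seq_Allele2": str})
    return df.rename(columns=inverse)[list(MAF_COLUMNS)]


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_assignment(labels: pd.Series, path: str | Path, provenance: dict | None = None) -> None:
    body = pd.DataFrame({"sample": labels.index, "label": labels.values}).to_csv(
        sep="\t", index=False
    )
    Path(path).write_text(_provenance_line(provenance) + body)


def read_assignment(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#")
    return pd.Series(df["label"].values, index=df["sample"].values, name="label")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [f"{name}\t.\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
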