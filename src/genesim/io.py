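"""Flat-file readers/writers for annotations, labels and similarity matrices.

Annotations come either as GAF 2.x (column 2 = gene symbol, column 5 = GO
term id, column 9 = aspect, keeping aspect ``P`` for biological process) or
as a plain two-column TSV ``gene<TAB>term``.  Labels are a two-column TSV
``gene<TAB>ASD|Non-ASD``.  Similarity matrices travel as CSV with gene ids
as the first row and column.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Dict, Set

import numpy as np
import pandas as pd

from .resampling import LabeledDataset
from .semsim import SimilarityMatrix

POSITIVE_TOKEN = "ASD"
NEGATIVE_TOKEN = "Non-ASD"


def read_annotations(path, fmt: str = "tsv") -> Dict[str, Set[str]]:
    """Gene -> term-id set, preserving first-seen gene order."""
    annotations: "OrderedDict[str, Set[str]]" = OrderedDict()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            cols = line.split("\t")
            if fmt == "gaf":
                if len(cols) < 9:
                    continue
                gene, term, aspect = cols[1], cols[4], cols[8]
                if aspect != "P":
                    continue
            elif fmt == "tsv":
                if len(cols) < 2:
                    continue
                gene, term = cols[0], cols[1]
            else:
                raise ValueError(f"unknown annotation format {fmt!r}")
            annotations.setdefault(gene, set()).add(term)
    return annotations


def write_annotations(annotations: Dict[str, Set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene, terms in annotations.items():
            for term in sorted(terms):
                fh.write(f"{gene}\t{term}\n")


def read_labels(path) -> Dict[str, int]:
    """Gene -> 1 (positive token) or 0."""
    labels: Dict[str, int] = OrderedDict()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, token = line.split("\t")[:2]
            labels[gene] = 1 if token == POSITIVE_TOKEN else 0
    return labels


def write_labels(labels: Dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for gene, lab in labels.items():
            token = POSITIVE_TOKEN if lab == 1 else NEGATIVE_TOKEN
            fh.write(f"{gene}\t{token}\n")


def write_matrix(matrix: SimilarityMatrix, path) -> None:
    matrix.to_dataframe().round(6).to_csv(path, float_format="%.6f")


def read_matrix(path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return SimilarityMatrix(gene_ids=[str(g) for g in df.index], values=df.values)


def dataset_from_matrix(
    matrix: SimilarityMatrix, labels: Dict[str, int]
) -> LabeledDataset:
    """Pair a similarity matrix's rows with labels, matrix row order."""
    missing = [g for g in matrix.gene_ids if g not in labels]
    if missing:
        raise ValueError("genes without labels: " + ", ".join(missing[:10]))
    y = np.array([labels[g] for g in matrix.gene_ids], dtype=int)
    return LabeledDataset(
        features=matrix.values, labels=y, sample_ids=list(matrix.gene_ids)
    )


def write_dataset(data: LabeledDataset, feature_names, path) -> None:
    """Dataset (e.g. after resampling) as CSV with label/synthetic columns."""
    df = pd.DataFrame(data.features, index=data.sample_ids, columns=list(feature_names))
    df["label"] = [POSITIVE_TOKEN if l == 1 else NEGATIVE_TOKEN for l in data.labels]
    df["synthetic"] = data.synthetic.astype(int)
    df.to_csv(path)


def read_dataset(path) -> LabeledDataset:
    df = pd.read_csv(path, index_col=0)
    labels = (df.pop("label") == POSITIVE_TOKEN).astype(int).values
    synthetic = df.pop("synthetic").astype(bool).values if "synthetic" in df else None
    return LabeledDataset(
        features=df.values,
        labels=labels,
        sample_ids=[str(i) for i in df.index],
        synthetic=synthetic,
    )
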