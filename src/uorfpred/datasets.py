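"""Label training/testing sets from differential-expression tables.

Training labels come from paired RNA-seq / Ribo-seq contrasts (stress vs
control): a gene qualifies when its total-RNA change is negligible
(-0.2 < log2FC < 0.2) while its ribosome-bound RNA changes significantly
(|log2FC| > 0.2, FDR < 0.05); the Ribo-seq sign gives the label
(up-regulated under stress = positive).

Testing labels come from translation-efficiency (TE) contrasts of a
phosphorylation-deficient eIF2alpha mutant against wild type: among genes
with padj < 0.05, TE log2FC < -0.2 marks a positive (translation would be
enhanced when eIF2alpha can be phosphorylated) and TE log2FC > 0.2 a
negative.  All inequalities are strict; boundary values are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"

RNA_DEADZONE = 0.2     # |RNA-seq log2FC| must stay strictly below this
RIBO_EFFECT = 0.2      # |Ribo-seq or TE log2FC| must strictly exceed this
SIGNIFICANCE = 0.05    # FDR / padj must stay strictly below this

TRAINING_COLUMNS = {
    "gene_id": "gene_id",
    "rnaseq_log2fc": "rnaseq_log2fc",
    "riboseq_log2fc": "riboseq_log2fc",
    "riboseq_fdr": "riboseq_fdr",
}
TESTING_COLUMNS = {
    "gene_id": "gene_id",
    "te_log2fc": "te_log2fc",
    "te_padj": "te_padj",
}


@dataclass(frozen=True)
class ExpressionRow:
    gene_id: str
    rnaseq_log2fc: float
    riboseq_log2fc: float
    riboseq_fdr: float


@dataclass(frozen=True)
class TERow:
    gene_id: str
    te_log2fc: float
    te_padj: float


class DuplicateGeneError(ValueError):
    """A gene identifier appears more than once in the input table."""


def _as_frame(
    rows: Iterable, columns: Mapping[str, str], fields: Sequence[str]
) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        df = rows.rename(columns={v: k for k, v in columns.items()})
    else:
        df = pd.DataFrame([
            {f: getattr(r, f) for f in fields} for r in rows
        ], columns=list(fields))
    missing = set(fields) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if len(dupes):
        raise DuplicateGeneError(f"duplicate gene_id: {dupes.iloc[0]!r}")
    return df


def label_training(
    rows: Iterable[ExpressionRow] | pd.DataFrame,
    columns: Mapping[str, str] = TRAINING_COLUMNS,
) -> pd.DataFrame:
    """Filter and label the training source.

    Keeps genes with -0.2 < RNA-seq log2FC < 0.2, Ribo-seq |log2FC| > 0.2
    and Ribo-seq FDR < 0.05 (all strict); the Ribo-seq sign sets the
    label.  Returns a DataFrame with columns ``gene_id``, ``label``.
    """
    df = _as_frame(rows, columns, list(TRAINING_COLUMNS))
    rna_quiet = (df["rnaseq_log2fc"] > -RNA_DEADZONE) & (
        df["rnaseq_log2fc"] < RNA_DEADZONE
    )
    ribo_moves = (df["riboseq_log2fc"] < -RIBO_EFFECT) | (
        df["riboseq_log2fc"] > RIBO_EFFECT
    )
    significant = df["riboseq_fdr"] < SIGNIFICANCE
    kept = df[rna_quiet & ribo_moves & significant]
    label = np.where(kept["riboseq_log2fc"] > RIBO_EFFECT, POSITIVE, NEGATIVE)
    return pd.DataFrame(
        {"gene_id": kept["gene_id"].to_numpy(), "label": label}
    )


def label_testing(
    rows: Iterable[TERow] | pd.DataFrame,
    columns: Mapping[str, str] = TESTING_COLUMNS,
) -> pd.DataFrame:
    """Filter and label the testing source.

    Keeps genes with padj < 0.05; TE log2FC < -0.2 (mutant vs wild type)
    labels a positive, > 0.2 a negative; the dead zone in between is
    dropped.  Returns a DataFrame with columns ``gene_id``, ``label``.
    """
    df = _as_frame(rows, columns, list(TESTING_COLUMNS))
    significant = df["te_padj"] < SIGNIFICANCE
    pos = significant & (df["te_log2fc"] < -RIBO_EFFECT)
    neg = significant & (df["te_log2fc"] > RIBO_EFFECT)
    kept = df[pos | neg]
    label = np.where(kept["te_log2fc"] < -RIBO_EFFECT, POSITIVE, NEGATIVE)
    return pd.DataFrame(
        {"gene_id": kept["gene_id"].to_numpy(), "label": label}
    )


def dedup(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove from the training set every gene also present in the test set.

    Returns the pruned training set and the 2x2 concordance table of
    (train label x test label) over the shared identifiers — rows indexed
    by the training label, columns by the testing label, order
    positive/negative.  The pruned training set shares no id with test.
    """
    shared = set(train["gene_id"]) & set(test["gene_id"])
    pruned = train[~train["gene_id"].isin(shared)].reset_index(drop=True)
    order = [POSITIVE, NEGATIVE]
    table = pd.DataFrame(0, index=order, columns=order)
    train_labels = dict(zip(train["gene_id"], train["label"]))
    test_labels = dict(zip(test["gene_id"], test["label"]))
    for g in shared:
        table.loc[train_labels[g], test_labels[g]] += 1
    table.index.name = "train"
    table.columns.name = "test"
    return pruned, table
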