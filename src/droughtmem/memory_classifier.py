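"""The drought stress-memory transcript taxonomy.

Over the four sampled states (WT1 watered control, DR1 first drought, WT2
re-watered recovery, DR2 second drought), transcripts are classified as
drought-induced (DIT) or drought-repressed (DRT) when their DR1/WT1
intensity ratio exceeds fourfold (or falls below a quarter) in BOTH
independent replicates. Memory transcripts are the already-responsive
subset changing more than fourfold again between the two droughts:
DIMT = DIT with DR2/DR1 > fold in both replicates, DRMT = DRT with
DR2/DR1 < 1/fold in both. Thresholds are strict inequalities ("more than
fourfold"). Recovery at WT2 is annotated separately and never filters
labels. Control rows (organellar genes, selection markers) are excluded
from memory labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import numpy as np
import pandas as pd

from droughtmem.preprocess_stats import ExpressionMatrix

LABELS = ("DIT", "DRT", "non-responsive")
MEMORY_LABELS = ("DIMT", "DRMT", "none")

# Strict thresholds are compared on the log2 scale with a small guard so a
# ratio sitting exactly on the fold boundary (up to float noise in the
# log2 round trip) is excluded, matching the strict "more than fourfold"
# reading.
_EPS_LOG2 = 1e-9


def _exceeds(lfc: np.ndarray, fold: float) -> np.ndarray:
    return lfc > np.log2(fold) + _EPS_LOG2


def _below(lfc: np.ndarray, fold: float) -> np.ndarray:
    return lfc < -np.log2(fold) - _EPS_LOG2


@dataclass
class MemoryClassification:
    """Per-transcript labels and fold changes.

    ``table`` columns: label, memory_label, fc_DR1_WT1_rep{1,2},
    fc_DR2_DR1_rep{1,2}, recovered_at_WT2 (filled by the respective
    steps).
    """

    table: pd.DataFrame
    fold: float
    control_rows: frozenset = frozenset()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="transcript_id")


def _replicate_lfc(
    m: ExpressionMatrix, num: str, den: str
) -> dict[int, np.ndarray]:
    """Per-replicate log2 fold changes num/den."""
    if m.scale != "log2":
        raise ValueError("classification expects a normalized log2 matrix")
    reps = sorted(set(m.sample_meta["replicate"]))
    return {
        r: m.column(num, r).to_numpy() - m.column(den, r).to_numpy()
        for r in reps
    }


def classify_response(m: ExpressionMatrix, fold: float = 4.0) -> MemoryClassification:
    """Label DIT / DRT / non-responsive from the first drought cycle.

    DIT requires DR1/WT1 > fold in both replicates; DRT requires
    DR1/WT1 < 1/fold in both; everything else is non-responsive.
    """
    m.require(("WT1", "DR1"))
    lfc = _replicate_lfc(m, "DR1", "WT1")
    up = np.logical_and.reduce([_exceeds(v, fold) for v in lfc.values()])
    down = np.logical_and.reduce([_below(v, fold) for v in lfc.values()])
    label = np.where(up, "DIT", np.where(down, "DRT", "non-responsive"))
    table = pd.DataFrame(index=m.values.index)
    table["label"] = label
    table["memory_label"] = "none"
    for r, v in lfc.items():
        table[f"fc_DR1_WT1_rep{r}"] = np.exp2(v)
    return MemoryClassification(table=table, fold=fold)


def classify_memory(
    c: MemoryClassification,
    m: ExpressionMatrix,
    fold: float | None = None,
    control_rows: Collection[str] = (),
    gate_on_response: bool = True,
) -> MemoryClassification:
    """Fill memory labels from the second drought cycle.

    DIMT = DIT whose DR2/DR1 ratio exceeds ``fold`` in both replicates;
    DRMT = DRT whose ratio falls below 1/fold in both. With
    ``gate_on_response=False`` the DR2-vs-DR1 screen is applied without
    requiring first-cycle responsiveness. Control rows never receive a
    memory label.
    """
    fold = c.fold if fold is None else fold
    m.require(("DR1", "DR2"))
    lfc = _replicate_lfc(m, "DR2", "DR1")
    up = np.logical_and.reduce([_exceeds(v, fold) for v in lfc.values()])
    down = np.logical_and.reduce([_below(v, fold) for v in lfc.values()])
    table = c.table.copy()
    is_dit = (table["label"] == "DIT").to_numpy()
    is_drt = (table["label"] == "DRT").to_numpy()
    if gate_on_response:
        dimt = up & is_dit
        drmt = down & is_drt
    else:
        dimt = up
        drmt = down
    is_control = table.index.isin(list(control_rows))
    memory = np.where(
        dimt & ~is_control, "DIMT", np.where(drmt & ~is_control, "DRMT", "none")
    )
    table["memory_label"] = memory
    for r, v in lfc.items():
        table[f"fc_DR2_DR1_rep{r}"] = np.exp2(v)
    return MemoryClassification(
        table=table, fold=c.fold, control_rows=frozenset(control_rows)
    )


def recovery_flag(
    m: ExpressionMatrix, tolerance_fold: float = 2.0
) -> pd.Series:
    """True where the WT2/WT1 ratio lies within [1/tol, tol] in both
    replicates — an annotation of recovery to pre-stress levels, never a
    label filter."""
    m.require(("WT1", "WT2"))
    lfc = _replicate_lfc(m, "WT2", "WT1")
    if np.isinf(tolerance_fold):
        ok = np.ones(len(m.values.index), dtype=bool)
    else:
        bound = np.log2(tolerance_fold) + _EPS_LOG2
        ok = np.logical_and.reduce(
            [(v >= -bound) & (v <= bound) for v in lfc.values()]
        )
    return pd.Series(ok, index=m.values.index, name="recovered_at_WT2")


def summarize_counts(c: MemoryClassification) -> dict[str, int]:
    """Counts of each label/memory label plus recovered transcripts."""
    t = c.table
    counts = {
        "DIT": int((t["label"] == "DIT").sum()),
        "DRT": int((t["label"] == "DRT").sum()),
        "DIMT": int((t["memory_label"] == "DIMT").sum()),
        "DRMT": int((t["memory_label"] == "DRMT").sum()),
        "non_responsive": int((t["label"] == "non-responsive").sum()),
    }
    if "recovered_at_WT2" in t.columns:
        counts["recovered"] = int(t["recovered_at_WT2"].sum())
    return counts


def category_members(c: MemoryClassification) -> dict[str, list[str]]:
    """Transcript-id lists per category (for per-category TSV export)."""
    t = c.table
    return {
        "DIT": list(t.index[t["label"] == "DIT"]),
        "DRT": list(t.index[t["label"] == "DRT"]),
        "DIMT": list(t.index[t["memory_label"] == "DIMT"]),
        "DRMT": list(t.index[t["memory_label"] == "DRMT"]),
    }
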