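import numpy as np
import pandas as pd
import pytest

from droughtmem.annotation_io import TranscriptModel
from droughtmem.preprocess_stats import CONDITIONS, ExpressionMatrix
from droughtmem.synthetic_data import SimulationConfig


def small_sim_cfg(seed: int, n_genes: int, **kwargs) -> SimulationConfig:
    """A SimulationConfig for small toy genomes: planted counts scaled to
    fit ``n_genes`` unless overridden."""
    kwargs.setdefault(
        "n_planted",
        {"DIT": max(1, n_genes // 10), "DRT": max(1, n_genes // 10),
         "DIMT": max(1, n_genes // 25), "DRMT": max(1, n_genes // 25)},
    )
    return SimulationConfig(seed=seed, n_genes=n_genes, **kwargs)

TOY_GFF3 = """\
##gff-version 3
chr1\ttest\tgene\t11\t190\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t11\t190\t.\t+\t.\tID=geneA.1;Parent=geneA
chr1\ttest\texon\t11\t70\t.\t+\t.\tParent=geneA.1
chr1\ttest\texon\t101\t150\t.\t+\t.\tParent=geneA.1
chr1\ttest\texon\t161\t190\t.\t+\t.\tParent=geneA.1
chr1\ttest\tCDS\t21\t70\t.\t+\t0\tParent=geneA.1
chr1\ttest\tCDS\t101\t130\t.\t+\t0\tParent=geneA.1
chr1\ttest\tmRNA\t11\t190\t.\t+\t.\tID=geneA.2;Parent=geneA
chr1\ttest\texon\t11\t70\t.\t+\t.\tParent=geneA.2
chr1\ttest\texon\t161\t190\t.\t+\t.\tParent=geneA.2
chr1\ttest\tCDS\t21\t70\t.\t+\t0\tParent=geneA.2
"""


def toy_fasta(n: int = 300, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
    return f">chr1\n{seq}\n"


@pytest.fixture
def toy_annotation():
    return TOY_GFF3, toy_fasta()


def make_transcript(
    sequence: str,
    stop_end_tx: int,
    transcript_id: str = "tx1",
    gene_id: str = "g1",
    strand: str = "+",
) -> TranscriptModel:
    """Build a free-standing transcript model for probe-geometry tests."""
    L = len(sequence)
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        chromosome="chr1",
        strand=strand,
        exons=((1, L),),
        cds_intervals=((1, stop_end_tx),),
        spliced_sequence=sequence,
        stop_end_tx=stop_end_tx,
        utr3_length_tx=L - stop_end_tx,
    )


def random_sequence(n: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_matrix(values, row_ids=None, scale: str = "log2") -> ExpressionMatrix:
    """Build an 8-sample matrix; ``values`` is rows x 8 in the column order
    WT1_r1, WT1_r2, DR1_r1, DR1_r2, WT2_r1, WT2_r2, DR2_r1, DR2_r2."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    cols, meta = [], []
    for cond in CONDITIONS:
        for rep in (1, 2):
            cols.append(f"{cond}_r{rep}")
            meta.append({"sample_id": f"{cond}_r{rep}", "condition": cond,
                         "replicate": rep})
    row_ids = row_ids or [f"t{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=row_ids, columns=cols),
        sample_meta=pd.DataFrame(meta).set_index("sample_id"),
        scale=scale,
    )
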