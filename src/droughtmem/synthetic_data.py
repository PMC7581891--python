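"""Seeded generators for every input the pipeline consumes.

Emulates the study design without downloads: a toy multi-isoform genome
annotation (GFF3 + FASTA) with unique skipped exons; an 8-array raw
intensity matrix over WT1/DR1/WT2/DR2 x 2 replicates with log-normal
noise, additive background and planted drought-responsive and memory
transcripts at configurable effect sizes; a flat GO annotation with one
planted enriched term; and a BLAST-like tabular alignment file.

Intensity model: per-transcript baseline log2 intensity ~ Normal(mu, sd)
with defaults anchored to a realistic single-channel dynamic range (median
around 230 on the raw scale); drought response adds +/-3 log2 (8-fold) in
DR1 and DR2; memory transcripts get a further +/-3 log2 increment in DR2
only, so the DR2/DR1 fold is directly controlled; WT2 returns to
baseline; replicate noise is Normal(0, 0.25) on the log2 scale; raw
intensities are 2^value plus a constant background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from droughtmem.annotation_io import revcomp
from droughtmem.preprocess_stats import CONDITIONS, ExpressionMatrix

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the simulated study
    conditions (two replicates of four states, 8-fold planted effects,
    log2 noise sd 0.25)."""

    seed: int = 0
    n_genes: int = 500
    fraction_alternatively_spliced: float = 0.3
    n_planted: dict = field(
        default_factory=lambda: {"DIT": 30, "DRT": 30, "DIMT": 10, "DRMT": 10}
    )
    effect_size_log2: dict = field(
        default_factory=lambda: {"DIT": 3.0, "DRT": -3.0, "DIMT": 3.0, "DRMT": -3.0}
    )
    noise_sigma_log2: float = 0.25
    baseline_log2_mean: float = 7.85
    baseline_log2_sd: float = 2.0
    # Responsive/memory transcripts sit in the upper intensity range:
    # induced genes reach chip maxima under drought and the repressed
    # memory genes are abundant photosynthesis transcripts, and a 4x4-fold
    # repression is only measurable from well above array background.
    planted_baseline_log2_mean: float = 12.0
    planted_baseline_log2_sd: float = 1.5
    planted_baseline_log2_min: float = 10.0
    background_level: float = 20.0
    n_control_rows: int = 10
    planted_go_overlap: float = 0.8
    n_go_terms: int = 30

    def __post_init__(self) -> None:
        if self.noise_sigma_log2 < 0 or self.baseline_log2_sd <= 0:
            raise ValueError("noise/baseline standard deviations must be positive")
        n = self.n_planted
        if n["DIMT"] > n["DIT"] or n["DRMT"] > n["DRT"]:
            raise ValueError("memory-planted counts cannot exceed response counts")
        if n["DIT"] + n["DRT"] > self.n_genes:
            raise ValueError("planted counts exceed n_genes")
        if not 0 <= self.fraction_alternatively_spliced <= 1:
            raise ValueError("fraction_alternatively_spliced must lie in [0,1]")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _split_intervals(rng: np.random.Generator, length: int, n_parts: int):
    """Partition [1, length] into n_parts non-empty consecutive intervals."""
    if n_parts == 1:
        return [(1, length)]
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_parts - 1, replace=False))
    bounds = [0, *cuts.tolist(), length]
    return [(bounds[i] + 1, bounds[i + 1]) for i in range(n_parts)]


def simulate_genome(cfg: SimulationConfig) -> tuple[str, str, pd.DataFrame]:
    """Generate (GFF3 text, FASTA text, truth exon table).

    Each gene has 1-4 exons, a CDS ending in a stop codon, a 5'-UTR of
    0-100 nt and a 3'-UTR of 0-200 nt (so some are shorter than the 60-nt
    probe and exercise the frame-shift rule). A configurable fraction of
    genes carries a second isoform that skips one internal exon, making
    that exon unique to the representative. Deterministic under the seed.
    """
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    chrom_parts: list[str] = []
    gff = ["##gff-version 3"]
    truth_rows = []
    pos = 1  # next free 1-based chromosome position
    chrom = "Chr01"

    for gi in range(cfg.n_genes):
        gene_id = f"G{gi:04d}"
        as_gene = rng.random() < cfg.fraction_alternatively_spliced
        n_exons = int(rng.integers(3, 5)) if as_gene else int(rng.integers(1, 5))
        utr5 = int(rng.integers(0, 101))
        utr3 = int(rng.integers(0, 201))
        cds_len = int(rng.integers(40, 201)) * 3
        tx_len = utr5 + cds_len + utr3
        strand = "+" if rng.random() < 0.5 else "-"

        tx_seq = (
            _random_seq(rng, utr5)
            + _random_seq(rng, cds_len - 3)
            + _STOPS[rng.integers(0, 3)]
            + _random_seq(rng, utr3)
        )
        exon_tx = _split_intervals(rng, tx_len, n_exons)

        # sense-local locus layout: exons separated by introns
        intron_lens = [int(rng.integers(30, 101)) for _ in range(n_exons - 1)]
        locus_parts, exon_local = [], []
        cursor = 0
        for k, (ts, te) in enumerate(exon_tx):
            seg = tx_seq[ts - 1 : te]
            locus_parts.append(seg)
            exon_local.append((cursor + 1, cursor + len(seg)))
            cursor += len(seg)
            if k < n_exons - 1:
                locus_parts.append(_random_seq(rng, intron_lens[k]))
                cursor += intron_lens[k]
        locus = "".join(locus_parts)
        L = len(locus)

        cds_tx = (utr5 + 1, utr5 + cds_len)
        cds_local = []
        for (ts, te), (ls, _) in zip(exon_tx, exon_local):
            lo, hi = max(ts, cds_tx[0]), min(te, cds_tx[1])
            if lo <= hi:
                cds_local.append((ls + (lo - ts), ls + (hi - ts)))

        o = pos  # 1-based genomic start of the locus

        def to_genomic(iv):
            a, b = iv
            if strand == "+":
                return (o + a - 1, o + b - 1)
            return (o + L - b, o + L - a)

        exon_genomic = sorted(to_genomic(iv) for iv in exon_local)
        cds_genomic = sorted(to_genomic(iv) for iv in cds_local)
        chrom_parts.append(locus if strand == "+" else revcomp(locus))
        spacer = int(rng.integers(20, 60))
        chrom_parts.append(_random_seq(rng, spacer))
        pos += L + spacer

        tx1 = f"{gene_id}.T1"
        isoforms = [(tx1, exon_genomic, cds_genomic)]
        skipped_tx_interval = None
        if as_gene:
            # skip one internal exon that leaves the CDS non-empty
            skip_k = int(rng.integers(1, n_exons - 1))
            kept = [iv for i, iv in enumerate(exon_local) if i != skip_k]
            kept_cds = []
            for (ls, le) in kept:
                for (cs, ce) in cds_local:
                    lo, hi = max(ls, cs), min(le, ce)
                    if lo <= hi:
                        kept_cds.append((lo, hi))
            if kept_cds:
                isoforms.append(
                    (
                        f"{gene_id}.T2",
                        sorted(to_genomic(iv) for iv in kept),
                        sorted(to_genomic(iv) for iv in kept_cds),
                    )
                )
                skipped_tx_interval = exon_tx[skip_k]

        g_start = min(s for _, ex, _ in isoforms for s, _ in ex)
        g_end = max(e for _, ex, _ in isoforms for _, e in ex)
        gff.append(
            f"{chrom}\tsim\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gene_id}"
        )
        for tx_id, ex, cds_iv in isoforms:
            t_start = min(s for s, _ in ex)
            t_end = max(e for _, e in ex)
            gff.append(
                f"{chrom}\tsim\tmRNA\t{t_start}\t{t_end}\t.\t{strand}\t.\t"
                f"ID={tx_id};Parent={gene_id}"
            )
            for s, e in ex:
                gff.append(
                    f"{chrom}\tsim\texon\t{s}\t{e}\t.\t{strand}\t.\tParent={tx_id}"
                )
            for s, e in cds_iv:
                gff.append(
                    f"{chrom}\tsim\tCDS\t{s}\t{e}\t.\t{strand}\t0\tParent={tx_id}"
                )
        truth_rows.append(
            {
                "gene_id": gene_id,
                "representative": tx1,
                "strand": strand,
                "tx_length": tx_len,
                "utr3_length": utr3,
                "stop_end_tx": utr5 + cds_len,
                "alternatively_spliced": len(isoforms) > 1,
                "unique_exon_tx_start": (
                    skipped_tx_interval[0] if skipped_tx_interval else -1
                ),
                "unique_exon_tx_end": (
                    skipped_tx_interval[1] if skipped_tx_interval else -1
                ),
            }
        )

    fasta = f">{chrom}\n" + "".join(chrom_parts) + "\n"
    return "\n".join(gff) + "\n", fasta, pd.DataFrame(truth_rows)


def _assign_labels(
    cfg: SimulationConfig, rng: np.random.Generator, transcript_ids: list[str]
) -> pd.DataFrame:
    n = cfg.n_planted
    total = n["DIT"] + n["DRT"]
    if total > len(transcript_ids):
        raise ValueError("planted counts exceed number of transcripts")
    chosen = rng.choice(len(transcript_ids), size=total, replace=False)
    label = np.array(["non-responsive"] * len(transcript_ids), dtype=object)
    memory = np.array(["none"] * len(transcript_ids), dtype=object)
    dit_idx = chosen[: n["DIT"]]
    drt_idx = chosen[n["DIT"] :]
    label[dit_idx] = "DIT"
    label[drt_idx] = "DRT"
    memory[dit_idx[: n["DIMT"]]] = "DIMT"
    memory[drt_idx[: n["DRMT"]]] = "DRMT"
    return pd.DataFrame(
        {"label": label, "memory_label": memory},
        index=pd.Index(transcript_ids, name="transcript_id"),
    )


def simulate_expression(
    cfg: SimulationConfig, transcript_ids: list[str]
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a raw 8-sample intensity matrix plus the truth table.

    Planted labels follow the gated taxonomy: every memory transcript is
    also response-planted, the memory increment acts on DR2 only, and
    control rows (appended as CTRL_*) carry no label. The truth table
    reports the planted label, memory label and exact planted log2 fold
    changes.
    """
    rng = np.random.default_rng((cfg.seed, 1))
    truth = _assign_labels(cfg, rng, list(transcript_ids))
    e = cfg.effect_size_log2
    response = np.zeros(len(truth))
    response[truth["label"] == "DIT"] = e["DIT"]
    response[truth["label"] == "DRT"] = e["DRT"]
    memory_inc = np.zeros(len(truth))
    memory_inc[truth["memory_label"] == "DIMT"] = e["DIMT"]
    memory_inc[truth["memory_label"] == "DRMT"] = e["DRMT"]

    control_ids = [f"CTRL_{i:03d}" for i in range(cfg.n_control_rows)]
    all_ids = list(truth.index) + control_ids
    response = np.concatenate([response, np.zeros(cfg.n_control_rows)])
    memory_inc = np.concatenate([memory_inc, np.zeros(cfg.n_control_rows)])

    baseline = rng.normal(
        cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=len(all_ids)
    )
    planted_mask = response != 0
    planted_base = np.clip(
        rng.normal(
            cfg.planted_baseline_log2_mean,
            cfg.planted_baseline_log2_sd,
            size=int(planted_mask.sum()),
        ),
        cfg.planted_baseline_log2_min,
        None,
    )
    baseline[planted_mask] = planted_base
    cond_mean = {
        "WT1": baseline,
        "DR1": baseline + response,
        "WT2": baseline,
        "DR2": baseline + response + memory_inc,
    }
    columns, data = [], []
    meta_rows = []
    for cond in CONDITIONS:
        for rep in (1, 2):
            name = f"{cond}_r{rep}"
            noise = rng.normal(0.0, cfg.noise_sigma_log2, size=len(all_ids))
            data.append(np.exp2(cond_mean[cond] + noise) + cfg.background_level)
            columns.append(name)
            meta_rows.append({"sample_id": name, "condition": cond, "replicate": rep})
    values = pd.DataFrame(
        np.column_stack(data), index=pd.Index(all_ids, name="transcript_id"),
        columns=columns,
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth_full = truth.reindex(all_ids)
    truth_full.loc[control_ids, ["label", "memory_label"]] = ["control", "none"]
    truth_full["planted_lfc_DR1_WT1"] = response
    truth_full["planted_lfc_DR2_DR1"] = memory_inc
    matrix = ExpressionMatrix(values=values, sample_meta=meta, scale="raw")
    return matrix, truth_full


def simulate_go(
    cfg: SimulationConfig,
    gene_ids: list[str],
    planted_genes: list[str] | None = None,
):
    """Generate a flat GO annotation with one planted enriched term.

    Background terms draw members uniformly from the universe; the planted
    term GO:PLANTED contains ``planted_go_overlap`` of the planted gene
    set (by default the memory-induced genes chosen by
    :func:`simulate_expression` under the same seed) topped up with random
    genes to a comparable size.
    """
    from droughtmem.enrichment import GoAnnotation

    if len(gene_ids) < 20:
        raise ValueError("need >= 20 genes for a meaningful annotation")
    rng = np.random.default_rng((cfg.seed, 2))
    universe = list(gene_ids)
    if planted_genes is None:
        label_rng = np.random.default_rng((cfg.seed, 1))
        truth = _assign_labels(cfg, label_rng, universe)
        planted_genes = list(truth.index[truth["memory_label"] == "DIMT"])
    term_genes: dict[str, frozenset] = {}
    for ti in range(cfg.n_go_terms):
        size = int(rng.integers(10, min(51, len(universe))))
        members = rng.choice(universe, size=size, replace=False)
        term_genes[f"GO:{ti:07d}"] = frozenset(members)
    n_in = max(1, int(round(cfg.planted_go_overlap * len(planted_genes))))
    core = list(rng.choice(planted_genes, size=n_in, replace=False))
    others = [g for g in universe if g not in set(core)]
    filler = list(rng.choice(others, size=min(5, len(others)), replace=False))
    term_genes["GO:PLANTED"] = frozenset(core + filler)
    names = {t: f"synthetic term {t}" for t in term_genes}
    names["GO:PLANTED"] = "planted enriched term"
    return GoAnnotation(term_genes, frozenset(universe), names)


def simulate_alignment(
    cfg: SimulationConfig,
    query_ids: list[str],
    n_subjects: int | None = None,
) -> str:
    """BLAST-like 12-column tabular text mapping queries to synthetic
    subject genes; roughly 80% of queries get a hit scoring >= 70."""
    rng = np.random.default_rng((cfg.seed, 3))
    n_subjects = n_subjects or max(10, len(query_ids) // 2)
    subjects = [f"AT{i:05d}" for i in range(n_subjects)]
    lines = []
    for q in query_ids:
        n_hits = int(rng.integers(1, 4))
        for _ in range(n_hits):
            s = subjects[rng.integers(0, n_subjects)]
            score = float(rng.uniform(40, 200)) if rng.random() < 0.8 else float(
                rng.uniform(20, 69)
            )
            ident = float(rng.uniform(40, 99))
            lines.append(
                f"{q}\t{s}\t{ident:.1f}\t{int(rng.integers(50, 400))}\t"
                f"{int(rng.integers(0, 40))}\t{int(rng.integers(0, 5))}\t"
                f"1\t100\t1\t100\t{10 ** -rng.uniform(3, 50):.2e}\t{score:.1f}"
            )
    return "\n".join(lines) + "\n"
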