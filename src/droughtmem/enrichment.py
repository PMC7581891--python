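"""GO-term enrichment with randomization-based FDR.

For each gene set (DIT/DRT/DIMT/DRMT), term over-representation is scored
with the upper-tail hypergeometric probability P(X >= k) against a fixed
gene universe. The false discovery rate is estimated by randomization:
random gene sets of the query's size are drawn from the universe, every
term's p-value is recomputed per draw, and FDR(term) is the mean number of
terms reaching p <= p_obs(term) under randomization divided by the number
observed to do so, capped at 1. Significant terms (FDR below a cutoff,
default 0.05) are mapped onto a signed heat score in +/-[0.5, 5]: 0.5 at
the cutoff, 5 at FDR 0, negated for repressed-direction sets; all
non-significant terms score 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Collection, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class GoAnnotation:
    """Flat term -> gene annotation over a fixed universe (no DAG
    propagation: annotations are taken as given)."""

    term_genes: dict[str, frozenset]
    universe: frozenset
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.term_genes = {
            t: frozenset(g) & self.universe
            for t, g in self.term_genes.items()
            if frozenset(g) & self.universe
        }
        self.universe = frozenset(self.universe)

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_genes)

    @classmethod
    def from_tsv(cls, path, name_path=None):
        """Two-column TSV (term_id, gene_id); universe = all annotated
        genes unless a larger one is supplied later."""
        df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"],
                         comment="#", dtype=str)
        term_genes: dict[str, set] = {}
        for term, gene in zip(df["term_id"], df["gene_id"]):
            term_genes.setdefault(term, set()).add(gene)
        names = {}
        if name_path is not None:
            nd = pd.read_csv(name_path, sep="\t", header=None,
                             names=["term_id", "name"], dtype=str)
            names = dict(zip(nd["term_id"], nd["name"]))
        universe = frozenset(df["gene_id"])
        return cls({t: frozenset(g) for t, g in term_genes.items()},
                   universe, names)


def _term_counts(anno: GoAnnotation, query: frozenset) -> pd.DataFrame:
    rows = []
    for term in anno.terms:
        genes = anno.term_genes[term]
        rows.append((term, len(genes & query), len(genes)))
    return pd.DataFrame(rows, columns=["term_id", "k", "K"]).set_index("term_id")


def hypergeom_enrich(query: Collection[str], anno: GoAnnotation) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment p-value per term.

    Genes outside the universe are dropped with a warning count. Returns a
    frame indexed by term with columns k, K, n, N, p.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query gene set")
    inside = frozenset(query) & anno.universe
    n_outside = len(query) - len(inside)
    if n_outside:
        warnings.warn(
            f"{n_outside} query gene(s) outside the annotation universe dropped",
            stacklevel=2,
        )
    if not inside:
        raise ValueError("no query gene lies in the annotation universe")
    N, n = len(anno.universe), len(inside)
    table = _term_counts(anno, inside)
    table["n"] = n
    table["N"] = N
    table["p"] = stats.hypergeom.sf(table["k"] - 1, N, table["K"], n)
    return table


def randomization_fdr(
    anno: GoAnnotation,
    query_size: int,
    observed_p: pd.Series,
    n_randomizations: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Randomization FDR per term.

    Draws ``n_randomizations`` random gene sets of size ``query_size`` from
    the universe, recomputes all term p-values per draw, and estimates
    FDR(term) as (mean count of terms with p' <= p_obs(term)) / (observed
    count of terms with p <= p_obs(term)), capped at 1. Deterministic under
    a fixed seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    universe = sorted(anno.universe)
    N = len(universe)
    if query_size > N:
        raise ValueError(f"query size {query_size} exceeds universe size {N}")
    terms = list(observed_p.index)
    # term x gene membership matrix for vectorized per-draw counts
    gene_pos = {g: i for i, g in enumerate(universe)}
    M = np.zeros((len(terms), N), dtype=bool)
    for ti, term in enumerate(terms):
        for g in anno.term_genes[term]:
            M[ti, gene_pos[g]] = True
    K = M.sum(axis=1)

    obs = observed_p.to_numpy(dtype=float)
    obs_sorted = np.sort(obs)
    n_obs_le = np.searchsorted(obs_sorted, obs, side="right")

    false_counts = np.zeros(len(terms))
    for _ in range(n_randomizations):
        draw = rng.choice(N, size=query_size, replace=False)
        k = M[:, draw].sum(axis=1)
        p_rand = stats.hypergeom.sf(k - 1, N, K, query_size)
        p_rand_sorted = np.sort(p_rand)
        false_counts += np.searchsorted(p_rand_sorted, obs, side="right")
    mean_false = false_counts / n_randomizations
    fdr = np.minimum(mean_false / np.maximum(n_obs_le, 1), 1.0)
    # enforce monotonicity in the observed p (running max over the sorted
    # order), so a more significant term never reports a larger FDR
    order = np.argsort(obs, kind="mergesort")
    fdr[order] = np.maximum.accumulate(fdr[order])
    return pd.Series(fdr, index=observed_p.index, name="fdr")


def enrich_with_fdr(
    query: Collection[str],
    anno: GoAnnotation,
    n_randomizations: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Convenience wrapper: hypergeometric p + randomization FDR."""
    table = hypergeom_enrich(query, anno)
    table["fdr"] = randomization_fdr(
        anno, int(table["n"].iloc[0]), table["p"], n_randomizations, seed
    )
    return table


def select_terms(
    tables: Mapping[str, pd.DataFrame], cutoff: float = 0.05
) -> list[str]:
    """Union of terms with fdr < cutoff in at least one gene-set class."""
    selected: set[str] = set()
    for table in tables.values():
        selected.update(table.index[table["fdr"] < cutoff])
    return sorted(selected)


def scale_scores(
    fdr: pd.Series, direction: str = "induced", cutoff: float = 0.05
) -> pd.Series:
    """Map FDR to the signed heat score.

    fdr >= cutoff -> 0; otherwise the score runs linearly from 0.5 (at the
    cutoff) to 5 (at fdr 0), negated for the repressed direction.
    """
    if direction not in ("induced", "repressed"):
        raise ValueError("direction must be 'induced' or 'repressed'")
    f = fdr.to_numpy(dtype=float)
    score = np.where(f < cutoff, 0.5 + 4.5 * (cutoff - f) / cutoff, 0.0)
    if direction == "repressed":
        score = -score
    return pd.Series(score, index=fdr.index, name="score")


def score_matrix(
    tables: Mapping[str, pd.DataFrame],
    directions: Mapping[str, str],
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Combined signed score matrix (terms x classes) over the selected
    term union — the tabular form of the enrichment heatmap."""
    terms = select_terms(tables, cutoff)
    out = pd.DataFrame(index=pd.Index(terms, name="term_id"))
    for cls, table in tables.items():
        s = scale_scores(table["fdr"], directions.get(cls, "induced"), cutoff)
        out[cls] = s.reindex(terms).fillna(0.0)
    return out


def cluster_term_order(scores: pd.DataFrame) -> list[str]:
    """Leaf order from average-linkage hierarchical clustering of term
    score profiles (Euclidean distance); presentation-only."""
    if len(scores) < 3:
        return list(scores.index)
    Z = hierarchy.linkage(pdist(scores.to_numpy()), method="average")
    order = hierarchy.leaves_list(Z)
    return [scores.index[i] for i in order]
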