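"""Intensity preprocessing and moderated differential statistics.

The workflow mirrors standard single-channel microarray practice for a
two-cycle drought design (conditions WT1, DR1, WT2, DR2 with two
biological replicates each): percentile background subtraction with a
positive floor, log2 transform, quantile normalization, optional
probe-to-transcript summarization, then a per-row linear model on
condition means with empirical-Bayes variance shrinkage (a moderated
t-statistic) for the contrasts DR1-WT1, WT2-WT1 and DR2-DR1, followed by
Benjamini-Hochberg adjustment.

Variance shrinkage: per-row residual variances s^2 with d degrees of
freedom are assumed to scale as s0^2 * F(d, d0); the prior (d0, s0^2) is
estimated in closed form by moment matching on log s^2 using digamma /
trigamma identities, and the posterior variance is the weighted mean
s~^2 = (d0*s0^2 + d*s^2) / (d0 + d). At d0=0 the moderated t reduces to
the ordinary linear-model t; as d0 -> inf every row is tested against the
common prior variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("WT1", "DR1", "WT2", "DR2")
DEFAULT_CONTRASTS = (("DR1", "WT1"), ("WT2", "WT1"), ("DR2", "DR1"))


@dataclass
class ExpressionMatrix:
    """Probes-or-transcripts x samples intensity table with metadata.

    ``values`` is indexed by row id; ``sample_meta`` is indexed by the same
    column labels and carries ``condition`` and ``replicate``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "raw"  # raw | log2

    def __post_init__(self) -> None:
        missing = {"condition", "replicate"} - set(self.sample_meta.columns)
        if missing:
            raise ValueError(f"sample_meta lacks columns: {sorted(missing)}")
        if list(self.values.columns) != list(self.sample_meta.index):
            raise ValueError("values columns and sample_meta index disagree")

    def column(self, condition: str, replicate: int) -> pd.Series:
        mask = (self.sample_meta["condition"] == condition) & (
            self.sample_meta["replicate"] == replicate
        )
        names = self.sample_meta.index[mask]
        if len(names) != 1:
            raise ValueError(
                f"expected exactly one sample for {condition} rep {replicate}, "
                f"found {len(names)}"
            )
        return self.values[names[0]]

    def condition_columns(self, condition: str) -> pd.DataFrame:
        names = self.sample_meta.index[self.sample_meta["condition"] == condition]
        return self.values[list(names)]

    def require(self, conditions=CONDITIONS, n_replicates: int = 2) -> None:
        for c in conditions:
            reps = self.sample_meta.loc[
                self.sample_meta["condition"] == c, "replicate"
            ]
            for r in range(1, n_replicates + 1):
                if r not in set(reps):
                    raise ValueError(f"missing sample: condition {c} replicate {r}")

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="row_id")

    @classmethod
    def from_tsv(cls, matrix_path, samples_path, scale: str = "raw"):
        """Read an intensity TSV (first column = row id) + sample sheet TSV
        (sample_id, condition, replicate). Lines starting with '!' or '#'
        are tolerated, which covers GEO series-matrix-like layouts."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="!")
        values = values[[c for c in values.columns if not c.startswith("#")]]
        meta = pd.read_csv(samples_path, sep="\t", comment="#").set_index("sample_id")
        return cls(values=values[list(meta.index)], sample_meta=meta, scale=scale)


def background_correct(
    raw: ExpressionMatrix, offset: float = 1.0, percentile: float = 5.0
) -> ExpressionMatrix:
    """Subtract a per-column lower-percentile background estimate and floor
    at ``offset`` so every value is strictly positive."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    if raw.scale != "raw":
        raise ValueError("background correction expects raw-scale intensities")
    vals = raw.values.to_numpy(dtype=float)
    bg = np.percentile(vals, percentile, axis=0, keepdims=True)
    corrected = np.maximum(vals - bg, offset)
    return replace(
        raw, values=pd.DataFrame(corrected, index=raw.values.index,
                                 columns=raw.values.columns)
    )


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    if m.scale == "log2":
        return m
    if (m.values.to_numpy() <= 0).any():
        raise ValueError("non-positive values: background-correct first")
    return replace(m, values=np.log2(m.values), scale="log2")


def _quantile_normalize_array(x: np.ndarray) -> np.ndarray:
    """Rank-mean quantile normalization with tie groups mapped to the mean
    of their rank-range targets."""
    n, k = x.shape
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(k):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = col[order]
        assigned = np.empty(n)
        i = 0
        while i < n:
            m = i
            while m + 1 < n and ranked[m + 1] == ranked[i]:
                m += 1
            assigned[i : m + 1] = target[i : m + 1].mean()
            i = m + 1
        out[order, j] = assigned
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force all columns onto a common distribution (the across-column mean
    of order statistics). A single-column matrix is returned unchanged."""
    if m.scale != "log2":
        raise ValueError("quantile normalization expects log2 scale")
    if m.values.shape[1] <= 1:
        return m
    out = _quantile_normalize_array(m.values.to_numpy(dtype=float))
    return replace(
        m, values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    )


def replicate_concordance(x, y) -> tuple[float, float, float]:
    """OLS fit of y on x plus the Pearson correlation, for replicate QC."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: zero variance in x")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def summarize_probes(
    m: ExpressionMatrix, probe_to_transcript: pd.Series, how: str = "median"
) -> ExpressionMatrix:
    """Collapse probe rows to transcript rows (median per transcript per
    sample by default, mean optionally)."""
    if how not in ("median", "mean"):
        raise ValueError("how must be 'median' or 'mean'")
    mapping = probe_to_transcript.reindex(m.values.index).dropna()
    grouped = m.values.loc[mapping.index].groupby(mapping)
    vals = grouped.median() if how == "median" else grouped.mean()
    return replace(m, values=vals)


def _invert_trigamma(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on the standard
    starting value; y must be positive)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Matches the mean and variance of log s^2 under the scaled-F model using
    digamma/trigamma identities. Returns d0 = inf when the observed spread
    of log s^2 is no larger than expected from chi^2_d noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive residual variances")
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    ev = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if ev <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e.mean()))
    else:
        d0 = 2.0 * _invert_trigamma(float(ev))
        s0_2 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


@dataclass
class DifferentialResult:
    """Per-row moderated statistics for a set of contrasts."""

    table: pd.DataFrame  # per-row columns, see moderated_differential
    contrasts: tuple[tuple[str, str], ...]
    d0: float
    s0_2: float
    residual_df: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="row_id")


def moderated_differential(
    m: ExpressionMatrix,
    contrasts=DEFAULT_CONTRASTS,
    prior_df: float | None = None,
    control: str = "WT1",
) -> DifferentialResult:
    """Fit condition means per row and compute moderated t-statistics.

    For each contrast (a, b): delta = mean(a) - mean(b); the residual
    variance pools within-condition scatter across all conditions
    (d = n_samples - n_conditions df); the moderated variance shrinks each
    row toward the moment-matched prior. ``prior_df`` overrides the
    estimated d0 (0 disables shrinkage; np.inf pools fully).

    The output table also carries per-replicate log2 fold changes for each
    contrast and ``max_abs_level``: the largest |log2(condition mean) -
    log2(control mean)| over the non-control stages.
    """
    if m.scale != "log2":
        raise ValueError("moderated statistics expect a normalized log2 matrix")
    conditions = list(dict.fromkeys(m.sample_meta["condition"]))
    for c in conditions:
        n = (m.sample_meta["condition"] == c).sum()
        if n < 2:
            raise ValueError(f"condition {c} has {n} replicate(s); need >= 2")

    X = m.values.to_numpy(dtype=float)
    n_rows, n_samples = X.shape
    means = {c: m.condition_columns(c).to_numpy().mean(axis=1) for c in conditions}
    resid_ss = np.zeros(n_rows)
    for c in conditions:
        block = m.condition_columns(c).to_numpy()
        resid_ss += ((block - means[c][:, None]) ** 2).sum(axis=1)
    d = n_samples - len(conditions)
    s2 = resid_ss / d

    d0_hat, s0_2 = estimate_prior(s2, d)
    d0 = d0_hat if prior_df is None else float(prior_df)
    if np.isinf(d0):
        s2_post = np.full(n_rows, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d) if d0 > 0 else s2
        df_total = d0 + d

    out = pd.DataFrame(index=m.values.index)
    reps = sorted(set(m.sample_meta["replicate"]))
    for a, b in contrasts:
        n_a = (m.sample_meta["condition"] == a).sum()
        n_b = (m.sample_meta["condition"] == b).sum()
        c_scale = np.sqrt(1.0 / n_a + 1.0 / n_b)
        delta = means[a] - means[b]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = delta / (np.sqrt(s2_post) * c_scale)
        if np.isinf(df_total):
            pvals = 2.0 * stats.norm.sf(np.abs(tstat))
        else:
            pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        adj = multipletests(pvals, method="fdr_bh")[1]
        tag = f"{a}_{b}"
        for r in reps:
            out[f"lfc_{tag}_rep{r}"] = (
                m.column(a, r).to_numpy() - m.column(b, r).to_numpy()
            )
        out[f"lfc_{tag}"] = delta
        out[f"t_{tag}"] = tstat
        out[f"p_{tag}"] = pvals
        out[f"adj_p_{tag}"] = adj

    stages = [c for c in conditions if c != control]
    levels = np.column_stack([means[s] - means[control] for s in stages])
    out["max_abs_level"] = np.abs(levels).max(axis=1)
    return DifferentialResult(
        table=out, contrasts=tuple(contrasts), d0=d0, s0_2=s0_2, residual_df=d
    )


def filter_significant(
    d: DifferentialResult, alpha: float = 0.05, level_cut: float = 1.0
) -> pd.Index:
    """Rows with adjusted p < alpha in at least one contrast AND
    |log2 level vs control| > level_cut at at least one stage."""
    adj_cols = [c for c in d.table.columns if c.startswith("adj_p_")]
    sig = (d.table[adj_cols] < alpha).any(axis=1)
    level = d.table["max_abs_level"] > level_cut
    return d.table.index[sig & level]
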