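"""Count-matrix analytics: normalization, filtering, NB differential
expression, pathway enrichment, PCA and phenotype correlation.

Differential expression uses a two-group negative-binomial likelihood-ratio
test with library-size offsets. The NB is parameterized by mean mu and
dispersion phi with variance mu + phi * mu^2. Per-gene dispersions are
estimated by method of moments on library-size-scaled counts (pooled
within-group variance), floored, and shrunk on the log scale toward a
trended mean-dispersion fit; the fitted dispersion is then plugged into the
likelihood-ratio test (chi-square with 1 df). Thresholds follow the study
design: a gene is differentially expressed when q < 0.05 (Benjamini-
Hochberg) and |log2 fold change| > 0.5; pathway enrichment uses the
hypergeometric upper tail with significance at p < 0.005.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

STRAINS = ("WT", "d6abc5_mt", "d6bc_mt")
DIETS = ("plant_oil", "fish_oil")

#: default DEG thresholds
Q_CUT = 0.05
LFC_CUT = 0.5
ENRICH_P = 0.005


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    strain: str
    diet: str
    tank: str = ""
    phenotype: float | None = None  # e.g. DHA % of phospholipids

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}; expected one of {STRAINS}")
        if self.diet not in DIETS:
            raise ValueError(f"unknown diet {self.diet!r}; expected one of {DIETS}")


@dataclass
class CountsMatrix:
    """Gene x sample non-negative integer counts, with optional gene lengths."""

    counts: pd.DataFrame  # index: gene_id, columns: sample_id
    gene_lengths: pd.Series | None = None  # nt, indexed by gene_id

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @classmethod
    def from_tsv(cls, counts_path: str | Path, lengths_path: str | Path | None = None) -> "CountsMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = None
        if lengths_path is not None:
            ldf = pd.read_csv(lengths_path, sep="\t", index_col=0)
            lengths = ldf.iloc[:, 0]
        return cls(counts, lengths)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tank": str})
    metas = []
    for _, row in df.iterrows():
        pheno = row.get("phenotype")
        metas.append(
            SampleMeta(
                str(row["sample_id"]),
                str(row["strain"]),
                str(row["diet"]),
                str(row.get("tank", "")),
                float(pheno) if pheno is not None and not pd.isna(pheno) else None,
            )
        )
    return metas


def cpm(counts: CountsMatrix) -> pd.DataFrame:
    """Counts per million: count * 1e6 / library size (no length correction)."""
    libs = counts.library_sizes
    zero = libs[libs == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {', '.join(zero.index)}")
    return counts.counts * 1e6 / libs


def tpm(counts: CountsMatrix) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled to 1e6 per sample."""
    if counts.gene_lengths is None or counts.gene_lengths.isna().any():
        raise ValueError("tpm requires a length for every gene")
    if (counts.gene_lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.counts.div(counts.gene_lengths, axis=0)
    return rate * 1e6 / rate.sum(axis=0)


def filter_genes(
    counts: CountsMatrix, min_cpm: float = 1.0, min_sample_frac: float = 0.75
) -> CountsMatrix:
    """Keep genes with CPM >= min_cpm in at least ceil(frac * n_samples) samples."""
    if not (0 < min_sample_frac <= 1):
        raise ValueError("min_sample_frac must be in (0, 1]")
    need = int(np.ceil(min_sample_frac * counts.counts.shape[1]))
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= need
    lengths = counts.gene_lengths[keep] if counts.gene_lengths is not None else None
    return CountsMatrix(counts.counts.loc[keep], lengths)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# negative-binomial two-group test


def size_factors(y: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (robust to asymmetric differential
    expression, unlike raw library sizes), normalized to mean 1.

    Falls back to library-size factors when too few genes are expressed in
    every sample.
    """
    libs = y.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("zero library size")
    positive = (y > 0).all(axis=1)
    if positive.sum() >= 10:
        logref = np.log(y[positive]).mean(axis=1)
        s = np.exp(np.median(np.log(y[positive]) - logref[:, None], axis=0))
    else:
        s = libs.astype(float)
    return s / s.mean()


def _trimmed_size_factors(
    y: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray, trim: float = 0.15
) -> np.ndarray:
    """Size factors after trimming genes with extreme between-group ratios.

    One-directional differential expression drags the plain median of ratios,
    which then shifts every null gene's fold change; trimming the ``trim``
    fraction of genes at each tail of the between-group log-ratio removes
    that bias (the trim is shift-invariant, so no prior normalization is
    needed).
    """
    d = np.log((y[:, idx_b].mean(axis=1) + 0.5) / (y[:, idx_a].mean(axis=1) + 0.5))
    lo, hi = np.quantile(d, [trim, 1.0 - trim])
    keep = (d >= lo) & (d <= hi)
    if keep.sum() < 10:
        keep = np.ones(len(d), dtype=bool)
    return size_factors(y[keep])


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB log-likelihood summed over samples (axis 1); var = mu + phi mu^2."""
    r = 1.0 / phi[:, None]
    mu = np.maximum(mu, 1e-10)
    return np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu)),
        axis=1,
    )


def _fit_nb_intercept(
    y: np.ndarray, s: np.ndarray, phi: np.ndarray, n_iter: int = 50
) -> np.ndarray:
    """MLE of mu0 per gene for the model mu_ij = s_j * mu0_i with fixed phi.

    Newton iterations on b = log mu0, vectorized over genes.
    """
    tot = y.sum(axis=1)
    b = np.log(np.maximum(tot, 0.5) / s.sum())
    phi_col = phi[:, None]
    for _ in range(n_iter):
        mu = np.exp(b)[:, None] * s[None, :]
        w = 1.0 + phi_col * mu
        score = np.sum((y - mu) / w, axis=1)
        info = np.sum(mu * (1.0 + phi_col * y) / w**2, axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -2.0, 2.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.exp(b)


def estimate_dispersion(
    y: np.ndarray,
    s: np.ndarray,
    groups: Sequence[np.ndarray],
    floor: float = 1e-4,
    ceiling: float = 20.0,
    shrink_weight: float = 0.9,
    n_bins: int = 20,
) -> np.ndarray:
    """Moment dispersion on scaled counts, shrunk toward a trended fit.

    For each gene the raw estimate is (pooled within-group variance - mean) /
    mean^2 on library-size-scaled counts; it is floored, a mean-dispersion
    trend is fitted as a running mean over log-mean bins, and the per-gene
    value is shrunk toward the trend on the log scale with ``shrink_weight``.
    """
    ys = y / s[None, :]
    means, sses, dfs = [], [], 0
    grand = np.zeros(y.shape[0])
    n_total = 0
    for idx in groups:
        g = ys[:, idx]
        m = g.mean(axis=1)
        means.append((m, len(idx)))
        sses.append(((g - m[:, None]) ** 2).sum(axis=1))
        dfs += len(idx) - 1
        grand += m * len(idx)
        n_total += len(idx)
    grand /= n_total
    pooled_var = sum(sses) / max(dfs, 1)
    # scaling by 1/s inflates the Poisson part of the variance by mean(1/s)
    poisson_part = grand * np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - poisson_part) / np.maximum(grand, 1e-10) ** 2
    raw = np.clip(np.nan_to_num(raw, nan=floor), floor, ceiling)

    # trended fit: running mean of raw dispersion in log-mean bins
    logm = np.log(np.maximum(grand, 1e-10))
    order = np.argsort(logm)
    trend = np.full_like(raw, np.mean(raw))
    if len(raw) >= 10:
        bins = np.array_split(order, min(n_bins, max(1, len(raw) // 50)))
        centers, values = [], []
        for b in bins:
            if len(b):
                centers.append(logm[b].mean())
                values.append(raw[b].mean())
        if len(centers) >= 2:
            trend = np.interp(logm, centers, values)
        else:
            trend = np.full_like(raw, values[0])
    w = shrink_weight
    shrunk = np.exp(w * np.log(trend) + (1 - w) * np.log(raw))
    return np.clip(shrunk, floor, ceiling)


def _select_samples(
    meta: Sequence[SampleMeta], group: object
) -> list[str]:
    """Resolve a group spec (callable, (strain, diet) tuple, or id list)."""
    if callable(group):
        return [m.sample_id for m in meta if group(m)]
    if isinstance(group, tuple) and len(group) == 2:
        strain, diet = group
        return [
            m.sample_id
            for m in meta
            if (strain is None or m.strain == strain) and (diet is None or m.diet == diet)
        ]
    ids = {m.sample_id for m in meta}
    sel = [g for g in group if g in ids]  # type: ignore[union-attr]
    if len(sel) != len(list(group)):  # type: ignore[arg-type]
        raise ValueError("unknown sample ids in group specification")
    return sel


def nb_de_test(
    counts: CountsMatrix,
    meta: Sequence[SampleMeta],
    group_a: object,
    group_b: object,
    q_cut: float = Q_CUT,
    lfc_cut: float = LFC_CUT,
    pseudo: float = 0.5,
    shrink_weight: float = 0.9,
) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test per gene.

    Returns a DataFrame indexed by gene_id with columns log2fc, p, q, is_deg.
    Offsets use median-of-ratios size factors (mean 1); log2fc is
    log2((mean_B + pseudo) / (mean_A + pseudo)) on size-factor-scaled counts.
    """
    ids_a = _select_samples(meta, group_a)
    ids_b = _select_samples(meta, group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group must contain at least 2 samples")
    if set(ids_a) & set(ids_b):
        raise ValueError("groups overlap")

    sub = counts.counts[ids_a + ids_b]
    y = sub.values.astype(float)
    na = len(ids_a)
    idx_a = np.arange(na)
    idx_b = np.arange(na, na + len(ids_b))
    s = _trimmed_size_factors(y, idx_a, idx_b)

    phi = estimate_dispersion(y, s, [idx_a, idx_b], shrink_weight=shrink_weight)

    mu_null = _fit_nb_intercept(y, s, phi)
    mu_a = _fit_nb_intercept(y[:, idx_a], s[idx_a], phi)
    mu_b = _fit_nb_intercept(y[:, idx_b], s[idx_b], phi)

    ll_null = _nb_loglik(y, mu_null[:, None] * s[None, :], phi)
    ll_alt = (
        _nb_loglik(y[:, idx_a], mu_a[:, None] * s[None, idx_a], phi)
        + _nb_loglik(y[:, idx_b], mu_b[:, None] * s[None, idx_b], phi)
    )
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)

    mean_a = (y[:, idx_a] / s[None, idx_a]).mean(axis=1)
    mean_b = (y[:, idx_b] / s[None, idx_b]).mean(axis=1)
    log2fc = np.log2((mean_b + pseudo) / (mean_a + pseudo))

    all_zero = y.sum(axis=1) == 0
    p[all_zero] = 1.0
    log2fc[all_zero] = 0.0

    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "is_deg": (q < q_cut) & (np.abs(log2fc) > lfc_cut),
        },
        index=sub.index.rename("gene_id"),
    )


# ---------------------------------------------------------------------------


def hypergeometric_enrichment(
    deg_set: Iterable[str],
    pathways: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    p_cut: float = ENRICH_P,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a DEG set in each pathway.

    p = P(X >= k) with N universe genes, K pathway genes, n DEGs, k DEGs in
    the pathway. Pathway memberships are intersected with the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    degs = set(deg_set)
    if not degs <= universe:
        raise ValueError("deg_set must be a subset of the universe")
    N, n = len(universe), len(degs)
    rows = []
    for pid, members in pathways.items():
        mem = set(members) & universe
        K = len(mem)
        k = len(mem & degs)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"pathway_id": pid, "k": k, "K": K, "n": n, "N": N,
             "p": p, "significant": p < p_cut}
        )
    df = pd.DataFrame(rows, columns=["pathway_id", "k", "K", "n", "N", "p", "significant"])
    return df.sort_values(["p", "pathway_id"], kind="stable").reset_index(drop=True)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components ("PC1", ...)
    varexp: np.ndarray  # percentage of variance per component


def pca_top_variant(
    counts: CountsMatrix, top_n: int = 1000, pseudo: float = 1.0
) -> PCAResult:
    """PCA of log2(CPM + pseudo) restricted to the top_n most variant genes.

    Genes are ranked by variance across samples (ties broken by gene_id);
    rows are centred but not scaled, then decomposed by SVD.
    """
    if counts.counts.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    logcpm = np.log2(cpm(counts) + pseudo)
    var = logcpm.var(axis=1, ddof=1)
    if top_n > len(var):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(var)} available genes; using all",
            stacklevel=2,
        )
        top_n = len(var)
    ranking = (
        var.rename("var")
        .rename_axis("gene_id")
        .reset_index()
        .sort_values(["var", "gene_id"], ascending=[False, True], kind="stable")
    )
    top = ranking["gene_id"].iloc[:top_n]
    X = logcpm.loc[top]
    X = X.sub(X.mean(axis=1), axis=0)
    U, S, Vt = np.linalg.svd(X.values.T, full_matrices=False)
    scores = U * S
    varexp = 100.0 * S**2 / np.maximum((S**2).sum(), 1e-300)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(pd.DataFrame(scores, index=counts.samples, columns=cols), varexp)


@dataclass(frozen=True)
class CorrelationResult:
    gene_id: str
    r: float | None
    p: float | None
    n: int
    reason: str | None = None  # set when the correlation is undefined


def correlate_with_phenotype(
    expr_row: Sequence[float],
    phenotype: Sequence[float],
    gene_id: str = "",
) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value (n - 2 df)."""
    x = np.asarray(expr_row, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression and phenotype vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("correlation requires at least 3 paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(gene_id, None, None, n, reason="zero_variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(gene_id, float(res.statistic), float(res.pvalue), n)
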