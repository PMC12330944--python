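"""Sample-level and list-level gene-set enrichment.

The workhorse is a per-sample enrichment score in the GSVA style: every
gene's expression is first summarized *across* samples by a CDF-like
statistic (empirical CDF for rank-harmonized input, a Gaussian-kernel CDF
for raw abundance), genes are then ranked *within* each sample by that
statistic, and for every gene set a weighted Kolmogorov-Smirnov-like random
walk is taken down the ranked list — accumulating symmetric rank weights
inside the set against a uniform step outside it. The enrichment score is
either the sum of the walk's maximum positive and maximum negative
deviations ("diff_of_extremes", the default) or the single largest-magnitude
deviation ("max_deviation"); both are bounded in [-1, 1].

A preranked GSEA variant scores externally ordered gene lists (here: genes
ranked by their hazard ratio for overall survival) against gene sets, with a
gene-label permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gene_sets import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentParams",
    "gsva_scores",
    "preranked_gsea",
    "rescale_percent",
    "remove_gene_then_tpm",
    "tpm_normalize",
    "immune_marker_score",
    "IMMUNE_MARKERS",
    "DEFAULT_MARKER_ALIASES",
]


@dataclass(frozen=True)
class EnrichmentParams:
    """Tuning of the sample-level enrichment walk.

    tau
        Exponent on the symmetric rank weight inside the set; tau=1 weights
        genes linearly by how extreme their within-sample rank is.
    score_mode
        "diff_of_extremes" (max positive + max negative walk deviation) or
        "max_deviation" (signed largest-magnitude deviation).
    kcdf_mode
        "empirical" uses the empirical CDF of each gene across samples —
        appropriate for harmonized ranks, which already share a scale;
        "gaussian_kernel" smooths with a Gaussian kernel (bandwidth sd/4),
        for raw TPM input such as single-cell profiles.
    """

    tau: float = 1.0
    score_mode: str = "diff_of_extremes"
    kcdf_mode: str = "empirical"
    min_set_size: int = 5
    max_set_size: int | None = None

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.score_mode not in ("diff_of_extremes", "max_deviation"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        if self.kcdf_mode not in ("empirical", "gaussian_kernel"):
            raise ValueError(f"unknown kcdf_mode {self.kcdf_mode!r}")
        if self.min_set_size < 1:
            raise ValueError("min_set_size must be >= 1")


def _across_sample_stat(x: np.ndarray, mode: str) -> np.ndarray:
    """Per-gene across-sample CDF statistic (genes x samples in, same out)."""
    if mode == "empirical":
        # ECDF evaluated at each observation: (# values <= x_ij) / n
        order = x.argsort(axis=1, kind="stable")
        n = x.shape[1]
        z = np.empty_like(x)
        # handle ties: ecdf value is count of <=, i.e. max rank / n
        ranks = pd.DataFrame(x).rank(axis=1, method="max").to_numpy()
        z = ranks / n
        del order
        return z
    # gaussian kernel CDF, bandwidth sd/4 per gene
    sd = x.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1.0)
    z = np.empty_like(x, dtype=float)
    for i in range(x.shape[0]):  # row-wise to bound memory
        z[i] = norm.cdf((x[i][:, None] - x[i][None, :]) / h[i]).mean(axis=1)
    return z


def gsva_scores(
    x: pd.DataFrame,
    gs: GeneSetCollection,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Score every gene set in every sample with the enrichment random walk.

    Parameters
    ----------
    x
        Gene-by-sample matrix (harmonized ranks, or TPM with
        ``kcdf_mode="gaussian_kernel"``).
    gs
        Gene sets; each is intersected with ``x``'s gene universe and must
        keep at least ``params.min_set_size`` members.

    Returns
    -------
    Pathway-by-sample DataFrame of scores in [-1, 1].
    """
    params = params or EnrichmentParams()
    if x.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    if x.index.has_duplicates:
        raise ValueError("gene identifiers must be unique")
    # canonical gene order: ties in the per-sample ranking statistic are
    # broken lexicographically, making scores invariant to input gene order
    x = x.reindex(sorted(x.index))
    universe = list(x.index)
    gs = gs.filter_to_universe(universe, params.min_set_size, params.max_set_size)
    p = len(universe)
    for name, genes in gs.sets.items():
        if len(genes) >= p:
            raise ValueError(
                f"gene set {name!r} covers the whole gene universe; "
                "the enrichment walk is degenerate"
            )

    z = _across_sample_stat(x.to_numpy(dtype=float), params.kcdf_mode)
    # within-sample ordering by decreasing statistic, stable in gene order
    order = np.argsort(-z, axis=0, kind="stable")          # p x n
    # symmetric rank weight by position (1 = most expressed): |p/2 - pos|^tau
    positions = np.arange(1, p + 1, dtype=float)
    wpos = np.abs(p / 2.0 - positions) ** params.tau        # p
    gene_pos = {g: i for i, g in enumerate(universe)}

    n = x.shape[1]
    out = np.empty((len(gs), n))
    for si, (name, genes) in enumerate(gs.sets.items()):
        member = np.zeros(p, dtype=bool)
        member[[gene_pos[g] for g in genes]] = True
        m = member.sum()
        ind = member[order]                                 # p x n, sorted order
        w_in = wpos[:, None] * ind
        denom_in = w_in.sum(axis=0)
        num = np.cumsum(w_in, axis=0) / denom_in
        den = np.cumsum(~ind, axis=0) / float(p - m)
        nu = num - den
        if params.score_mode == "diff_of_extremes":
            out[si] = np.maximum(nu.max(axis=0), 0.0) + np.minimum(nu.min(axis=0), 0.0)
        else:
            hi, lo = nu.max(axis=0), nu.min(axis=0)
            out[si] = np.where(hi >= -lo, hi, lo)
    return pd.DataFrame(out, index=list(gs.sets), columns=x.columns)


def preranked_gsea(
    ranked_genes: pd.Series,
    gs: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    tau: float = 1.0,
    min_set_size: int = 5,
) -> pd.DataFrame:
    """Weighted-KS enrichment of gene sets in an externally ranked gene list.

    ``ranked_genes`` maps gene id -> ranking statistic (e.g. per-gene hazard
    ratio); genes are ordered by decreasing statistic. The null distribution
    is built by permuting gene labels (drawing random member positions) and
    the normalized enrichment score (NES) divides the observed score by the
    mean magnitude of same-sign null scores. The leading edge contains the
    member genes at or before (positive scores) / at or after (negative
    scores) the walk extremum.

    Returns a DataFrame indexed by set name with columns
    ``es, nes, p, size, leading_edge``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stat = ranked_genes.astype(float)
    if not np.isfinite(stat.to_numpy()).all():
        raise ValueError("ranking statistic must be finite for all genes")
    if stat.nunique() == 1:
        raise ValueError("ranking statistic is constant; no ordering exists")
    # deterministic ordering: decreasing statistic, gene id breaks ties
    ordering = sorted(stat.index, key=lambda g: (-stat[g], g))
    stat = stat.loc[ordering]
    p = len(stat)
    w = np.abs(stat.to_numpy()) ** tau
    gs = gs.filter_to_universe(ordering, min_set_size)
    rng = np.random.default_rng(seed)

    rows = []
    for name, genes in gs.sets.items():
        m = len(genes)
        if m >= p:
            raise ValueError(f"gene set {name!r} covers the whole ranked list")
        member = np.zeros(p, dtype=bool)
        pos_of = {g: i for i, g in enumerate(ordering)}
        member[[pos_of[g] for g in genes]] = True
        es, ext = _walk_es(w, member, p, m)

        null = np.empty(n_perm)
        picks = np.argsort(rng.random((n_perm, p)), axis=1)[:, :m]
        for b in range(n_perm):
            mb = np.zeros(p, dtype=bool)
            mb[picks[b]] = True
            null[b], _ = _walk_es(w, mb, p, m)
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size:
            pval = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + same.size)
            nes = es / np.mean(np.abs(same))
        else:
            pval, nes = 1.0 / (1 + n_perm), np.nan
        if es >= 0:
            lead = [g for g in ordering[: ext + 1] if g in set(genes)]
        else:
            lead = [g for g in ordering[ext:] if g in set(genes)]
        rows.append((name, es, nes, pval, m, lead))
    return pd.DataFrame(
        rows, columns=["set", "es", "nes", "p", "size", "leading_edge"]
    ).set_index("set")


def _walk_es(w: np.ndarray, member: np.ndarray, p: int, m: int):
    w_in = np.where(member, w, 0.0)
    denom = w_in.sum()
    if denom <= 0:  # all member stats exactly zero: fall back to equal weights
        w_in = member.astype(float)
        denom = float(m)
    nu = np.cumsum(w_in) / denom - np.cumsum(~member) / float(p - m)
    ext = int(np.argmax(np.abs(nu)))
    return float(nu[ext]), ext


def rescale_percent(
    s: pd.DataFrame, reference_samples=None
) -> pd.DataFrame:
    """Min-max rescale each pathway's scores to 0-100 over a reference set.

    Values outside the reference range clamp to 0 or 100. A pathway that is
    constant over the reference is an error.
    """
    ref = list(s.columns) if reference_samples is None else list(reference_samples)
    if not ref:
        raise ValueError("reference sample set is empty")
    ref_block = s[ref]
    lo = ref_block.min(axis=1)
    hi = ref_block.max(axis=1)
    flat = lo.index[(hi - lo) == 0].tolist()
    if flat:
        raise ValueError(f"pathways constant over the reference: {flat}")
    scaled = s.sub(lo, axis=0).div(hi - lo, axis=0).clip(0.0, 1.0) * 100.0
    return scaled


def tpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize a nonnegative matrix so each sample sums to 1e6."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    return counts.div(totals, axis=1) * 1e6


def remove_gene_then_tpm(counts: pd.DataFrame, gene_id: str) -> pd.DataFrame:
    """Drop one gene (e.g. contaminating hemoglobin, HBB) then TPM-normalize.

    Removing a dominant contaminant before normalization stops it from
    compressing every other gene's abundance. If the gene is absent the
    matrix is normalized as-is with a warning.
    """
    if gene_id in counts.index:
        counts = counts.drop(index=gene_id)
    else:
        warnings.warn(f"gene {gene_id!r} not present; nothing removed", stacklevel=2)
    return tpm_normalize(counts)


IMMUNE_MARKERS = ("CD45", "CD14", "CD16", "CD11b", "CD27", "CD3")

#: protein name -> candidate gene symbols, tried in order after the name itself
DEFAULT_MARKER_ALIASES: dict[str, tuple[str, ...]] = {
    "CD45": ("PTPRC",),
    "CD16": ("FCGR3A", "FCGR3B"),
    "CD11b": ("ITGAM",),
    "CD3": ("CD3E", "CD3D", "CD3G"),
}


def immune_marker_score(
    x: pd.DataFrame,
    markers=IMMUNE_MARKERS,
    aliases: dict | None = None,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sample immune content: sum of log2 expression of six markers.

    Markers are the leukocyte antigens CD45, CD14, CD16, CD11b, CD27 and
    CD3; each is resolved first by its own name, then through the alias
    table (protein name -> gene symbols). An unresolvable marker is an
    error listing everything missing.
    """
    aliases = DEFAULT_MARKER_ALIASES if aliases is None else aliases
    resolved: dict[str, str] = {}
    missing: list[str] = []
    for marker in markers:
        for cand in (marker, *aliases.get(marker, ())):
            if cand in x.index:
                resolved[marker] = cand
                break
        else:
            missing.append(marker)
    if missing:
        raise KeyError(f"markers unresolvable in the gene universe: {missing}")
    block = x.loc[[resolved[m] for m in markers]].to_numpy(dtype=float)
    score = np.log2(block + pseudocount).sum(axis=0)
    return pd.Series(score, index=x.columns, name="immune_score")
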