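"""Downstream statistics on OTU/ASV count tables.

Covers the post-clustering 16S workflow: low-abundance filtration, taxon
composition profiles (top-10 + "Others"), alpha diversity (Good's coverage,
Chao1, ACE, Shannon, Gini–Simpson), exact rarefaction, binary-Jaccard beta
diversity, PCoA and NMDS ordination, UPGMA clustering, and a two-class
LEfSe-style biomarker scan (Kruskal–Wallis screen + bootstrapped LDA effect
size).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from scipy.stats import kruskal
from skbio import DistanceMatrix
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "FeatureTable",
    "OrdinationResult",
    "filter_low_abundance",
    "composition_profile",
    "alpha_diversity",
    "rarefaction_curve",
    "jaccard_distance_matrix",
    "pcoa",
    "nmds",
    "upgma",
    "cophenetic_distances",
    "lefse",
]

#: Table-wide relative-abundance cutoff for OTU filtration (0.005%).
DEFAULT_MIN_FRACTION = 0.00005

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_RANK_PREFIX = dict(zip(RANKS, ("k__", "p__", "c__", "o__", "f__", "g__")))


@dataclass
class FeatureTable:
    """Sample x feature count table with taxonomy and group labels.

    ``counts`` is a samples-by-features DataFrame of non-negative integers,
    ``groups`` maps each sample to its group label, and ``taxonomy``
    (optional) maps each feature to a greengenes-style lineage string
    ``"k__...;p__...;c__...;o__...;f__...;g__..."`` (ranks may be empty).
    """

    counts: pd.DataFrame
    groups: pd.Series
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts in feature table")
        missing = set(self.counts.index) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        self.groups = self.groups.loc[self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def features(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class OrdinationResult:
    """Coordinates plus either eigenvalues (PCoA) or stress (NMDS)."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray | None = None
    stress: float | None = None
    valid: bool = True
    converged: bool = True
    stress_sequence: list[float] = field(default_factory=list)
    method: str = ""


def filter_low_abundance(
    t: FeatureTable, min_fraction: float = DEFAULT_MIN_FRACTION
) -> FeatureTable:
    """Drop features whose table-wide total is below ``min_fraction`` of all
    reads; a feature sitting exactly on the threshold is kept."""
    grand = t.counts.to_numpy().sum()
    if grand <= 0:
        raise ValueError("feature table has no reads")
    totals = t.counts.sum(axis=0)
    keep = totals >= min_fraction * grand
    if not keep.any():
        warnings.warn("all features fall below the abundance threshold")
    tax = t.taxonomy.loc[keep[keep].index] if t.taxonomy is not None else None
    return FeatureTable(t.counts.loc[:, keep], t.groups.copy(), tax)


def taxon_at_rank(lineage: str, rank: str) -> str:
    prefix = _RANK_PREFIX[rank]
    for part in str(lineage).split(";"):
        part = part.strip()
        if part.startswith(prefix):
            name = part[len(prefix):].strip()
            return name if name else "Unassigned"
    return "Unassigned"


def composition_profile(
    t: FeatureTable, rank: str = "genus", top_n: int = 10
) -> pd.DataFrame:
    """Relative-abundance profile at a rank, top ``top_n`` taxa + "Others".

    Taxa are ranked by mean relative abundance across samples; everything
    beyond the top ``top_n`` is summed into an "Others" row.  Columns are
    samples and each column sums to 1.
    """
    if t.taxonomy is None:
        raise ValueError("feature table has no taxonomy")
    taxa = t.taxonomy.map(lambda s: taxon_at_rank(s, rank))
    if (taxa == "Unassigned").all():
        raise ValueError(f"no feature is annotated at rank {rank!r}")
    agg = t.counts.T.groupby(taxa.loc[t.counts.columns]).sum()  # taxa x samples
    rel = agg / agg.sum(axis=0)
    order = rel.mean(axis=1).sort_values(ascending=False).index
    top = [x for x in order[:top_n]]
    rest = [x for x in order[top_n:]]
    out = rel.loc[top]
    if rest:
        out.loc["Others"] = rel.loc[rest].sum(axis=0)
    return out


def _freq_counts(counts: np.ndarray) -> tuple[np.ndarray, int, int]:
    c = np.asarray(counts)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector")
    return c, int(c.sum()), int(c.size)


def alpha_diversity(
    counts,
    chao1_bias_corrected: bool = True,
    simpson_gini: bool = True,
    ace_rare_cutoff: int = 10,
) -> dict[str, float]:
    """Alpha-diversity panel for one sample.

    Returns ``{"coverage", "chao1", "ace", "shannon", "simpson"}`` where

    - coverage : Good's coverage ``1 - F1/N`` (F1 = singletons, N = reads);
    - chao1    : ``S + F1(F1-1)/(2(F2+1))`` (bias-corrected, default) or the
      classic ``S + F1^2/(2 F2)`` when ``chao1_bias_corrected=False`` and
      doubletons exist (falls back to the bias-corrected form at F2 = 0);
    - ace      : Chao–Lee estimator with rare/abundant cutoff
      ``ace_rare_cutoff`` reads, ``C_ace = 1 - F1/N_rare`` and coefficient of
      variation ``gamma^2`` floored at 0; a degenerate ``C_ace = 0`` (or
      ``N_rare < 2``) falls back to Chao1 with a warning;
    - shannon  : ``-sum p ln p`` (natural log);
    - simpson  : Gini–Simpson ``1 - sum p^2`` (default; the classic dominance
      ``sum p^2`` with ``simpson_gini=False``).
    """
    c, n_reads, s_obs = _freq_counts(counts)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())

    coverage = 1.0 - f1 / n_reads

    chao1_bc = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if chao1_bias_corrected or f2 == 0:
        chao1 = chao1_bc
    else:
        chao1 = s_obs + f1 * f1 / (2.0 * f2)

    rare = c[c <= ace_rare_cutoff]
    s_abund = int((c > ace_rare_cutoff).sum())
    s_rare = int(rare.size)
    n_rare = int(rare.sum())
    if s_rare == 0:
        ace = float(s_obs)
    else:
        c_ace = 1.0 - f1 / n_rare
        if c_ace <= 0 or n_rare < 2:
            warnings.warn("degenerate ACE coverage; falling back to Chao1")
            ace = chao1
        else:
            ssum = float(sum(i * (i - 1) * (rare == i).sum()
                             for i in range(1, ace_rare_cutoff + 1)))
            gamma2 = max(
                s_rare * ssum / (c_ace * n_rare * (n_rare - 1)) - 1.0, 0.0
            )
            ace = s_abund + s_rare / c_ace + f1 / c_ace * gamma2

    p = c / n_reads
    shannon = float(-(p * np.log(p)).sum())
    sum_p2 = float((p * p).sum())
    simpson = 1.0 - sum_p2 if simpson_gini else sum_p2

    return {
        "coverage": coverage,
        "chao1": float(chao1),
        "ace": float(ace),
        "shannon": shannon,
        "simpson": simpson,
    }


def _log_choose(a: np.ndarray, b: float) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Exact expected richness ``E[S_n]`` at each subsampling depth.

    ``E[S_n] = S - sum_i C(N - N_i, n) / C(N, n)``, evaluated in log space.
    Depths above the sample's read total raise an error.
    """
    c, n_reads, s_obs = _freq_counts(counts)
    depths = np.asarray(depths, dtype=int)
    if (depths > n_reads).any():
        raise ValueError("rarefaction depth exceeds the sample's read count")
    if (depths < 0).any():
        raise ValueError("negative rarefaction depth")
    out = np.empty(depths.shape, dtype=float)
    for j, n in enumerate(depths):
        rem = n_reads - c  # reads left if taxon i is excluded
        ok = rem >= n
        terms = np.exp(_log_choose(rem[ok].astype(float), float(n))
                       - _log_choose(float(n_reads), float(n)))
        out[j] = s_obs - terms.sum()
    return out


def jaccard_distance_matrix(t: FeatureTable) -> DistanceMatrix:
    """Binary (presence/absence) Jaccard distances between samples.

    ``d = 1 - |A ∩ B| / |A ∪ B|``; two samples with no features at all are at
    distance 0.
    """
    if len(t.samples) < 2:
        raise ValueError("need at least 2 samples")
    presence = (t.counts.to_numpy() > 0).astype(float)
    inter = presence @ presence.T
    sizes = presence.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=t.samples)


def _as_distance_matrix(d) -> DistanceMatrix:
    if isinstance(d, DistanceMatrix):
        return d
    d = np.asarray(d, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    return DistanceMatrix(d)


def pcoa(d) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Gower-centres ``-D^2/2``, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues.  Eigenvalues are reported in
    non-increasing order including negative ones; only positive eigenvalues
    contribute coordinate axes.
    """
    dm = _as_distance_matrix(d)
    dd = dm.data
    n = dd.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dd * dd) @ j
    w, v = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > max(w.max(), 0) * 1e-12
    coords = v[:, pos] * np.sqrt(w[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=w,
        method="pcoa",
    )


def _kruskal_stress(d_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = float((d_config**2).sum())
    if denom == 0:
        return np.inf
    return float(np.sqrt(((d_config - disparities) ** 2).sum() / denom))


def nmds(
    d,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> OrdinationResult:
    """Non-metric MDS by majorization (SMACOF) with isotonic disparities.

    Minimizes Kruskal stress-1
    ``sqrt(sum (d_ij - dhat_ij)^2 / sum d_ij^2)`` where ``d`` are
    configuration distances and ``dhat`` the monotone (isotonic) regression
    of ``d`` on the observed dissimilarity order (ties averaged).  The best of
    one PCoA start plus ``n_starts`` random starts is returned; within a run
    iteration stops as soon as stress fails to decrease, so the recorded
    stress trajectory is non-increasing.  ``valid`` flags stress < 0.2.
    """
    dm = _as_distance_matrix(d)
    n = dm.shape[0]
    if n < 4 and k >= 2:
        raise ValueError("NMDS with k>=2 needs at least 4 samples")
    delta = squareform(dm.data, checks=False)
    rng = np.random.default_rng(seed)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    def run(x0: np.ndarray) -> tuple[np.ndarray, float, list[float], bool]:
        x = x0.copy()
        seq: list[float] = []
        best_x, best_s = x, np.inf
        converged = False
        for _ in range(max_iter):
            dc = pdist(x)
            dc = np.maximum(dc, 1e-12)
            dhat = iso.fit_transform(delta, dc)
            s = _kruskal_stress(dc, dhat)
            if seq and s >= seq[-1] - tol:
                if s < best_s:
                    best_x, best_s = x, s
                    seq.append(s)
                converged = True
                break
            seq.append(s)
            if s < best_s:
                best_x, best_s = x, s
            if s < 1e-12:
                converged = True
                break
            # Guttman transform with unit weights
            ratio = squareform(dhat / dc, checks=False)
            bmat = -ratio
            np.fill_diagonal(bmat, ratio.sum(axis=1))
            x = bmat @ x / n
            # stress-1 is scale-invariant; pin the configuration scale so
            # the iteration cannot drift into a numerically collapsed
            # (all-distances-clamped) configuration
            x -= x.mean(axis=0)
            rms = np.sqrt((pdist(x) ** 2).mean())
            if rms > 0:
                x *= np.sqrt((delta**2).mean()) / rms
        return best_x, best_s, seq, converged

    starts = [pcoa(dm).coordinates.to_numpy()[:, :k]]
    if starts[0].shape[1] < k:  # degenerate PCoA: pad with zeros
        pad = np.zeros((n, k - starts[0].shape[1]))
        starts[0] = np.hstack([starts[0], pad])
    starts += [rng.standard_normal((n, k)) for _ in range(n_starts)]

    best = None
    for x0 in starts:
        x, s, seq, conv = run(x0)
        if best is None or s < best[1]:
            best = (x, s, seq, conv)
    x, s, seq, conv = best
    if not conv:
        warnings.warn("NMDS did not converge; returning best configuration")
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(x, index=list(dm.ids), columns=cols),
        stress=s,
        valid=bool(s < 0.2),
        converged=conv,
        stress_sequence=seq,
        method="nmds",
    )


def _newick(node: int, n: int, z: np.ndarray, heights: np.ndarray,
            labels: list[str], parent_h: float) -> str:
    if node < n:
        return f"{labels[node]}:{parent_h:g}"
    i = node - n
    a, b = int(z[i, 0]), int(z[i, 1])
    h = heights[i]

    def min_leaf(x: int) -> str:
        if x < n:
            return labels[x]
        j = x - n
        return min(min_leaf(int(z[j, 0])), min_leaf(int(z[j, 1])))

    children = sorted((a, b), key=min_leaf)
    inner = ",".join(_newick(c, n, z, heights, labels, h) for c in children)
    return f"({inner}):{parent_h - h:g}"


def upgma(d) -> tuple[str, pd.DataFrame]:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Returns a rooted Newick string with branch lengths (node height = half
    the merge distance, so cophenetic distances reproduce ultrametric inputs
    exactly) and the merge table.  Child order inside each clade is
    deterministic (by smallest leaf label).
    """
    dm = _as_distance_matrix(d)
    labels = list(dm.ids)
    if len(labels) < 2:
        raise ValueError("need at least 2 samples")
    z = linkage(squareform(dm.data, checks=False), method="average")
    heights = z[:, 2] / 2.0
    n = len(labels)
    root = 2 * n - 2
    i = root - n
    a, b = int(z[i, 0]), int(z[i, 1])
    h = heights[i]

    def min_leaf(x: int) -> str:
        if x < n:
            return labels[x]
        j = x - n
        return min(min_leaf(int(z[j, 0])), min_leaf(int(z[j, 1])))

    children = sorted((a, b), key=min_leaf)
    inner = ",".join(_newick(c, n, z, heights, labels, h) for c in children)
    newick = f"({inner});"
    merges = pd.DataFrame(z, columns=["left", "right", "distance", "size"])
    return newick, merges


def cophenetic_distances(d) -> DistanceMatrix:
    """Cophenetic distance matrix implied by the UPGMA tree of ``d``."""
    dm = _as_distance_matrix(d)
    z = linkage(squareform(dm.data, checks=False), method="average")
    return DistanceMatrix(squareform(cophenet(z)), ids=list(dm.ids))


def lefse(
    t: FeatureTable,
    alpha: float = 0.05,
    lda_min: float = 2.0,
    n_boot: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-class LEfSe-style biomarker discovery.

    Per feature, on relative abundances scaled to 1e6: (1) Kruskal–Wallis
    screen at ``alpha``; (2) for screened features, over ``n_boot`` bootstrap
    resamples (within-class, with replacement) fit a one-feature LDA and
    average ``(|class-mean gap along the discriminant| + |raw class-mean
    gap|) / 2``; the effect size is ``log10`` of that average, floored at 1
    (so effects are >= 0).  ``significant`` requires both the screen and
    ``lda_effect >= lda_min``; ``enriched_group`` is the group with the
    higher mean.

    This is a documented reimplementation variant (two classes only, fixed
    1e6 scaling, bootstrap averaging); bit-parity with the original tool is
    out of scope.
    """
    glabels = pd.unique(t.groups)
    if len(glabels) != 2:
        raise ValueError(f"lefse requires exactly 2 groups, got {list(glabels)}")
    idx0 = np.flatnonzero((t.groups == glabels[0]).to_numpy())
    idx1 = np.flatnonzero((t.groups == glabels[1]).to_numpy())
    if len(idx0) < 3 or len(idx1) < 3:
        raise ValueError("lefse needs at least 3 samples per group")

    counts = t.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("sample with zero reads")
    x = counts / totals * 1e6

    rng = np.random.default_rng(seed)
    rows = []
    for f, feat in enumerate(t.features):
        a, b = x[idx0, f], x[idx1, f]
        if np.ptp(np.concatenate([a, b])) == 0:
            kw_p = 1.0
        else:
            kw_p = float(kruskal(a, b).pvalue)
        m0, m1 = a.mean(), b.mean()
        enriched = glabels[0] if m0 >= m1 else glabels[1]
        effect = np.nan
        significant = False
        if kw_p < alpha:
            effs = np.empty(n_boot)
            for bi in range(n_boot):
                ra = a[rng.integers(0, len(a), len(a))]
                rb = b[rng.integers(0, len(b), len(b))]
                raw = abs(ra.mean() - rb.mean())
                xs = np.concatenate([ra, rb])[:, None]
                ys = np.r_[np.zeros(len(ra)), np.ones(len(rb))]
                if np.ptp(xs) == 0:
                    proj = 0.0
                else:
                    try:
                        lda = LinearDiscriminantAnalysis(solver="eigen")
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            lda.fit(xs, ys)
                        w = float(lda.scalings_[0, 0])
                        proj = abs((ra.mean() - rb.mean()) * w)
                    except Exception:  # singular within-class scatter
                        proj = raw
                effs[bi] = (proj + raw) / 2.0
            effect = float(np.log10(max(effs.mean(), 1.0)))
            significant = effect >= lda_min
        rows.append(
            {
                "feature": feat,
                "kw_p": kw_p,
                "lda_effect": effect,
                "enriched_group": enriched,
                "significant": significant,
            }
        )
    return pd.DataFrame(rows).set_index("feature")
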