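"""Surrogate ground-truth labels, clustering evaluation, cluster-specific
features, cross-condition subpopulation linking, and marker-pattern
distances.

Surrogate labels assign single cells to FACS-sorted bulk reference cell
types (top specifically-expressed genes for RNA, quantile-normalized open
peak counts for ATAC), providing validation labels without manual
annotation.  Clustering is evaluated by Hungarian one-to-one matching of
clusters to labels (accuracy, per-class accuracy) and normalized mutual
information.  Subpopulations are linked across conditions by the mapping
score: the observed Pearson correlation of cluster profiles minus its
marginal expectation, linked when positive in both modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import normalized_mutual_info_score, silhouette_samples

from .coupled_clustering import quantile_normalize

__all__ = [
    "BulkReference",
    "MappingScoreMatrix",
    "surrogate_labels_rna",
    "surrogate_labels_atac",
    "match_clusters",
    "cluster_specific_features",
    "link_subpopulations",
    "mapping_scores",
    "marker_pattern_distance",
    "hellinger",
    "silhouette_eval",
]

AMBIGUOUS = "ambiguous"   # label for argmax ties / cells matching nothing


@dataclass
class BulkReference:
    """Bulk reference profiles for surrogate ground-truth labelling.

    ``rna_profiles`` is gene x celltype; ``atac_peak_sets`` maps celltype ->
    interval frame (chrom, start, end).  ``merge_map`` optionally collapses
    reference cell types to coarser labels (e.g. all progenitors -> one).
    """

    rna_profiles: pd.DataFrame | None = None
    atac_peak_sets: dict[str, pd.DataFrame] = field(default_factory=dict)
    merge_map: dict[str, str] = field(default_factory=dict)

    def merged(self, label: str) -> str:
        return self.merge_map.get(label, label)


@dataclass
class MappingScoreMatrix:
    """Cluster(cond1) x cluster(cond2) mapping scores per modality."""

    rna_scores: pd.DataFrame
    atac_scores: pd.DataFrame
    links: list[tuple] = field(default_factory=list)
    confidence: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Surrogate labels
# ---------------------------------------------------------------------------

def surrogate_labels_rna(
    sc_expr: pd.DataFrame,
    ref: BulkReference,
    n_top: int = 1000,
) -> np.ndarray:
    """Label cells by the reference type whose signature they express most.

    Per type, specificity = bulk expression / median across types; the
    ``n_top`` most specific genes form the signature.  Each cell is labelled
    with the type for which the largest number of signature genes is
    expressed (count > 0); ties or all-zero matches give ``ambiguous``.
    """
    if ref.rna_profiles is None:
        raise ValueError("reference has no RNA profiles")
    bulk = ref.rna_profiles
    shared = [g for g in bulk.index if g in sc_expr.index]
    bulk = bulk.loc[shared]
    med = bulk.median(axis=1).to_numpy()
    spec = bulk.to_numpy() / np.maximum(med, 1e-12)[:, None]

    types = list(bulk.columns)
    signatures = {}
    for j, t in enumerate(types):
        order = np.argsort(-spec[:, j], kind="stable")[:n_top]
        signatures[t] = [shared[i] for i in order]
        if len(signatures[t]) < 50:
            warnings.warn(
                f"only {len(signatures[t])} signature genes for type {t!r} "
                "present in the single-cell data", stacklevel=2,
            )

    expressed = sc_expr.loc[shared].to_numpy() > 0        # genes x cells
    gene_pos = {g: i for i, g in enumerate(shared)}
    counts = np.zeros((len(types), sc_expr.shape[1]), dtype=int)
    for j, t in enumerate(types):
        idx = [gene_pos[g] for g in signatures[t]]
        counts[j] = expressed[idx].sum(axis=0)
    return _argmax_or_ambiguous(counts, [ref.merged(t) for t in types])


def surrogate_labels_atac(
    sc_acc: pd.DataFrame,
    ref: BulkReference,
    peak_coords: pd.DataFrame | None = None,
) -> np.ndarray:
    """Label cells by quantile-normalized open-peak counts per reference type.

    c_ij = number of open (count > 0) peaks of type j in cell i; the count
    matrix is quantile-normalized across type columns to remove the bias
    from unequal reference peak-set sizes, then each cell takes the argmax
    type.  Single-cell peaks are matched to reference peak sets by interval
    overlap using ``peak_coords`` (chrom, start, end per sc peak; defaults
    to parsing ids like ``chr1:100-200``).
    """
    if not ref.atac_peak_sets:
        raise ValueError("reference has no ATAC peak sets")
    if peak_coords is None:
        peak_coords = _parse_peak_ids(list(sc_acc.index))
    types = list(ref.atac_peak_sets)
    membership = np.zeros((len(sc_acc.index), len(types)), dtype=bool)
    for j, t in enumerate(types):
        membership[:, j] = _overlaps_any(peak_coords, ref.atac_peak_sets[t])

    open_ = (sc_acc.to_numpy() > 0)                        # peaks x cells
    C = (membership.T.astype(float) @ open_.astype(float)).T   # cells x types
    no_overlap = C.sum(axis=1) == 0
    Cn = quantile_normalize(C.T).T                          # normalize across type columns
    labels = _argmax_or_ambiguous(Cn.T, [ref.merged(t) for t in types])
    labels[no_overlap] = AMBIGUOUS
    return labels


def _argmax_or_ambiguous(scores: np.ndarray, type_names: list[str]) -> np.ndarray:
    """Argmax over rows (types) per column (cell); exact ties -> ambiguous."""
    # merge rows that map to the same (merged) label first
    frame = pd.DataFrame(scores, index=type_names).groupby(level=0).sum()
    arr = frame.to_numpy()
    names = np.array(frame.index)
    best = arr.max(axis=0)
    n_best = (arr == best[None, :]).sum(axis=0)
    labels = names[arr.argmax(axis=0)].astype(object)
    labels[(n_best > 1) | (best <= 0)] = AMBIGUOUS
    return np.asarray(labels, dtype=object)


def _parse_peak_ids(ids: list[str]) -> pd.DataFrame:
    rows = []
    for pid in ids:
        chrom, rest = pid.split(":")
        start, end = rest.replace("-", ":").split(":")
        rows.append((chrom, int(start), int(end)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"], index=ids)


def _overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Whether each query interval overlaps any target interval (half-open)."""
    out = np.zeros(len(query), dtype=bool)
    for chrom, tgt in targets.groupby("chrom"):
        sel = query["chrom"] == chrom
        if not sel.any():
            continue
        starts = np.sort(tgt["start"].to_numpy())
        order = np.argsort(tgt["start"].to_numpy())
        ends = tgt["end"].to_numpy()[order]
        # max end among targets starting at or before the query end
        cummax_end = np.maximum.accumulate(ends)
        qs = query.loc[sel, "start"].to_numpy()
        qe = query.loc[sel, "end"].to_numpy()
        pos = np.searchsorted(starts, qe, side="left") - 1
        hit = (pos >= 0) & (cummax_end[np.maximum(pos, 0)] > qs)
        out[np.nonzero(sel.to_numpy())[0]] = hit
    return out


# ---------------------------------------------------------------------------
# Clustering evaluation
# ---------------------------------------------------------------------------

def match_clusters(pred_labels, true_labels) -> dict:
    """Hungarian one-to-one matching of clusters to true labels.

    Returns mapping (cluster -> truth), per-class accuracy
    accuracy_j = S_ij / sum_k S_kj for the matched cluster i, overall
    accuracy (fraction of correctly predicted cells under the matching) and
    NMI.  Extra clusters beyond the number of truth labels stay unmatched.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError("labelings must cover the same cells")
    S = pd.crosstab(pd.Series(pred, name="pred"), pd.Series(true, name="true"))
    cost = -S.to_numpy()
    ri, ci = linear_sum_assignment(cost)
    mapping = {S.index[i]: S.columns[j] for i, j in zip(ri, ci)}
    per_class = {}
    correct = 0
    for i, j in zip(ri, ci):
        col_total = S.to_numpy()[:, j].sum()
        per_class[S.columns[j]] = S.to_numpy()[i, j] / col_total if col_total else np.nan
        correct += S.to_numpy()[i, j]
    return {
        "mapping": mapping,
        "per_class_accuracy": per_class,
        "accuracy": correct / len(pred),
        "nmi": normalized_mutual_info_score(true, pred),
        "overlap": S,
        "unmatched_clusters": [c for c in S.index if c not in mapping],
    }


# ---------------------------------------------------------------------------
# Cluster-specific features
# ---------------------------------------------------------------------------

def cluster_specific_features(
    matrix: np.ndarray,
    labels: np.ndarray,
    modality: str,
    feature_ids: list[str] | None = None,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Cluster specificity score -log10(p) * fold-change per feature/cluster.

    ATAC: features binarized (open = count > 0), one-sided Fisher exact test
    (hypergeometric enrichment of openness in the cluster).  RNA: one-tailed
    two-sample t-test (cluster vs rest, greater).  Fold change uses a
    pseudocount on the denominator: mean_in / (mean_out + 0.01).  p-values
    are floored at 1e-300 before the log.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels).tolist())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    if modality not in ("rna", "atac"):
        raise ValueError(f"modality must be 'rna' or 'atac', got {modality!r}")
    ids = feature_ids if feature_ids is not None else list(range(X.shape[0]))

    records = []
    for c in clusters:
        in_ = labels == c
        n_in, n_out = int(in_.sum()), int((~in_).sum())
        if modality == "atac":
            open_ = X > 0
            a = open_[:, in_].sum(axis=1)          # open in cluster
            total_open = open_.sum(axis=1)
            # one-sided Fisher = hypergeometric upper tail
            p = stats.hypergeom.sf(a - 1, n_in + n_out, total_open, n_in)
            mean_in = a / n_in
            mean_out = (total_open - a) / n_out
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                t, p2 = stats.ttest_ind(X[:, in_], X[:, ~in_], axis=1, equal_var=False)
            t = np.nan_to_num(t, nan=0.0)
            # one-tailed (greater in cluster)
            p = np.where(np.isnan(p2), 1.0, np.where(t > 0, p2 / 2, 1 - p2 / 2))
            mean_in = X[:, in_].mean(axis=1)
            mean_out = X[:, ~in_].mean(axis=1)
        p = np.maximum(p, 1e-300)
        fc = mean_in / (mean_out + pseudocount)
        score = -np.log10(p) * fc
        records.append(pd.DataFrame({
            "feature": ids, "cluster": c, "pvalue": p, "fold_change": fc,
            "score": score,
        }))
    out = pd.concat(records, ignore_index=True)
    out["rank"] = out.groupby("cluster")["score"].rank(ascending=False, method="first")
    return out


# ---------------------------------------------------------------------------
# Subpopulation linking
# ---------------------------------------------------------------------------

def mapping_scores(profiles1: pd.DataFrame, profiles2: pd.DataFrame) -> pd.DataFrame:
    """Observed-minus-expected Pearson correlation between cluster profiles.

    score_ij = r_ij - (sum_i r_ij)(sum_j r_ij) / (sum_ij r_ij), with r the
    PCC of the i-th cond-1 and j-th cond-2 cluster profiles over shared
    features.  Constant profiles give undefined correlations; their scores
    are set to -inf (they can never link) with a warning.
    """
    shared = [f for f in profiles1.index if f in profiles2.index]
    if not shared:
        raise ValueError("profiles share no features")
    P1 = profiles1.loc[shared]
    P2 = profiles2.loc[shared]
    r = np.zeros((P1.shape[1], P2.shape[1]))
    bad = False
    for i, c1 in enumerate(P1.columns):
        for j, c2 in enumerate(P2.columns):
            x, y = P1[c1].to_numpy(float), P2[c2].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                r[i, j] = np.nan
                bad = True
            else:
                r[i, j] = np.corrcoef(x, y)[0, 1]
    if bad:
        warnings.warn("constant cluster profile(s): correlations undefined", stacklevel=2)
    total = np.nansum(r)
    expected = np.nansum(r, axis=1)[:, None] * np.nansum(r, axis=0)[None, :] / total \
        if total != 0 else np.zeros_like(r)
    score = r - expected
    score[np.isnan(score)] = -np.inf
    return pd.DataFrame(score, index=P1.columns, columns=P2.columns)


def link_subpopulations(
    profiles1_rna: pd.DataFrame,
    profiles2_rna: pd.DataFrame,
    profiles1_atac: pd.DataFrame,
    profiles2_atac: pd.DataFrame,
) -> MappingScoreMatrix:
    """Link cluster i (cond 1) to cluster j (cond 2) when both the RNA and
    the ATAC mapping score are positive; confidence is their sum."""
    s_rna = mapping_scores(profiles1_rna, profiles2_rna)
    s_atac = mapping_scores(profiles1_atac, profiles2_atac)
    if list(s_rna.index) != list(s_atac.index) or list(s_rna.columns) != list(s_atac.columns):
        raise ValueError("RNA and ATAC profiles must cover the same clusters")
    links, conf = [], {}
    for i in s_rna.index:
        for j in s_rna.columns:
            if s_rna.loc[i, j] > 0 and s_atac.loc[i, j] > 0:
                links.append((i, j))
                conf[(i, j)] = float(s_rna.loc[i, j] + s_atac.loc[i, j])
    return MappingScoreMatrix(rna_scores=s_rna, atac_scores=s_atac,
                              links=links, confidence=conf)


# ---------------------------------------------------------------------------
# Marker patterns and silhouette
# ---------------------------------------------------------------------------

def hellinger(p: np.ndarray, q: np.ndarray) -> float:
    """Hellinger distance (1/sqrt(2)) * ||sqrt(p) - sqrt(q)||_2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.linalg.norm(np.sqrt(p) - np.sqrt(q)) / np.sqrt(2.0))


def marker_pattern_distance(
    expr: pd.DataFrame,
    marker_genes: list[str],
    group_labels: np.ndarray,
) -> pd.DataFrame:
    """Pairwise Hellinger distances between marker-pattern distributions.

    Markers are binarized (expressed = count > 0); each group's cells are
    tallied over the 2^m joint on/off patterns and groups are compared by
    the Hellinger distance between those frequency vectors.
    """
    missing = [g for g in marker_genes if g not in expr.index]
    if missing:
        raise ValueError(f"markers absent from expression matrix: {missing}")
    groups = list(pd.unique(np.asarray(group_labels)))
    bits = (expr.loc[marker_genes].to_numpy() > 0).astype(int)    # m x cells
    pattern = np.zeros(bits.shape[1], dtype=int)
    for row in bits:
        pattern = pattern * 2 + row
    n_patterns = 2 ** len(marker_genes)
    dists = {}
    for g in groups:
        cells = np.asarray(group_labels) == g
        if cells.sum() < 10:
            warnings.warn(f"group {g!r} has fewer than 10 cells", stacklevel=2)
        counts = np.bincount(pattern[cells], minlength=n_patterns).astype(float)
        dists[g] = counts / counts.sum()
    out = pd.DataFrame(0.0, index=groups, columns=groups)
    for a in groups:
        for b in groups:
            out.loc[a, b] = hellinger(dists[a], dists[b])
    return out


def silhouette_eval(coords: np.ndarray, labels: np.ndarray) -> dict:
    """Per-cell silhouette on Euclidean distances plus the mean summary.

    Singleton clusters get silhouette 0 for their cell (flagged).
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least two labels")
    singletons = set(uniq[counts == 1])
    if singletons:
        keep = ~np.isin(labels, list(singletons))
        values = np.zeros(len(labels))
        values[keep] = silhouette_samples(coords[keep], labels[keep])
    else:
        values = silhouette_samples(coords, labels)
    return {
        "values": values,
        "mean": float(values.mean()),
        "singleton_clusters": sorted(map(str, singletons)),
    }


def compare_silhouettes(values_a: np.ndarray, values_b: np.ndarray) -> dict:
    """Paired sign-rank comparison of two per-cell silhouette vectors."""
    stat, p = stats.wilcoxon(values_a, values_b)
    return {"statistic": float(stat), "pvalue": float(p),
            "mean_difference": float(np.mean(values_a) - np.mean(values_b))}
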