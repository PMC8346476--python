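"""TF regulatory potential (TFRP) and the peak-gene coupling matrix.

The TFRP of TF *i* on TG *j* in cell *t* is

    TFRP_ijt = TF_it * sum_k B_ik * RE_kt * I_kj

where TF_it is the TF's expression in cell t, B_ik the motif-binding
strength of the TF in RE k, RE_kt the subpopulation-level accessibility of
RE k in the subpopulation cell t belongs to, and I_kj the RE-TG interaction
strength.  The coupling matrix used by coupled clustering weights each
gene-peak pair by context correlation and exponential distance decay,
A_gj = max(R_gj, 0) * exp(-d_gj / d0), with d the peak-midpoint-to-TSS
distance and d0 = 40 kb by default.

Internally TFs are indexed by ``k``, REs by ``r`` and TGs by ``j``; the
formulas above quote the conventional symbols.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "RegulatoryPrior",
    "CouplingMatrix",
    "TfrpMatrix",
    "build_coupling_matrix",
    "cluster_accessibility_profiles",
    "compute_tfrp",
    "baseline_regulator_signal",
]

DEFAULT_D0 = 40_000.0          # bp, decay scale of the distance penalty
DEFAULT_DISTANCE_CUTOFF = 1_000_000.0   # beyond 1 Mb exp(-d/d0) < 2e-11 at default d0


@dataclass
class RegulatoryPrior:
    """Motif-binding and RE-TG interaction priors plus coordinates.

    ``B`` is TF x RE (nonnegative motif binding strengths), ``I`` is
    RE x TG.  ``peak_coords`` is a frame with columns (chrom, start, end)
    indexed by peak id (BED convention, 0-based half-open); ``tss_coords``
    has columns (chrom, pos) indexed by gene id.  ``context_corr`` is an
    optional gene x peak correlation matrix across cellular contexts;
    negative entries are floored at zero.  When absent, the coupling matrix
    falls back to pure distance decay.
    """

    B: pd.DataFrame                      # TF x RE
    I: pd.DataFrame                      # RE x TG
    peak_coords: pd.DataFrame | None = None
    tss_coords: pd.DataFrame | None = None
    context_corr: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.B.to_numpy() < 0).any():
            raise ValueError("motif binding strengths B must be nonnegative")
        if (self.I.to_numpy() < 0).any():
            raise ValueError("interaction strengths I must be nonnegative")


@dataclass
class CouplingMatrix:
    """Gene x peak coupling weights with their decay scale."""

    A: sparse.csr_matrix
    gene_ids: list[str]
    peak_ids: list[str]
    d0: float = DEFAULT_D0
    used_context_corr: bool = True   # False => distance-only fallback


@dataclass
class TfrpMatrix:
    """(TF, TG)-pair x cell TFRP values with cell annotations."""

    values: np.ndarray                       # n_pairs x n_cells
    pair_index: list[tuple[str, str]]
    cell_condition: np.ndarray | None = None
    cell_cluster: np.ndarray | None = None
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)


def _peak_midpoints(peak_coords: pd.DataFrame) -> pd.Series:
    return (peak_coords["start"] + peak_coords["end"]) / 2.0


def build_coupling_matrix(
    prior: RegulatoryPrior,
    d0: float = DEFAULT_D0,
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
) -> CouplingMatrix:
    """A_gj = max(R_gj, 0) * exp(-|peak midpoint - TSS| / d0), per chromosome.

    Entries beyond ``distance_cutoff`` or on different chromosomes are zero
    (and not stored).  Without ``context_corr`` the correlation term is 1
    and the result is flagged as a distance-only fallback.
    """
    if d0 <= 0:
        raise ValueError(f"d0 must be positive, got {d0}")
    if prior.peak_coords is None or prior.tss_coords is None:
        raise ValueError("peak and TSS coordinates are required to build A")
    peaks = prior.peak_coords
    tss = prior.tss_coords
    genes = list(tss.index)
    peak_ids = list(peaks.index)
    mid = _peak_midpoints(peaks).to_numpy()
    gpos = tss["pos"].to_numpy(dtype=float)

    corr = prior.context_corr
    if corr is not None:
        missing = [g for g in genes if g not in corr.index]
        if missing:
            raise ValueError(
                f"context_corr is missing {len(missing)} genes, e.g. {missing[:5]}"
            )

    rows, cols, vals = [], [], []
    peak_chrom = peaks["chrom"].to_numpy()
    gene_chrom = tss["chrom"].to_numpy()
    for chrom in np.unique(gene_chrom):
        gi = np.nonzero(gene_chrom == chrom)[0]
        pi = np.nonzero(peak_chrom == chrom)[0]
        if gi.size == 0 or pi.size == 0:
            continue
        d = np.abs(mid[pi][None, :] - gpos[gi][:, None])
        w = np.exp(-d / d0)
        w[d > distance_cutoff] = 0.0
        if corr is not None:
            r = np.maximum(
                corr.loc[tss.index[gi], [peak_ids[p] for p in pi]].to_numpy(dtype=float),
                0.0,
            )
            w = w * r
        r_idx, c_idx = np.nonzero(w)
        rows.extend(gi[r_idx])
        cols.extend(pi[c_idx])
        vals.extend(w[r_idx, c_idx])

    A = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(genes), len(peak_ids)), dtype=float
    )
    return CouplingMatrix(
        A=A, gene_ids=genes, peak_ids=peak_ids, d0=d0,
        used_context_corr=corr is not None,
    )


def cluster_accessibility_profiles(
    acc: np.ndarray,
    cluster_labels: np.ndarray,
    clusters: list | None = None,
) -> pd.DataFrame:
    """Mean accessibility of each RE within each cluster (RE x cluster).

    ``acc`` is RE x cell; every cell must carry a label.  Raises if a
    requested cluster is empty.
    """
    acc = np.asarray(acc, dtype=float)
    labels = np.asarray(cluster_labels)
    if labels.shape[0] != acc.shape[1]:
        raise ValueError("one label per cell required")
    if clusters is None:
        clusters = sorted(pd.unique(labels).tolist())
    profiles = {}
    for c in clusters:
        members = labels == c
        if not members.any():
            raise ValueError(f"cluster {c!r} has no cells")
        profiles[c] = acc[:, members].mean(axis=1)
    return pd.DataFrame(profiles)


def compute_tfrp(
    expr: pd.DataFrame,
    prior: RegulatoryPrior,
    re_profiles: pd.DataFrame,
    cell_cluster_map: np.ndarray,
    pairs: list[tuple[str, str]],
    cell_condition: np.ndarray | None = None,
) -> TfrpMatrix:
    """TFRP for every requested (TF, TG) pair and cell.

    ``expr`` is gene x cell (rows indexed by gene id), ``re_profiles`` is
    RE x cluster (from :func:`cluster_accessibility_profiles`), and
    ``cell_cluster_map`` assigns each cell to a column of ``re_profiles``.
    Pairs whose TF is absent from ``expr`` are skipped with a warning and
    recorded in ``skipped_pairs``.
    """
    labels = np.asarray(cell_cluster_map)
    if labels.shape[0] != expr.shape[1]:
        raise ValueError("cell_cluster_map must label every cell of expr")
    unknown = set(pd.unique(labels)) - set(re_profiles.columns)
    if unknown:
        raise ValueError(f"cells reference clusters without profiles: {sorted(unknown)!r}")

    re_ids = [r for r in re_profiles.index if r in prior.B.columns and r in prior.I.index]
    P = re_profiles.loc[re_ids].to_numpy(dtype=float)      # R x C
    col_of = {c: i for i, c in enumerate(re_profiles.columns)}
    cell_cols = np.array([col_of[c] for c in labels])

    kept_pairs: list[tuple[str, str]] = []
    skipped: list[tuple[str, str]] = []
    rows = []
    for tf, tg in pairs:
        if tf not in expr.index or tf not in prior.B.index or tg not in prior.I.columns:
            skipped.append((tf, tg))
            continue
        b = prior.B.loc[tf, re_ids].to_numpy(dtype=float)
        i_w = prior.I.loc[re_ids, tg].to_numpy(dtype=float)
        # per-cluster regulatory weight, then broadcast to cells via their cluster
        w_cluster = (b * i_w) @ P                           # (C,)
        rows.append(expr.loc[tf].to_numpy(dtype=float) * w_cluster[cell_cols])
        kept_pairs.append((tf, tg))
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} pairs with missing TF/TG, e.g. {skipped[:3]}",
            stacklevel=2,
        )
    values = np.vstack(rows) if rows else np.empty((0, expr.shape[1]))
    return TfrpMatrix(
        values=values, pair_index=kept_pairs,
        cell_condition=None if cell_condition is None else np.asarray(cell_condition),
        cell_cluster=labels, skipped_pairs=skipped,
    )


def baseline_regulator_signal(
    expr: pd.DataFrame,
    pairs: list[tuple[str, str]],
    cell_condition: np.ndarray | None = None,
    cell_cluster_map: np.ndarray | None = None,
) -> TfrpMatrix:
    """Expression-only baseline: the pair's signal is the raw TF expression."""
    kept, skipped, rows = [], [], []
    for tf, tg in pairs:
        if tf not in expr.index:
            skipped.append((tf, tg))
            continue
        rows.append(expr.loc[tf].to_numpy(dtype=float))
        kept.append((tf, tg))
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} pairs with missing TF, e.g. {skipped[:3]}",
            stacklevel=2,
        )
    values = np.vstack(rows) if rows else np.empty((0, expr.shape[1]))
    return TfrpMatrix(
        values=values, pair_index=kept,
        cell_condition=None if cell_condition is None else np.asarray(cell_condition),
        cell_cluster=None if cell_cluster_map is None else np.asarray(cell_cluster_map),
        skipped_pairs=skipped,
    )
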