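"""Readers/writers for the standard formats and the end-to-end pipeline.

Matrices travel as 10x-style Matrix Market bundles (matrix.mtx +
features.tsv + barcodes.tsv, optionally gzipped), peaks as BED (0-based
half-open), TSS tables as TSV with 1-based positions, and regulatory priors
as long-form TSV.  ``run_pipeline`` drives the full comparative analysis:
preprocess -> CoupledNMF per condition -> link subpopulations -> screen
differential TGs -> TFRP -> LR / Gamma null / BH -> differential networks,
writing a JSON manifest of everything it produced.
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import diffreg
from .coupled_clustering import (
    SingleCellMatrix,
    assign_clusters,
    coupled_nmf,
    preprocess,
)
from .population_tools import link_subpopulations
from .regulatory_potential import (
    RegulatoryPrior,
    compute_tfrp,
    baseline_regulator_signal,
)
from .simulate import SimulatedDataset

logger = logging.getLogger("sccompreg")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_bed",
    "read_tss",
    "read_long_tsv",
    "read_prior",
    "write_simulated_bundle",
    "expand_accessibility_to_cells",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Matrix Market bundles
# ---------------------------------------------------------------------------

def _find(dirpath: Path, names: list[str]) -> Path:
    for name in names:
        for cand in (dirpath / name, dirpath / (name + ".gz")):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {names} found in {dirpath}")


def _read_tsv_column(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df[0].tolist()


def read_mtx_bundle(dirpath: str | os.PathLike, modality: str = "rna") -> SingleCellMatrix:
    """Load a 10x-style bundle (matrix.mtx, features.tsv, barcodes.tsv).

    Accepts gzipped variants and the legacy ``genes.tsv`` name.  Duplicate
    feature ids are de-duplicated by suffixing ``.1``, ``.2``, ... (logged).
    """
    dirpath = Path(dirpath)
    mtx = _find(dirpath, ["matrix.mtx"])
    feats = _read_tsv_column(_find(dirpath, ["features.tsv", "genes.tsv", "peaks.tsv"]))
    barcodes = _read_tsv_column(_find(dirpath, ["barcodes.tsv"]))
    opener = gzip.open if mtx.suffix == ".gz" else open
    try:
        with opener(mtx, "rb") as fh:
            M = spio.mmread(fh)
    except ValueError as e:
        raise ValueError(f"malformed Matrix Market file {mtx}: {e}") from e
    M = sparse.csr_matrix(M)
    if M.shape != (len(feats), len(barcodes)):
        raise ValueError(
            f"matrix shape {M.shape} does not match {len(feats)} features x "
            f"{len(barcodes)} barcodes in {dirpath}"
        )
    if len(set(feats)) != len(feats):
        logger.info("de-duplicating feature ids in %s", dirpath)
        seen: dict[str, int] = {}
        out = []
        for f in feats:
            if f in seen:
                seen[f] += 1
                out.append(f"{f}.{seen[f]}")
            else:
                seen[f] = 0
                out.append(f)
        feats = out
    return SingleCellMatrix(
        values=np.asarray(M.todense(), dtype=float),
        feature_ids=feats, cell_ids=barcodes, modality=modality,
    )


def write_mtx_bundle(mat: SingleCellMatrix, dirpath: str | os.PathLike) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(dirpath / "matrix.mtx", sparse.coo_matrix(mat.values))
    pd.Series(mat.feature_ids).to_csv(dirpath / "features.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(mat.cell_ids).to_csv(dirpath / "barcodes.tsv", sep="\t",
                                   header=False, index=False)


# ---------------------------------------------------------------------------
# Coordinates and priors
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """BED3+ -> sorted frame (chrom, start, end), 0-based half-open.

    Peak ids are ``chrom:start-end``.  Raises (with the line number) on
    start >= end.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    bad = df["start"] >= df["end"]
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 1
        raise ValueError(f"{path}: start >= end at line {line}")
    df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    df.index = df["chrom"] + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)
    return df


def read_tss(path: str | os.PathLike) -> pd.DataFrame:
    """TSS TSV (gene, chrom, pos[, strand]); 1-based pos converted to 0-based."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "pos"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: TSS table needs columns {sorted(required)}")
    df = df.set_index("gene")
    df["pos"] = df["pos"].astype(int) - 1
    return df


def read_long_tsv(path: str | os.PathLike, rows: str, cols: str, value: str = "weight") -> pd.DataFrame:
    """Long-form (row, col, weight) TSV -> wide nonnegative matrix."""
    df = pd.read_csv(path, sep="\t")
    for c in (rows, cols, value):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    wide = df.pivot_table(index=rows, columns=cols, values=value,
                          aggfunc="sum", fill_value=0.0)
    return wide


def read_prior(
    b_path: str | os.PathLike,
    i_path: str | os.PathLike,
    bed_path: str | os.PathLike | None = None,
    tss_path: str | os.PathLike | None = None,
) -> RegulatoryPrior:
    """Assemble a RegulatoryPrior from long-form B / I TSVs plus coordinates."""
    B = read_long_tsv(b_path, rows="tf", cols="peak")
    I = read_long_tsv(i_path, rows="peak", cols="gene")
    peaks = read_bed(bed_path) if bed_path else None
    tss = read_tss(tss_path) if tss_path else None
    return RegulatoryPrior(B=B, I=I, peak_coords=peaks, tss_coords=tss)


# ---------------------------------------------------------------------------
# Simulated-bundle export (fixture glue for the end-to-end driver)
# ---------------------------------------------------------------------------

def expand_accessibility_to_cells(
    dataset: SimulatedDataset, n_cells: int, seed: int = 0
) -> tuple[SingleCellMatrix, SingleCellMatrix]:
    """Per-cell ATAC count matrices from the condition-level RE profiles.

    The generative model keeps accessibility at the subpopulation level; the
    end-to-end pipeline, however, ingests per-cell ATAC matrices, so for
    pipeline runs each condition's cells draw Poisson counts around the
    condition-level accessibility.  This is fixture plumbing, not part of
    the generative model.
    """
    rng = np.random.default_rng(seed)
    out = []
    for cond, acc in ((1, dataset.acc_cond1), (2, dataset.acc_cond2)):
        counts = rng.poisson(np.maximum(acc, 0.0)[:, None], size=(acc.size, n_cells))
        out.append(SingleCellMatrix(
            values=counts.astype(float),
            feature_ids=[f"peak{i}" for i in range(acc.size)],
            cell_ids=[f"c{cond}_atac_{t}" for t in range(n_cells)],
            modality="atac",
        ))
    return out[0], out[1]


def write_simulated_bundle(dataset: SimulatedDataset, outdir: str | os.PathLike) -> None:
    """Persist a simulated dataset: MTX bundles, truth tables, params JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    H = dataset.params.n_cells
    for cond in (1, 2):
        expr = dataset.expr_cond1 if cond == 1 else dataset.expr_cond2
        mat = SingleCellMatrix(
            values=expr, feature_ids=dataset.gene_names,
            cell_ids=[f"c{cond}_rna_{t}" for t in range(H)], modality="rna",
        )
        write_mtx_bundle(mat, outdir / f"cond{cond}" / "rna")
    acc = pd.DataFrame({
        "peak": [f"peak{i}" for i in range(dataset.params.n_re)],
        "cond1": dataset.acc_cond1,
        "cond2": dataset.acc_cond2,
    })
    acc.to_csv(outdir / "accessibility.tsv", sep="\t", index=False)

    truth = dataset.truth
    k_idx, j_idx = np.nonzero(truth.tested_mask)
    pd.DataFrame({
        "tf": [f"TF{k}" for k in k_idx],
        "tg": [f"TG{j}" for j in j_idx],
        "gamma_cond1": truth.gamma_cond[0][k_idx, j_idx],
        "gamma_cond2": truth.gamma_cond[1][k_idx, j_idx],
        "differential": truth.diff_edge_labels[k_idx, j_idx].astype(int),
    }).to_csv(outdir / "truth_edges.tsv", sep="\t", index=False)

    params = dataclasses.asdict(dataset.params)
    params["scenario"] = dataset.params.scenario.value
    (outdir / "params.json").write_text(json.dumps(params, indent=2))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Inputs and knobs of the end-to-end comparative analysis."""

    rna_cond1: str
    rna_cond2: str
    atac_cond1: str
    atac_cond2: str
    b_path: str
    i_path: str
    out_dir: str
    k: int = 2
    alpha_couple: float = 0.001
    beta_balance: float = 0.5
    d0: float = 40_000.0
    bed_path: str | None = None
    tss_path: str | None = None
    screen_fdr: float = 0.05
    edge_fdr: float = 0.1
    min_cells: int = diffreg.MIN_CELLS
    null: str = "gamma"
    method: str = "tfrp"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate(self) -> None:
        for name in ("rna_cond1", "rna_cond2", "atac_cond1", "atac_cond2",
                     "b_path", "i_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


@dataclass
class RunManifest:
    config: dict
    version: str
    started: float
    finished: float | None = None
    stages: list[str] = field(default_factory=list)
    outputs: dict = field(default_factory=dict)   # path -> sha256
    warnings: list[str] = field(default_factory=list)

    def record(self, path: Path) -> None:
        self.outputs[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        self.finished = time.time()
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        tmp.rename(path)


def _float_fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Full comparative analysis; returns the manifest (also written to disk)."""
    from . import __version__

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__,
                           started=time.time())

    def stage(name: str) -> None:
        logger.info("pipeline stage: %s", name)
        manifest.stages.append(name)

    try:
        stage("load")
        rna = {c: read_mtx_bundle(getattr(config, f"rna_cond{c}"), "rna") for c in (1, 2)}
        atac = {c: read_mtx_bundle(getattr(config, f"atac_cond{c}"), "atac") for c in (1, 2)}
        prior = read_prior(config.b_path, config.i_path, config.bed_path, config.tss_path)

        stage("preprocess")
        rna_n = {c: preprocess(m) for c, m in rna.items()}
        atac_n = {c: preprocess(m) for c, m in atac.items()}

        stage("coupled_nmf")
        # coupling matrix on the shared feature spaces: B^T I gives gene x peak
        # structure when coordinates are absent
        if prior.peak_coords is not None and prior.tss_coords is not None:
            from .regulatory_potential import build_coupling_matrix
            A_full = build_coupling_matrix(prior, d0=config.d0)
            A_genes, A_peaks = A_full.gene_ids, A_full.peak_ids
            A_mat = A_full.A.toarray()
        else:
            A_peaks = list(prior.I.index)
            A_genes = list(prior.I.columns)
            A_mat = prior.I.to_numpy(dtype=float).T
        results, assigns = {}, {}
        for c in (1, 2):
            g_idx = [i for i, g in enumerate(rna_n[c].feature_ids) if g in set(A_genes)]
            p_idx = [i for i, p in enumerate(atac_n[c].feature_ids) if p in set(A_peaks)]
            gpos = {g: i for i, g in enumerate(A_genes)}
            ppos = {p: i for i, p in enumerate(A_peaks)}
            rows = [gpos[rna_n[c].feature_ids[i]] for i in g_idx]
            cols = [ppos[atac_n[c].feature_ids[i]] for i in p_idx]
            A_c = A_mat[np.ix_(rows, cols)]
            res = coupled_nmf(
                atac_n[c].values[p_idx], rna_n[c].values[g_idx], A_c,
                K=config.k, alpha_couple=config.alpha_couple,
                beta_balance=config.beta_balance, seed=config.seed,
            )
            results[c] = res
            assigns[c] = assign_clusters(res, O=atac_n[c].values, E=rna_n[c].values)

        stage("link_subpopulations")
        prof = {}
        for c in (1, 2):
            prof[c] = {
                "rna": pd.DataFrame(assigns[c].rna_profiles, index=rna_n[c].feature_ids),
                "atac": pd.DataFrame(assigns[c].atac_profiles, index=atac_n[c].feature_ids),
            }
            for mod in prof[c]:
                prof[c][mod] = prof[c][mod].dropna(axis=1, how="all")
        mapping = link_subpopulations(
            prof[1]["rna"], prof[2]["rna"], prof[1]["atac"], prof[2]["atac"]
        )
        links_df = pd.DataFrame(
            [(i, j, mapping.confidence[(i, j)]) for i, j in mapping.links],
            columns=["cluster_cond1", "cluster_cond2", "confidence"],
        )
        _float_fmt(links_df, out / "links.tsv")
        manifest.record(out / "links.tsv")

        stage("diffreg")
        tables = []
        tf_ids = list(prior.B.index)
        for i, j, _conf in links_df.itertuples(index=False):
            cells1 = assigns[1].rna_labels == i
            cells2 = assigns[2].rna_labels == j
            if cells1.sum() < config.min_cells or cells2.sum() < config.min_cells:
                manifest.warnings.append(
                    f"link ({i},{j}): fewer than {config.min_cells} cells, skipped"
                )
                continue
            e1 = pd.DataFrame(rna_n[1].values[:, cells1], index=rna_n[1].feature_ids)
            e2 = pd.DataFrame(rna_n[2].values[:, cells2], index=rna_n[2].feature_ids)
            shared_genes = [g for g in e1.index if g in set(e2.index)]
            passed, screen_stats = diffreg.screen_differential_targets(
                e1.loc[shared_genes].to_numpy(), e2.loc[shared_genes].to_numpy(),
                alpha_fdr=config.screen_fdr, gene_ids=shared_genes,
            )
            tgs = [g for g, ok in zip(shared_genes, passed)
                   if ok and g in prior.I.columns]
            pairs = [(tf, tg) for tf in tf_ids for tg in tgs if tf in e1.index]
            if not pairs:
                continue
            # subpopulation accessibility profiles on the linked clusters
            acc1 = pd.DataFrame(atac_n[1].values, index=atac_n[1].feature_ids)
            acc2 = pd.DataFrame(atac_n[2].values, index=atac_n[2].feature_ids)
            profs = pd.DataFrame({
                "cond1": acc1.loc[:, assigns[1].atac_labels == i].mean(axis=1),
                "cond2": acc2.loc[:, assigns[2].atac_labels == j].mean(axis=1),
            })
            rows = []
            for cond, expr in ((1, e1), (2, e2)):
                cl = np.array([f"cond{cond}"] * expr.shape[1])
                if config.method == "tfrp":
                    sig = compute_tfrp(expr, prior, profs, cl, pairs)
                else:
                    sig = baseline_regulator_signal(expr, pairs)
                rows.append(sig)
            kept = [p for p in rows[0].pair_index if p in set(rows[1].pair_index)]
            lrs = []
            for tf, tg in kept:
                i1 = rows[0].pair_index.index((tf, tg))
                i2 = rows[1].pair_index.index((tf, tg))
                obs = diffreg.PairObservations(
                    tfrp_cond1=rows[0].values[i1], tfrp_cond2=rows[1].values[i2],
                    tg_cond1=e1.loc[tg].to_numpy(), tg_cond2=e2.loc[tg].to_numpy(),
                    tf=tf, tg=tg, subpopulation=f"{i}-{j}",
                )
                lrs.append(diffreg.lr_statistic(obs, min_cells=config.min_cells))
            lrs = np.asarray(lrs)
            if config.null == "gamma":
                fit = diffreg.fit_gamma_null(lrs)
                p = diffreg.lr_pvalues(lrs, fit)
            else:
                from scipy import stats as sstats
                p = sstats.chi2.sf(lrs, df=3)
            table = pd.DataFrame({
                "tf": [t for t, _ in kept], "tg": [g for _, g in kept],
                "subpopulation": f"{i}-{j}", "lr": lrs, "pvalue": p,
                "fdr": diffreg.bh_adjust(p),
            })
            tables.append(table)

        full = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
            columns=["tf", "tg", "subpopulation", "lr", "pvalue", "fdr"])
        _float_fmt(full, out / "diffreg_table.tsv")
        manifest.record(out / "diffreg_table.tsv")

        stage("networks")
        nets = []
        for sub, tab in full.groupby("subpopulation"):
            net = diffreg.build_differential_network(tab, config.edge_fdr)
            nets.append(net.edges.assign(subpopulation=sub))
        edges = pd.concat(nets, ignore_index=True) if nets else pd.DataFrame(
            columns=["tf", "tg", "subpopulation", "lr", "pvalue", "fdr"])
        _float_fmt(edges, out / "network_edges.tsv")
        manifest.record(out / "network_edges.tsv")
    except Exception as e:
        manifest.warnings.append(f"pipeline failed: {e}")
        manifest.write(out / "manifest.json")
        raise

    manifest.write(out / "manifest.json")
    return manifest
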