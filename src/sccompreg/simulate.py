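"""Two-condition regulatory-network simulator.

Generates a ground-truth TF -> RE -> TG regulatory system and single-cell
expression read-outs under two conditions, for benchmarking differential
regulatory-network detection.  The generative model is:

* motif binding          B_ik  ~ Bernoulli(10/K)      (RE i, TF k)
* RE-TG connection       beta_ij ~ Bernoulli(10/M)    (RE i, TG j)
* TF-TG strength         gamma_kj ~ 0.1 N(0,1) + 0.9 delta_0
* TF mean expression     mu_k  ~ Gamma(shape=2, scale=2)
* RE mean accessibility  nu_i  ~ Gamma(shape=1, scale=2)
* TG baseline            nu_j  ~ Gamma(shape=2, scale=2)
* TF expression          TF_kh ~ N(mu_k, mu_k^2) per cell
* RE accessibility       RE_ic ~ N(nu_i, (0.01 nu_i)^2), one scalar per
                         condition (subpopulation-level accessibility)
* TG expression          TG_jh = nu_j + sum_k gamma_kj (sum_i B_ik beta_ij
                         RE_ic) TF_kh + eps,  eps ~ N(0, (0.5 nu_j)^2)

Differential mechanisms (applied to condition 2 only):

* ``diff_tf``        -- a fraction of TFs get a per-cell shift r*mu_k,
                        r ~ U(0.1, 1)
* ``diff_re``        -- a fraction of REs get a shift r*nu_i, r ~ U(0.1, 1)
* ``diff_structure`` -- each nonzero gamma edge is independently zeroed in
                        each condition with probability ``edge_drop_prob``
* ``combined``       -- all three at once
* ``null``           -- no differential mechanism (calibration runs)

Dropout is applied to the expression matrices with a logistic probability
that decreases with expression level (lowly expressed genes are more likely
to drop out); see :func:`apply_dropout`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "regulatory_tg_mean",
    "Scenario",
    "SimulationParams",
    "GroundTruthNetwork",
    "SimulatedDataset",
    "simulate_network",
    "simulate_expression",
    "simulate_dataset",
    "apply_dropout",
    "dropout_probability",
]


class Scenario(str, Enum):
    """Which differential mechanism(s) the two conditions differ by."""

    diff_tf = "diff_tf"
    diff_re = "diff_re"
    diff_structure = "diff_structure"
    combined = "combined"
    null = "null"


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the two-condition generative model.

    Defaults are the benchmark conditions: K=50 TFs, N=500 TGs, M=1000 REs,
    H=500 cells per condition, 10% differential TFs/REs, structural edge
    deletion probability 0.01, dropout (kappa, lambda) = (0.1, 0.5).

    The Gamma laws for the mean parameters are parameterized as
    (shape, scale); ``gamma(2, 2)`` therefore has mean 4.
    """

    n_tf: int = 50
    n_tg: int = 500
    n_re: int = 1000
    n_cells: int = 500
    frac_diff_tf: float = 0.1
    frac_diff_re: float = 0.1
    edge_drop_prob: float = 0.01
    dropout_kappa: float = 0.1
    dropout_lambda: float = 0.5
    dropout_literal: bool = False
    scenario: Scenario = Scenario.combined
    seed: int = 0
    # distributional knobs (documented defaults above; rarely changed)
    motif_rate: float = 10.0          # B ~ Bern(motif_rate / K), beta ~ Bern(motif_rate / M)
    gamma_nonzero_frac: float = 0.1   # mixture weight of the N(0,1) component
    tf_mean_shape: float = 2.0
    tf_mean_scale: float = 2.0
    re_mean_shape: float = 1.0
    re_mean_scale: float = 2.0
    tg_base_shape: float = 2.0
    tg_base_scale: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_tf", "n_tg", "n_re", "n_cells"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("frac_diff_tf", "frac_diff_re", "edge_drop_prob", "gamma_nonzero_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not np.isfinite(self.dropout_kappa) or not np.isfinite(self.dropout_lambda):
            raise ValueError("dropout parameters must be finite")
        if self.dropout_kappa < 0:
            raise ValueError(f"dropout_kappa must be >= 0, got {self.dropout_kappa}")
        if self.motif_rate / self.n_tf > 1.0:
            raise ValueError(
                f"n_tf={self.n_tf} too small: motif Bernoulli rate "
                f"{self.motif_rate}/{self.n_tf} exceeds 1"
            )
        if self.motif_rate / self.n_re > 1.0:
            raise ValueError(
                f"n_re={self.n_re} too small: RE-TG Bernoulli rate "
                f"{self.motif_rate}/{self.n_re} exceeds 1"
            )
        if not isinstance(self.scenario, Scenario):
            object.__setattr__(self, "scenario", Scenario(self.scenario))


@dataclass
class GroundTruthNetwork:
    """Planted regulatory system plus differential ground-truth labels.

    ``diff_edge_labels[k, j]`` is defined (meaningful) wherever
    ``tested_mask[k, j]`` is True, i.e. for every (TF k, TG j) pair whose
    regulatory strength is nonzero in at least one condition.  A pair is
    labelled differential iff its per-condition strengths differ, or its TF
    is differentially expressed and gamma_kj != 0, or some RE wired between
    them (B_ik * beta_ij = 1) is differentially accessible and gamma_kj != 0.
    """

    B: np.ndarray               # (M, K) binary motif matrix
    beta: np.ndarray            # (M, N) binary RE-TG connections
    gamma: np.ndarray           # (K, N) base strengths
    gamma_cond: np.ndarray      # (2, K, N) per-condition strengths
    tf_means: np.ndarray        # (K,)
    tg_baselines: np.ndarray    # (N,)
    re_means: np.ndarray        # (M,)
    diff_tf_set: np.ndarray     # indices of differentially expressed TFs
    diff_re_set: np.ndarray     # indices of differentially accessible REs
    tested_mask: np.ndarray     # (K, N) bool: gamma nonzero in >= 1 condition
    diff_edge_labels: np.ndarray  # (K, N) bool


@dataclass
class SimulatedDataset:
    """Observed (post-dropout) and latent expression for both conditions.

    Expression matrices stack the K TF rows on top of the N TG rows
    (``(K + N) x H``).  Accessibility is one subpopulation-level scalar per
    RE per condition.
    """

    expr_cond1: np.ndarray       # observed, post-dropout
    expr_cond2: np.ndarray
    expr_real_cond1: np.ndarray  # latent, pre-dropout (clamped at 0)
    expr_real_cond2: np.ndarray
    acc_cond1: np.ndarray        # (M,) RE accessibility, condition 1
    acc_cond2: np.ndarray
    truth: GroundTruthNetwork
    params: SimulationParams
    gene_names: list[str] = field(default_factory=list)

    @property
    def n_tf(self) -> int:
        return self.params.n_tf

    def tf_expr(self, cond: int, observed: bool = True) -> np.ndarray:
        m = self._expr(cond, observed)
        return m[: self.n_tf]

    def tg_expr(self, cond: int, observed: bool = True) -> np.ndarray:
        m = self._expr(cond, observed)
        return m[self.n_tf:]

    def _expr(self, cond: int, observed: bool) -> np.ndarray:
        if cond not in (1, 2):
            raise ValueError(f"condition must be 1 or 2, got {cond}")
        if observed:
            return self.expr_cond1 if cond == 1 else self.expr_cond2
        return self.expr_real_cond1 if cond == 1 else self.expr_real_cond2


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    # independent, reproducible streams for network / expression / dropout
    return np.random.default_rng(np.random.SeedSequence([int(params.seed), stream]))


def dropout_probability(
    expr: np.ndarray, kappa: float, lambda_: float, literal: bool = False
) -> np.ndarray:
    """Per-entry dropout probability as a function of expression level E.

    Default orientation is monotone decreasing in E,
    ``p(E) = 1 / (1 + E^kappa * exp(lambda))`` -- lowly expressed genes drop
    out more often.  ``literal=True`` flips the orientation to
    ``p(E) = 1 / (1 + E^-kappa * exp(-lambda))`` (increasing in E).
    Entries with E <= 0 get p = 0 (they are already zero).
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    E = np.asarray(expr, dtype=float)
    p = np.zeros_like(E)
    pos = E > 0
    if literal:
        p[pos] = 1.0 / (1.0 + np.power(E[pos], -kappa) * np.exp(-lambda_))
    else:
        p[pos] = 1.0 / (1.0 + np.power(E[pos], kappa) * np.exp(lambda_))
    return p


def apply_dropout(
    expr: np.ndarray,
    kappa: float,
    lambda_: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    literal: bool = False,
) -> np.ndarray:
    """Zero out entries of ``expr`` with the logistic dropout probability.

    Negative entries are clamped to 0 first (log E is undefined for them);
    zero entries stay zero.  Exactly one of ``seed`` / ``rng`` provides the
    randomness.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    E = np.maximum(np.asarray(expr, dtype=float), 0.0)
    p = dropout_probability(E, kappa, lambda_, literal=literal)
    u = rng.uniform(size=E.shape)
    out = E.copy()
    out[u < p] = 0.0
    return out


def simulate_network(params: SimulationParams) -> GroundTruthNetwork:
    """Draw the planted regulatory system and differential ground truth."""
    K, N, M = params.n_tf, params.n_tg, params.n_re
    rng = _rng(params, 0)

    B = (rng.random((M, K)) < params.motif_rate / K).astype(np.int8)
    beta = (rng.random((M, N)) < params.motif_rate / M).astype(np.int8)

    nonzero = rng.random((K, N)) < params.gamma_nonzero_frac
    gamma = np.where(nonzero, rng.normal(0.0, 1.0, size=(K, N)), 0.0)

    scen = params.scenario
    gamma_cond = np.stack([gamma.copy(), gamma.copy()])
    if scen in (Scenario.diff_structure, Scenario.combined) and params.edge_drop_prob > 0:
        for c in range(2):
            drop = (rng.random((K, N)) < params.edge_drop_prob) & nonzero
            gamma_cond[c][drop] = 0.0

    diff_tf_set = np.array([], dtype=int)
    diff_re_set = np.array([], dtype=int)
    if scen in (Scenario.diff_tf, Scenario.combined):
        n_diff = int(round(params.frac_diff_tf * K))
        diff_tf_set = np.sort(rng.choice(K, size=n_diff, replace=False))
    if scen in (Scenario.diff_re, Scenario.combined):
        n_diff = int(round(params.frac_diff_re * M))
        diff_re_set = np.sort(rng.choice(M, size=n_diff, replace=False))

    tf_means = rng.gamma(params.tf_mean_shape, params.tf_mean_scale, size=K)
    tg_baselines = rng.gamma(params.tg_base_shape, params.tg_base_scale, size=N)
    re_means = rng.gamma(params.re_mean_shape, params.re_mean_scale, size=M)

    tested = (gamma_cond[0] != 0) | (gamma_cond[1] != 0)
    labels = gamma_cond[0] != gamma_cond[1]
    if diff_tf_set.size:
        tf_mask = np.zeros(K, dtype=bool)
        tf_mask[diff_tf_set] = True
        labels |= tf_mask[:, None] & (gamma != 0)
    if diff_re_set.size:
        # (K, N) count of differential REs wired between TF k and TG j
        wired = B[diff_re_set].T.astype(np.int64) @ beta[diff_re_set].astype(np.int64)
        labels |= (wired > 0) & (gamma != 0)
    labels &= tested

    return GroundTruthNetwork(
        B=B, beta=beta, gamma=gamma, gamma_cond=gamma_cond,
        tf_means=tf_means, tg_baselines=tg_baselines, re_means=re_means,
        diff_tf_set=diff_tf_set, diff_re_set=diff_re_set,
        tested_mask=tested, diff_edge_labels=labels,
    )


def regulatory_tg_mean(
    truth: GroundTruthNetwork,
    tf_matrix: np.ndarray,
    acc: np.ndarray,
    condition: int,
) -> np.ndarray:
    """Noise-free TG expression under the wiring model.

    TG_jh = nu_j + sum_k gamma_kj^(c) (sum_i B_ik beta_ij RE_ic) TF_kh,
    vectorized over genes and cells.
    """
    if condition not in (1, 2):
        raise ValueError(f"condition must be 1 or 2, got {condition}")
    # effective strength g[k, j] = gamma_kj^(c) * sum_i B_ik beta_ij RE_ic
    w = truth.B.T.astype(float) @ (truth.beta * np.asarray(acc, float)[:, None])
    g = truth.gamma_cond[condition - 1] * w
    return truth.tg_baselines[:, None] + g.T @ np.asarray(tf_matrix, float)


def simulate_expression(
    truth: GroundTruthNetwork, params: SimulationParams
) -> SimulatedDataset:
    """Draw per-cell expression / per-condition accessibility and apply dropout."""
    K, N, M, H = params.n_tf, params.n_tg, params.n_re, params.n_cells
    rng = _rng(params, 1)
    mu = truth.tf_means
    nu_re = truth.re_means
    nu_tg = truth.tg_baselines

    tf = [rng.normal(mu[:, None], mu[:, None], size=(K, H)) for _ in range(2)]
    if truth.diff_tf_set.size:
        idx = truth.diff_tf_set
        r = rng.uniform(0.1, 1.0, size=(idx.size, H))
        tf[1][idx] += r * mu[idx, None]

    acc = [np.maximum(rng.normal(nu_re, 0.01 * nu_re), 0.0) for _ in range(2)]
    if truth.diff_re_set.size:
        idx = truth.diff_re_set
        r = rng.uniform(0.1, 1.0, size=idx.size)
        acc[1][idx] += r * nu_re[idx]

    real = []
    for c in range(2):
        eps = rng.normal(0.0, 0.5 * nu_tg[:, None], size=(N, H))
        tg = regulatory_tg_mean(truth, tf[c], acc[c], condition=c + 1) + eps
        real.append(np.maximum(np.vstack([tf[c], tg]), 0.0))

    drop_rng = _rng(params, 2)
    observed = [
        apply_dropout(
            real[c], params.dropout_kappa, params.dropout_lambda,
            rng=drop_rng, literal=params.dropout_literal,
        )
        for c in range(2)
    ]

    gene_names = [f"TF{k}" for k in range(K)] + [f"TG{j}" for j in range(N)]
    return SimulatedDataset(
        expr_cond1=observed[0], expr_cond2=observed[1],
        expr_real_cond1=real[0], expr_real_cond2=real[1],
        acc_cond1=acc[0], acc_cond2=acc[1],
        truth=truth, params=params, gene_names=gene_names,
    )


def simulate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Convenience: :func:`simulate_network` then :func:`simulate_expression`."""
    truth = simulate_network(params)
    return simulate_expression(truth, params)
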