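"""Gibbs sampling with interleaved pseudo-likelihood parameter estimation.

Three execution modes are provided:

``imrf1``
    Every sweep first re-estimates theta by a binary logistic regression
    of the *current* labels (known + sampled) on the per-network neighbor
    counts, then performs one sequential Gibbs sweep. After the burn-in,
    the per-sweep conditional probabilities are recorded every ``thin``-th
    sweep and averaged into the posterior; theta is averaged over the same
    snapshots.

``imrf2``
    Runs ``imrf1``, then freezes theta at its lag-period average,
    re-initializes the unknown labels from the lag-period posterior, and
    runs a further prediction period with no re-estimation; the posterior
    is the average conditional probability over that period.

``deng``
    The classical baseline: theta is estimated once, from the known
    positives plus a negative set (known genes of other disease classes),
    with neighbor counts restricted to known-labelled genes, and then held
    fixed for the whole run.

The logistic regression regresses ``logit P(x_i = 1)`` on
``(M0_1, M1_1, ..., M0_K, M1_K)``; the fitted coefficients map to the
edge weights as ``beta_k = b_k + 1`` and ``gamma_k = c_k + beta_k``.
A small ridge penalty keeps coefficients finite when a column is
degenerate or the design separates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from ._gibbs import pack_adjacency, run_sweeps
from .core import (
    LabelConfig,
    MRFParams,
    PriorVector,
    neighbor_count_matrix,
    sigmoid,
)
from .data import GeneUniverse, NetworkCollection
from .errors import ConfigurationError, DimensionError, EstimationError

RIDGE = 1e-6
MAX_IRLS_ITER = 100


@dataclass(frozen=True)
class SamplerConfig:
    """Gibbs schedule and reproducibility settings.

    ``total`` sweeps are run; the first ``burn_in`` are discarded and every
    ``thin``-th sweep thereafter is recorded (defaults 1000/100/10 give 90
    snapshots). ``prediction_steps`` applies to the imrf2 mode only.
    """

    burn_in: int = 100
    total: int = 1000
    thin: int = 10
    prediction_steps: int = 100
    seed: int = 0
    alpha_mode: str = "global"
    update_order: str = "index"

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.total):
            raise ConfigurationError(
                f"need 0 < burn_in < total, got ({self.burn_in}, {self.total})"
            )
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.prediction_steps < 0:
            raise ConfigurationError("prediction_steps must be >= 0")
        if self.alpha_mode not in ("global", "offset"):
            raise ConfigurationError(f"unknown alpha_mode: {self.alpha_mode!r}")
        if self.update_order not in ("index", "shuffled"):
            raise ConfigurationError(f"unknown update_order: {self.update_order!r}")

    @property
    def n_snapshots(self) -> int:
        return (self.total - self.burn_in) // self.thin


@dataclass
class SamplerResult:
    """Output of one sampling run.

    ``posterior`` holds the averaged conditional probability for every
    gene; clamped (known) genes are reported with posterior 1 and flagged
    by ``known``. ``theta_trace`` has one row per sweep as the flat vector
    (alpha, beta_1..K, gamma_1..K).
    """

    posterior: np.ndarray
    known: np.ndarray
    prior: np.ndarray
    theta_trace: np.ndarray
    theta_final: MRFParams
    q_trace: np.ndarray
    config: SamplerConfig
    mode: str
    n_recorded: int = 0

    def decision_scores(self) -> np.ndarray:
        """Rank-percentile decision scores; clamped genes score 1."""
        from .evaluation import decision_scores as _ds

        scores = np.ones(len(self.posterior), dtype=float)
        free = ~self.known
        if free.any():
            scores[free] = _ds(self.posterior[free])
        return scores

    def to_frame(self, universe: GeneUniverse):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": list(universe),
                "known_flag": self.known.astype(int),
                "prior": self.prior,
                "posterior": self.posterior,
                "decision_score": self.decision_scores(),
            }
        )

    def summary(self) -> str:
        K = self.theta_final.K
        lines = [
            "Gibbs MRF sampling result",
            "=" * 25,
            f"mode:            {self.mode}",
            f"alpha mode:      {self.config.alpha_mode}",
            f"genes:           {len(self.posterior)} "
            f"({int(self.known.sum())} known, {int((~self.known).sum())} candidates)",
            f"sweeps:          {self.config.total} "
            f"(burn-in {self.config.burn_in}, thin {self.config.thin}"
            + (f", prediction {self.config.prediction_steps}"
               if self.mode == "imrf2" else "")
            + ")",
            f"alpha:           {self.theta_final.alpha:+.4f}",
        ]
        for k in range(K):
            lines.append(
                f"network {k + 1}:       beta = {self.theta_final.beta[k]:+.4f}, "
                f"gamma = {self.theta_final.gamma[k]:+.4f}"
            )
        q = self.q_trace[np.isfinite(self.q_trace)]
        if len(q):
            lines.append(f"final Q(t):      {q[-1]:.6g}")
        return "\n".join(lines)


def chain_variation(prob_t: np.ndarray, prob_prev: np.ndarray) -> float:
    """Q(t) = sum_i (P_i(t) - P_i(t-1))^2 over the unclamped genes."""
    prob_t = np.asarray(prob_t, float)
    prob_prev = np.asarray(prob_prev, float)
    if prob_t.shape != prob_prev.shape:
        raise DimensionError("probability vectors differ in length")
    d = prob_t - prob_prev
    return float(d @ d)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def _ridge_logistic(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None,
    ridge: float = RIDGE,
    max_iter: int = MAX_IRLS_ITER,
    tol: float = 1e-10,
) -> tuple[np.ndarray, bool]:
    """Newton fit of a ridge-penalized logistic regression.

    Returns (coefficients, converged). The intercept (column 0) is not
    penalized. On non-convergence within ``max_iter`` iterations the
    current finite iterate is returned — under complete separation the
    tiny ridge yields large-but-finite coefficients.
    """
    n, p = X.shape
    off = np.zeros(n) if offset is None else offset
    pen = np.full(p, ridge)
    pen[0] = 0.0
    w = np.zeros(p)

    def objective(w):
        eta = X @ w + off
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * (pen * w**2).sum())

    f = objective(w)
    converged = False
    for _ in range(max_iter):
        eta = X @ w + off
        mu = sigmoid(eta)
        g = X.T @ (mu - y) + pen * w
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        wgt = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = (X.T * wgt) @ X + np.diag(pen + 1e-12)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        while t > 1e-10:
            w_new = w - t * step
            f_new = objective(w_new)
            if f_new <= f:
                break
            t *= 0.5
        if f - f_new < 1e-14 * (abs(f) + 1.0):
            w = w_new
            f = f_new
            converged = True
            break
        w, f = w_new, f_new
    return w, converged


def design_matrix(
    collection: NetworkCollection,
    labels: LabelConfig | np.ndarray,
    count_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Pseudo-likelihood design: one row per gene, columns
    (1, M0_1, M1_1, ..., M0_K, M1_K). With ``count_mask`` the neighbor
    counts only consider genes where the mask is True."""
    x = labels.labels if isinstance(labels, LabelConfig) else np.asarray(labels, np.int8)
    if count_mask is None:
        m0, m1 = neighbor_count_matrix(collection, x)
    else:
        masked = (x.astype(np.float64)) * count_mask
        m1 = np.stack([a @ masked for a in collection.adjacencies()])
        known_deg = np.stack(
            [a @ count_mask.astype(np.float64) for a in collection.adjacencies()]
        )
        m0 = known_deg - m1
    n = m0.shape[1]
    cols = [np.ones(n)]
    for k in range(m0.shape[0]):
        cols.append(m0[k])
        cols.append(m1[k])
    return np.column_stack(cols)


def estimate_parameters(
    collection: NetworkCollection,
    labels: LabelConfig | np.ndarray,
    priors: PriorVector | None = None,
    alpha_mode: str = "global",
    rows_mask: np.ndarray | None = None,
    count_mask: np.ndarray | None = None,
) -> MRFParams:
    """Pseudo-likelihood estimate of theta from a full labelling.

    Fits ``logit P(x_i = 1) = alpha + sum_k (b_k M0_k + c_k M1_k)`` over the
    selected rows (default: all genes) and maps the coefficients to the
    edge weights ``beta_k = b_k + 1``, ``gamma_k = c_k + beta_k``. In
    ``offset`` mode the per-gene prior log-odds enter as a fixed offset
    and alpha is the remaining free constant.
    """
    x = labels.labels if isinstance(labels, LabelConfig) else np.asarray(labels, np.int8)
    X = design_matrix(collection, x, count_mask=count_mask)
    y = x.astype(np.float64)
    offset = None
    if alpha_mode == "offset":
        if priors is None:
            raise ConfigurationError("offset alpha mode requires priors")
        offset = priors.alpha
    elif alpha_mode != "global":
        raise ConfigurationError(f"unknown alpha_mode: {alpha_mode!r}")
    if rows_mask is not None:
        X = X[rows_mask]
        y = y[rows_mask]
        if offset is not None:
            offset = offset[rows_mask]
    if len(y) == 0:
        raise EstimationError("no rows available for parameter estimation")
    if np.all(y == y[0]):
        raise EstimationError(
            f"degenerate design: all {len(y)} labels equal {int(y[0])}; "
            "the logistic regression is not identifiable"
        )
    w, _ = _ridge_logistic(X, y, offset)
    K = collection.K
    alpha = float(w[0])
    b = w[1:1 + 2 * K:2]
    c = w[2:2 + 2 * K:2]
    beta = b + 1.0
    gamma = c + beta
    return MRFParams(alpha=alpha, beta=beta, gamma=gamma)


# ---------------------------------------------------------------------------
# sweeping
# ---------------------------------------------------------------------------

class _Sampler:
    """Bookkeeping shared by the run_* drivers."""

    def __init__(self, collection: NetworkCollection, state: LabelConfig,
                 config: SamplerConfig, rng: np.random.Generator):
        self.collection = collection
        self.state = state
        self.config = config
        self.rng = rng
        self.indptr, self.indices = pack_adjacency(collection.adjacencies())
        self.free = np.where(~state.clamped)[0].astype(np.int64)
        self.n = state.n

    def field_vector(self, params: MRFParams, priors: PriorVector) -> np.ndarray:
        if self.config.alpha_mode == "offset":
            return priors.alpha + params.alpha
        return np.full(self.n, params.alpha)

    def sweep(self, params: MRFParams, priors: PriorVector) -> np.ndarray:
        """One sequential sweep in place; returns the per-gene conditional
        probabilities (clamped genes reported as 1)."""
        if self.config.update_order == "shuffled":
            order = self.rng.permutation(self.free)
        else:
            order = self.free
        uniforms = self.rng.random(len(order))
        probs = np.ones((1, self.n))
        run_sweeps(
            self.state.labels,
            self.indptr,
            self.indices,
            self.field_vector(params, priors),
            params.beta,
            params.gamma,
            order.reshape(1, -1),
            uniforms.reshape(1, -1),
            probs,
        )
        return probs[0]


def gibbs_sweep(
    state: LabelConfig,
    collection: NetworkCollection,
    params: MRFParams,
    priors: PriorVector,
    rng: np.random.Generator,
    alpha_mode: str = "global",
    update_order: str = "index",
) -> tuple[LabelConfig, np.ndarray]:
    """One sequential Gibbs sweep (new state, conditional probabilities).

    Unclamped genes are visited in the chosen order; each local field is
    computed from the current labels so updates within the sweep chain.
    """
    cfg = SamplerConfig(alpha_mode=alpha_mode, update_order=update_order)
    new_state = state.copy()
    sampler = _Sampler(collection, new_state, cfg, rng)
    probs = sampler.sweep(params, priors)
    return new_state, probs


# ---------------------------------------------------------------------------
# run drivers
# ---------------------------------------------------------------------------

def _init_labels(
    n: int,
    known: np.ndarray,
    pi: np.ndarray,
    rng: np.random.Generator,
) -> LabelConfig:
    labels = (rng.random(n) < pi).astype(np.int8)
    clamped = np.zeros(n, dtype=bool)
    labels[known] = 1
    clamped[known] = True
    return LabelConfig(labels, clamped)


def _run_chain(
    sampler: _Sampler,
    priors: PriorVector,
    config: SamplerConfig,
    theta_of_sweep: Callable[[int, LabelConfig], MRFParams],
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Drive ``total`` sweeps; returns (posterior over recorded snapshots,
    theta rows per sweep, recorded theta rows, q trace)."""
    theta_rows: list[np.ndarray] = []
    recorded_theta: list[np.ndarray] = []
    q_trace = np.full(config.total, np.nan)
    post_sum = np.zeros(sampler.n)
    n_rec = 0
    prev_probs: np.ndarray | None = None
    for t in range(1, config.total + 1):
        try:
            params = theta_of_sweep(t, sampler.state)
        except EstimationError as err:
            raise EstimationError(f"sweep {t}: {err}") from err
        probs = sampler.sweep(params, priors)
        theta_rows.append(params.as_vector())
        if prev_probs is not None:
            q_trace[t - 1] = chain_variation(
                probs[sampler.free], prev_probs[sampler.free]
            )
        prev_probs = probs
        if t > config.burn_in and (t - config.burn_in) % config.thin == 0:
            post_sum += probs
            recorded_theta.append(params.as_vector())
            n_rec += 1
    posterior = post_sum / max(n_rec, 1)
    return posterior, theta_rows, recorded_theta, q_trace


def run_imrf1(
    collection: NetworkCollection,
    known_genes,
    priors: PriorVector,
    config: SamplerConfig | None = None,
) -> SamplerResult:
    """Interleaved estimation/sampling: theta re-estimated every sweep from
    the current full labelling."""
    config = config or SamplerConfig()
    known = np.asarray(sorted(known_genes), dtype=np.int64)
    if len(known) == 0:
        raise ConfigurationError("known_genes must be non-empty")
    rng = np.random.default_rng(config.seed)
    state = _init_labels(collection.n_genes, known, priors.pi, rng)
    sampler = _Sampler(collection, state, config, rng)

    def theta_of_sweep(t: int, st: LabelConfig) -> MRFParams:
        return estimate_parameters(collection, st, priors, config.alpha_mode)

    posterior, theta_rows, recorded, q_trace = _run_chain(
        sampler, priors, config, theta_of_sweep
    )
    posterior[state.clamped] = 1.0
    theta_final = MRFParams.from_vector(np.mean(recorded, axis=0))
    return SamplerResult(
        posterior=posterior,
        known=state.clamped.copy(),
        prior=priors.pi.copy(),
        theta_trace=np.array(theta_rows),
        theta_final=theta_final,
        q_trace=q_trace,
        config=config,
        mode="imrf1",
        n_recorded=len(recorded),
    )


def run_imrf2(
    collection: NetworkCollection,
    known_genes,
    priors: PriorVector,
    config: SamplerConfig | None = None,
) -> SamplerResult:
    """imrf1 followed by a frozen-theta prediction period.

    Theta is fixed at the lag-period average, unknown labels are
    re-initialized from the lag-period posterior, and the average
    conditional probability over ``prediction_steps`` further sweeps is
    the final posterior.
    """
    config = config or SamplerConfig()
    lag = run_imrf1(collection, known_genes, priors, config)
    if config.prediction_steps == 0:
        return replace(lag, mode="imrf2")
    theta = lag.theta_final
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    known = np.where(lag.known)[0]
    state = _init_labels(collection.n_genes, known, lag.posterior, rng)
    sampler = _Sampler(collection, state, config, rng)
    post_sum = np.zeros(collection.n_genes)
    q_ext = []
    prev = None
    for _ in range(config.prediction_steps):
        probs = sampler.sweep(theta, priors)
        post_sum += probs
        if prev is not None:
            q_ext.append(chain_variation(probs[sampler.free], prev[sampler.free]))
        prev = probs
    posterior = post_sum / config.prediction_steps
    posterior[state.clamped] = 1.0
    theta_trace = np.vstack(
        [lag.theta_trace]
        + [theta.as_vector()] * config.prediction_steps
    )
    q_trace = np.concatenate([lag.q_trace, [np.nan], q_ext])
    return SamplerResult(
        posterior=posterior,
        known=state.clamped.copy(),
        prior=priors.pi.copy(),
        theta_trace=theta_trace,
        theta_final=theta,
        q_trace=q_trace,
        config=config,
        mode="imrf2",
        n_recorded=config.prediction_steps,
    )


def run_deng(
    collection: NetworkCollection,
    known_genes,
    negative_genes,
    priors: PriorVector,
    config: SamplerConfig | None = None,
) -> SamplerResult:
    """Baseline mode: theta estimated once from known-labelled genes only.

    The regression rows are the known positives (label 1) and the negative
    set (label 0), with neighbor counts restricted to known-labelled
    genes; theta is then fixed for the whole Gibbs run.
    """
    config = config or SamplerConfig()
    known = np.asarray(sorted(known_genes), dtype=np.int64)
    negatives = np.asarray(sorted(negative_genes), dtype=np.int64)
    if len(known) == 0:
        raise ConfigurationError("known_genes must be non-empty")
    if np.intersect1d(known, negatives).size:
        raise ConfigurationError("known and negative gene sets overlap")
    n = collection.n_genes
    K = collection.K
    n_rows = len(known) + len(negatives)
    if n_rows < 2 * K + 2:
        raise EstimationError(
            f"only {n_rows} known-labelled genes for {2 * K + 2} coefficients"
        )
    known_mask = np.zeros(n, dtype=bool)
    known_mask[known] = True
    known_mask[negatives] = True
    est_labels = np.zeros(n, dtype=np.int8)
    est_labels[known] = 1
    theta = estimate_parameters(
        collection,
        est_labels,
        priors,
        config.alpha_mode,
        rows_mask=known_mask,
        count_mask=known_mask,
    )
    rng = np.random.default_rng(config.seed)
    state = _init_labels(n, known, priors.pi, rng)
    sampler = _Sampler(collection, state, config, rng)
    posterior, theta_rows, _, q_trace = _run_chain(
        sampler, priors, config, lambda t, st: theta
    )
    posterior[state.clamped] = 1.0
    return SamplerResult(
        posterior=posterior,
        known=state.clamped.copy(),
        prior=priors.pi.copy(),
        theta_trace=np.array(theta_rows),
        theta_final=theta,
        q_trace=q_trace,
        config=config,
        mode="deng",
        n_recorded=config.n_snapshots,
    )
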