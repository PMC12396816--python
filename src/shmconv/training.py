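"""Likelihood and training for SHM models.

The generative assumption: each site of a parent sequence carries an
independent exponential mutation clock with rate ``lambda_i``; over a
branch of length ``t`` the site mutates with probability
``p_i = 1 - exp(-t * lambda_i)``, and a mutated site draws its new base
from the conditional substitution probability (CSP) row.  Only the
product ``t * lambda_i`` is identified per pair, so ``t`` enters the
model as a fixed multiplicative offset (by default the pair's normalized
mutation count) and the model learns ``lambda`` on a common scale.

The loss is the Bernoulli negative log-likelihood of the mutation
placements plus a categorical cross-entropy on the base identity at
mutated sites, the latter down-weighted (default 0.01) to roughly even
out the two contributions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .models import SHMModel, _BASE_INDEX
from .pcp import (
    ParentChildPair,
    PcpDataset,
    fourfold_degenerate_mask,
    mutation_count,
    mutation_indicators,
)

LOSS_SITE_MODES = ("all_informative", "fourfold_synonymous")


@dataclass
class TrainingConfig:
    epochs: int = 100
    learning_rate: float = 1e-3
    csp_weight: float = 0.01
    batch_size: int = 32
    seed: int = 0
    loss_sites: str = "all_informative"
    joint_branch_opt: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.csp_weight < 0:
            raise ValueError("csp_weight must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss_sites not in LOSS_SITE_MODES:
            raise ValueError(f"loss_sites must be one of {LOSS_SITE_MODES}")


@dataclass
class LossBreakdown:
    """Placement and base-identity components of the two-part loss."""

    placement_nll: float
    csp_nll: float
    csp_weight: float

    @property
    def total(self) -> float:
        return self.placement_nll + self.csp_weight * self.csp_nll


def substitution_probability(lam, t):
    """P(site mutates within branch length t) = 1 - exp(-t * lambda).

    Accepts scalars or arrays; uses expm1 so tiny ``t * lambda`` keeps full
    relative precision (p -> t * lambda as t * lambda -> 0).
    """
    lam = np.asarray(lam, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("rates must be positive")
    if np.any(t_arr < 0):
        raise ValueError("branch length must be nonnegative")
    out = -np.expm1(-t_arr * lam)
    return float(out) if out.ndim == 0 else out


def _placement_terms(x: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Per-site Bernoulli NLL terms given x = t*lambda and indicators m.

    -log(1 - p) = x for unmutated sites; -log p = -log(-expm1(-x)) for
    mutated ones (infinite when x == 0, reported as such).
    """
    terms = np.where(m, 0.0, x)
    if m.any():
        xm = x[m]
        with np.errstate(divide="ignore"):
            terms = terms.copy()
            terms[m] = -np.log(-np.expm1(-xm))
    return terms


def pcp_loss(pred, pcp: ParentChildPair, csp_weight: float = 0.01) -> LossBreakdown:
    """Two-part negative log-likelihood of one pair under a prediction.

    Sites are restricted to the pair's loss mask.  A mutated site whose
    CSP row assigns zero to the observed child base yields an explicitly
    infinite csp_nll rather than a clipped value.
    """
    m, mask = mutation_indicators(pcp)
    x = pcp.branch_length * pred.rates
    placement = float(_placement_terms(x, m)[mask].sum())
    csp_nll = 0.0
    for i in np.nonzero(m & mask)[0]:
        p_child = pred.csp[i, _BASE_INDEX[pcp.child[i]]]
        with np.errstate(divide="ignore"):
            csp_nll -= float(np.log(p_child))
    return LossBreakdown(placement, csp_nll, csp_weight)


# ---------------------------------------------------------------------------
# loss + analytic gradients through a model
# ---------------------------------------------------------------------------

def _csp_log_softmax(csp_logits: np.ndarray, parent: str):
    """Masked log-softmax over the 5-wide CSP logits.

    The ambiguity column and the parent-base column are excluded, so rows
    normalize over the three non-parent bases.  Returns (log-probs,
    allowed-column mask); disallowed entries hold -inf.
    """
    L = csp_logits.shape[0]
    allowed = np.ones((L, 5), dtype=bool)
    allowed[:, 4] = False
    for i, b in enumerate(parent):
        if b in _BASE_INDEX:
            allowed[i, _BASE_INDEX[b]] = False
    z = np.where(allowed, csp_logits, -np.inf)
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    return z - logsumexp, allowed


def pair_loss_and_grads(
    model: SHMModel,
    pcp: ParentChildPair,
    csp_weight: float,
    train: bool = False,
    rng: np.random.Generator | None = None,
):
    """One forward/backward pass: (LossBreakdown, parameter gradients)."""
    m, mask = mutation_indicators(pcp)
    log_rates, csp_logits, cache = model.forward(pcp.parent, train=train, rng=rng)
    lam = np.exp(log_rates)
    x = pcp.branch_length * lam

    placement = float(_placement_terms(x, m)[mask].sum())
    # d placement / d log-rate: x for unmutated sites, -x/(e^x - 1) mutated
    dlog = np.where(m, 0.0, x)
    mut = m & mask
    if mut.any():
        xm = x[mut]
        with np.errstate(divide="ignore", invalid="ignore"):
            dlog_mut = -xm * np.exp(-xm) / (-np.expm1(-xm))
        dlog = dlog.copy()
        dlog[mut] = np.where(xm > 0, dlog_mut, 0.0)
    dlog[~mask] = 0.0
    dlog[m & ~mask] = 0.0

    log_csp, allowed = _csp_log_softmax(csp_logits, pcp.parent)
    csp_nll = 0.0
    dcsp = np.zeros_like(csp_logits)
    for i in np.nonzero(mut)[0]:
        j = _BASE_INDEX[pcp.child[i]]
        csp_nll -= float(log_csp[i, j])
        probs = np.where(allowed[i], np.exp(log_csp[i]), 0.0)
        probs[j] -= 1.0
        dcsp[i] = csp_weight * probs

    grads = model.backward(cache, dlog, dcsp)
    return LossBreakdown(placement, csp_nll, csp_weight), grads


# ---------------------------------------------------------------------------
# branch-length optimization
# ---------------------------------------------------------------------------

def placement_log_likelihood(rates: np.ndarray, pcp: ParentChildPair, t: float) -> float:
    """Bernoulli log-likelihood of the mutation placements at offset t."""
    m, mask = mutation_indicators(pcp)
    return -float(_placement_terms(t * rates, m)[mask].sum())


def optimize_branch_length(
    model: SHMModel,
    pcp: ParentChildPair,
    t_max: float = 5.0,
    rates: np.ndarray | None = None,
) -> float:
    """Branch length maximizing the placement likelihood of one pair.

    One-dimensional bounded search on [0, t_max] to absolute tolerance
    1e-8; for uniform rates the optimum has the closed form
    -log(1 - m/L) / lambda, which the search reproduces.  Pairs with no
    mutations get t* = 0 (the likelihood is decreasing in t).
    """
    m, mask = mutation_indicators(pcp)
    if not mask.any():
        raise ValueError("pair has no informative sites")
    if rates is None:
        rates = model.predict_rates(pcp.parent).rates
    if not (m & mask).any():
        return 0.0
    res = minimize_scalar(
        lambda t: -placement_log_likelihood(rates, pcp, t),
        bounds=(0.0, t_max),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _dataset_losses(model: SHMModel, pcps, csp_weight: float):
    """Mean per-pair placement and CSP losses in evaluation mode."""
    if not pcps:
        return float("nan"), float("nan")
    pl, ce = 0.0, 0.0
    for pcp in pcps:
        lb = pcp_loss(model.predict_rates(pcp.parent), pcp, csp_weight)
        pl += lb.placement_nll
        ce += lb.csp_nll
    return pl / len(pcps), ce / len(pcps)


def train(
    model: SHMModel,
    train_set: PcpDataset,
    val_set: PcpDataset | None,
    config: TrainingConfig,
    verbose: bool = False,
) -> pd.DataFrame:
    """Fit a model by Adam on the mean per-pair two-part loss.

    Pairs with zero observed substitutions are excluded from training
    (their offset t = 0 gives identically zero loss and gradient).  In
    ``fourfold_synonymous`` mode the loss mask of every pair is first
    restricted to fourfold-degenerate third codon positions (idempotent if
    the masks were already applied).  With ``joint_branch_opt``, gradient
    epochs alternate with per-pair branch-length re-optimization.  The
    model is updated in place; the returned frame holds one row per epoch
    with train/validation placement and CSP losses.
    """
    pairs = list(train_set)
    if config.loss_sites == "fourfold_synonymous":
        pairs = [fourfold_degenerate_mask(p) for p in pairs]
        val_pairs = [fourfold_degenerate_mask(p) for p in (val_set or [])]
    else:
        val_pairs = list(val_set or [])
    pairs = [p for p in pairs if mutation_count(p) > 0]
    if not pairs:
        raise ValueError("training set is empty after zero-substitution exclusion")

    rng = np.random.default_rng(config.seed)
    lr, b1, b2, eps = config.learning_rate, 0.9, 0.999, 1e-8
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    step = 0
    history = []

    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(pairs))
        run_pl, run_ce = 0.0, 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [pairs[i] for i in order[start : start + config.batch_size]]
            grads = model.zero_grads()
            for pcp in batch:
                lb, g = pair_loss_and_grads(
                    model, pcp, config.csp_weight, train=True, rng=rng
                )
                if not np.isfinite(lb.total):
                    raise RuntimeError(
                        f"non-finite loss on pair (sample={pcp.sample_id!r}, "
                        f"family={pcp.family_id!r}): placement="
                        f"{lb.placement_nll}, csp={lb.csp_nll}"
                    )
                run_pl += lb.placement_nll
                run_ce += lb.csp_nll
                for k in grads:
                    grads[k] += g[k]
            reg, reg_grads = model.regularization()
            for k in grads:
                grads[k] /= len(batch)
                if k in reg_grads:
                    grads[k] += reg_grads[k]
            step += 1
            for k, p in model.params.items():
                m_state[k] = b1 * m_state[k] + (1 - b1) * grads[k]
                v_state[k] = b2 * v_state[k] + (1 - b2) * grads[k] ** 2
                mhat = m_state[k] / (1 - b1 ** step)
                vhat = v_state[k] / (1 - b2 ** step)
                p -= lr * mhat / (np.sqrt(vhat) + eps)

        if config.joint_branch_opt:
            for pcp in pairs:
                pcp.branch_length = optimize_branch_length(model, pcp)

        val_pl, val_ce = _dataset_losses(model, val_pairs, config.csp_weight)
        row = {
            "epoch": epoch,
            "train_placement_nll": run_pl / len(pairs),
            "train_csp_nll": run_ce / len(pairs),
            "val_placement_nll": val_pl,
            "val_csp_nll": val_ce,
            "seconds": time.perf_counter() - t0,
        }
        history.append(row)
        if verbose:
            print(
                f"epoch {epoch:4d}  train {row['train_placement_nll']:.4f}"
                f"+{row['train_csp_nll']:.4f}  val {val_pl:.4f}+{val_ce:.4f}"
                f"  {row['seconds']:.2f}s"
            )
    return pd.DataFrame(history)
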