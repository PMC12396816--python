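"""Convolutional and k-mer table models of per-site SHM rates and CSPs.

All models map a parent nucleotide sequence to a per-site mutation rate
``lambda_i > 0`` and a conditional substitution probability (CSP) row
``p_i`` over the three non-parent bases.  The convolutional family embeds
each overlapping 3-mer into a trainable E-dimensional space and convolves
a width-K kernel over the embedding sequence, so the number of parameters
grows linearly in K while the effective context is K+2 bases.  Three
wirings differ in how much the rate and CSP outputs share:

* ``joined`` — one embedding + convolution stack feeds both heads;
* ``hybrid`` — a shared embedding, separate convolution per head;
* ``independent`` — a rate sub-model (one stack) and a CSP sub-model
  (two stacks combined by element-wise addition).

The 5-mer table baseline (and its per-site elaboration) shares the same
prediction interface so training and evaluation are model-agnostic.

Networks are implemented directly in NumPy with analytic gradients: the
models are tiny (a few thousand scalars), which keeps training fast,
dependency-light, and bit-reproducible on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .pcp import AMBIG_3MER_TOKEN, BASES, tokenize_3mers, validate_sequence

WIRINGS = ("joined", "hybrid", "independent")
VOCAB_3MER = 65  # 64 unambiguous 3-mers + 1 ambiguity/boundary token
CSP_WIDTH = 5  # A, C, G, T, ambiguity (ambiguity column always masked out)
SCHEMA_VERSION = "shmconv-model-1"

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvConfig:
    """Architecture hyperparameters of a convolutional SHM model.

    kernel must be odd so the context is symmetric around the focal site;
    the effective context width is kernel + 2 because the embedded 3-mers
    already add one base on either side of the kernel window.
    """

    kernel: int = 11
    embed: int = 7
    filters: int = 19
    dropout: float = 0.3
    wiring: str = "joined"

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and positive, got {self.kernel}")
        if self.embed < 1:
            raise ValueError(f"embed must be >= 1, got {self.embed}")
        if self.filters < 1:
            raise ValueError(f"filters must be >= 1, got {self.filters}")
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.wiring not in WIRINGS:
            raise ValueError(
                f"wiring must be one of {WIRINGS}, got {self.wiring!r}"
            )


def receptive_field(config: ConvConfig) -> int:
    """Effective k-mer context width: kernel + 2.

    A kernel of width K sees K consecutive 3-mer embeddings; the outermost
    3-mers each contribute one base beyond the kernel window, so a model
    with kernel 11 is effectively a 13-mer model.
    """
    return config.kernel + 2


def count_params(config: ConvConfig) -> int:
    """Closed-form count of trainable scalars for a configuration.

    One embedding+convolution stack has 65*E embedding scalars plus
    E*F*K + F convolution weights and biases.  The rate head is F+1, the
    CSP head 5F+5.  Joined uses one stack; hybrid one embedding with two
    convolutions; independent three full stacks.
    """
    K, E, F = config.kernel, config.embed, config.filters
    stack = VOCAB_3MER * E + (E * F * K + F)
    conv_only = E * F * K + F
    rate_head = F + 1
    csp_head = CSP_WIDTH * F + CSP_WIDTH
    if config.wiring == "joined":
        return stack + rate_head + csp_head
    if config.wiring == "hybrid":
        return VOCAB_3MER * E + 2 * conv_only + rate_head + csp_head
    return 3 * stack + rate_head + csp_head


# ---------------------------------------------------------------------------
# prediction container
# ---------------------------------------------------------------------------

@dataclass
class RatePrediction:
    """Per-site rates and CSP rows for one parent sequence.

    ``rates[i] > 0`` is the exponential mutation rate at site i; ``csp[i]``
    is a probability row over (A, C, G, T) with zero mass on the parent
    base.  ``flagged[i]`` is True where the parent base is ambiguous, in
    which case the CSP row is a placeholder (uniform over all four bases)
    and should not enter losses or metrics.
    """

    rates: np.ndarray
    csp: np.ndarray
    flagged: np.ndarray


def _masked_csp(logits: np.ndarray, parent: str) -> tuple[np.ndarray, np.ndarray]:
    """Softmax the 5-wide CSP logits into rows over (A,C,G,T).

    The ambiguity column and the parent-base column are forced to -inf
    before normalization, so each row is a distribution over the three
    non-parent bases.  Rows with an ambiguous parent base are flagged and
    normalized over all four bases instead.
    """
    L = logits.shape[0]
    masked = logits.copy()
    masked[:, 4] = -np.inf
    flagged = np.zeros(L, dtype=bool)
    for i, b in enumerate(parent):
        if b in _BASE_INDEX:
            masked[i, _BASE_INDEX[b]] = -np.inf
        else:
            flagged[i] = True
    masked -= masked.max(axis=1, keepdims=True)
    ex = np.exp(masked)
    csp = ex / ex.sum(axis=1, keepdims=True)
    return csp[:, :4], flagged


# ---------------------------------------------------------------------------
# layers (forward + analytic backward)
# ---------------------------------------------------------------------------

def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-length 1-D convolution: x (L,E), w (F,K,E), b (F) -> (L,F).

    Symmetric zero padding of (K-1)/2 keeps one output per input site.
    """
    K = w.shape[1]
    half = (K - 1) // 2
    xp = np.pad(x, ((half, half), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (K, x.shape[1]))[:, 0]
    return np.einsum("lke,fke->lf", windows, w) + b


def _conv1d_backward(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of _conv1d: returns (dx, dw, db)."""
    K = w.shape[1]
    half = (K - 1) // 2
    xp = np.pad(x, ((half, half), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (K, x.shape[1]))[:, 0]
    dw = np.einsum("lke,lf->fke", windows, dout)
    db = dout.sum(axis=0)
    # scatter dout back through the sliding windows
    dxp = np.zeros_like(xp)
    for k in range(K):
        dxp[k : k + x.shape[0]] += dout @ w[:, k, :]
    dx = dxp[half : half + x.shape[0]] if half else dxp
    return dx, dw, db


class _Stack:
    """Embedding lookup + same-length convolution, as named parameters."""

    def __init__(self, prefix: str, share_embedding_with: str | None = None):
        self.prefix = prefix
        self.emb_name = (share_embedding_with or prefix) + ".emb"
        self.w_name = prefix + ".conv_w"
        self.b_name = prefix + ".conv_b"

    def init(self, params: dict, cfg: ConvConfig, rng: np.random.Generator) -> None:
        K, E, F = cfg.kernel, cfg.embed, cfg.filters
        if self.emb_name not in params:
            params[self.emb_name] = rng.normal(0.0, 1.0, size=(VOCAB_3MER, E))
        params[self.w_name] = rng.normal(0.0, np.sqrt(2.0 / (E * K)), size=(F, K, E))
        params[self.b_name] = np.zeros(F)

    def forward(self, params: dict, tokens: np.ndarray):
        x = params[self.emb_name][tokens]
        out = _conv1d(x, params[self.w_name], params[self.b_name])
        return out, x

    def backward(
        self, params: dict, grads: dict, tokens: np.ndarray, x: np.ndarray,
        dout: np.ndarray,
    ) -> None:
        dx, dw, db = _conv1d_backward(x, params[self.w_name], dout)
        grads[self.w_name] += dw
        grads[self.b_name] += db
        np.add.at(grads[self.emb_name], tokens, dx)


def _relu_dropout(
    pre: np.ndarray, dropout: float, train: bool, rng: np.random.Generator | None
):
    """Rectifier followed by inverted dropout (active in training only)."""
    act = np.maximum(pre, 0.0)
    if train and dropout > 0.0:
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        keep = (rng.random(act.shape) >= dropout) / (1.0 - dropout)
        return act * keep, (pre > 0, keep)
    return act, (pre > 0, None)


def _relu_dropout_backward(dact: np.ndarray, cache) -> np.ndarray:
    pos, keep = cache
    if keep is not None:
        dact = dact * keep
    return dact * pos


# ---------------------------------------------------------------------------
# model classes
# ---------------------------------------------------------------------------

class SHMModel:
    """Common interface: forward to (log-rates, CSP logits), backward, I/O."""

    params: dict[str, np.ndarray]

    def forward(self, parent: str, train: bool = False,
                rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, cache, dlog_rates: np.ndarray, dcsp_logits: np.ndarray
                 ) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def regularization(self) -> tuple[float, dict[str, np.ndarray]]:
        """Penalty value and its gradient (zero for unregularized models)."""
        return 0.0, {}

    def predict_rates(self, parent: str) -> RatePrediction:
        """Deterministic (evaluation-mode) rates and CSP rows."""
        validate_sequence(parent)
        log_rates, csp_logits, _ = self.forward(parent, train=False)
        csp, flagged = _masked_csp(csp_logits, parent)
        return RatePrediction(rates=np.exp(log_rates), csp=csp, flagged=flagged)

    # -- serialization ------------------------------------------------------

    def _config_dict(self) -> dict:
        raise NotImplementedError

    def save(self, path) -> None:
        payload = {
            "schema": SCHEMA_VERSION,
            "model_class": type(self).__name__,
            "config": self._config_dict(),
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def load(path) -> "SHMModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model schema {payload.get('schema')!r}; "
                f"expected {SCHEMA_VERSION!r}"
            )
        cls = {
            "ConvModel": ConvModel,
            "FivemerModel": FivemerModel,
            "SitewiseFivemerModel": SitewiseFivemerModel,
        }[payload["model_class"]]
        model = cls._from_config_dict(payload["config"])
        for k, v in payload["params"].items():
            arr = np.asarray(v, dtype=float)
            if arr.shape != model.params[k].shape:
                raise ValueError(f"parameter {k} has wrong shape in file")
            model.params[k] = arr
        return model


class ConvModel(SHMModel):
    """A 3-mer-embedding convolutional SHM model (any of the three wirings)."""

    def __init__(self, config: ConvConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.params = {}
        if config.wiring == "joined":
            self.stacks = {"trunk": _Stack("trunk")}
            self._rate_stacks = ["trunk"]
            self._csp_stacks = ["trunk"]
        elif config.wiring == "hybrid":
            self.stacks = {
                "rate": _Stack("rate", share_embedding_with="shared"),
                "csp": _Stack("csp", share_embedding_with="shared"),
            }
            self._rate_stacks = ["rate"]
            self._csp_stacks = ["csp"]
        else:  # independent
            self.stacks = {
                "rate": _Stack("rate"),
                "csp_a": _Stack("csp_a"),
                "csp_b": _Stack("csp_b"),
            }
            self._rate_stacks = ["rate"]
            self._csp_stacks = ["csp_a", "csp_b"]
        for st in self.stacks.values():
            st.init(self.params, config, rng)
        F = config.filters
        self.params["rate_head.w"] = rng.normal(0.0, 1.0 / np.sqrt(F), size=(F,))
        self.params["rate_head.b"] = np.zeros(1)
        self.params["csp_head.w"] = rng.normal(
            0.0, 1.0 / np.sqrt(F), size=(CSP_WIDTH, F)
        )
        self.params["csp_head.b"] = np.zeros(CSP_WIDTH)

    def _config_dict(self) -> dict:
        c = self.config
        return {
            "kernel": c.kernel, "embed": c.embed, "filters": c.filters,
            "dropout": c.dropout, "wiring": c.wiring,
        }

    @classmethod
    def _from_config_dict(cls, d: dict) -> "ConvModel":
        return cls(ConvConfig(**d), seed=0)

    def _branch(self, names, tokens, train, rng):
        """Run one or two stacks (summed element-wise), then relu+dropout."""
        pre = None
        xs = []
        for name in names:
            out, x = self.stacks[name].forward(self.params, tokens)
            xs.append(x)
            pre = out if pre is None else pre + out
        act, rd_cache = _relu_dropout(pre, self.config.dropout, train, rng)
        return act, (names, tokens, xs, rd_cache)

    def _branch_backward(self, grads, cache, dact):
        names, tokens, xs, rd_cache = cache
        dpre = _relu_dropout_backward(dact, rd_cache)
        for name, x in zip(names, xs):
            self.stacks[name].backward(self.params, grads, tokens, x, dpre)

    def forward(self, parent: str, train: bool = False,
                rng: np.random.Generator | None = None):
        tokens = tokenize_3mers(parent)
        rate_act, rate_cache = self._branch(self._rate_stacks, tokens, train, rng)
        if self.config.wiring == "joined":
            csp_act, csp_cache = rate_act, None
        else:
            csp_act, csp_cache = self._branch(self._csp_stacks, tokens, train, rng)
        log_rates = rate_act @ self.params["rate_head.w"] + self.params["rate_head.b"][0]
        csp_logits = csp_act @ self.params["csp_head.w"].T + self.params["csp_head.b"]
        cache = (rate_act, rate_cache, csp_act, csp_cache)
        return log_rates, csp_logits, cache

    def backward(self, cache, dlog_rates, dcsp_logits):
        rate_act, rate_cache, csp_act, csp_cache = cache
        grads = self.zero_grads()
        grads["rate_head.w"] += rate_act.T @ dlog_rates
        grads["rate_head.b"] += np.array([dlog_rates.sum()])
        grads["csp_head.w"] += dcsp_logits.T @ csp_act
        grads["csp_head.b"] += dcsp_logits.sum(axis=0)
        drate_act = np.outer(dlog_rates, self.params["rate_head.w"])
        dcsp_act = dcsp_logits @ self.params["csp_head.w"]
        if self.config.wiring == "joined":
            self._branch_backward(grads, rate_cache, drate_act + dcsp_act)
        else:
            self._branch_backward(grads, rate_cache, drate_act)
            self._branch_backward(grads, csp_cache, dcsp_act)
        return grads


def build_model(config: ConvConfig, seed: int = 0) -> ConvModel:
    """Instantiate a convolutional model with seeded weight initialization."""
    return ConvModel(config, seed=seed)


def measured_context_width(
    model: SHMModel, length: int = 60, seed: int = 0, trials: int = 3
) -> int:
    """Empirical context width of a model, by single-base perturbation.

    For random sequences, every base of the interior is substituted in
    turn and the focal-site rate and CSP logits are compared against the
    unperturbed forward pass; the width is 2*d+1 where d is the largest
    |perturbed - focal| offset that changes the focal prediction in any
    trial.  For a convolutional model this measures kernel + 2.
    """
    rng = np.random.default_rng(seed)
    focal = length // 2
    max_d = 0
    for _ in range(trials):
        seq = "".join(rng.choice(list(BASES), size=length))
        log_rates, csp_logits, _ = model.forward(seq)
        for j in range(length):
            for b in BASES:
                if b == seq[j]:
                    continue
                pert = seq[:j] + b + seq[j + 1 :]
                lr, cl, _ = model.forward(pert)
                if (
                    abs(lr[focal] - log_rates[focal]) > 1e-12
                    or np.max(np.abs(cl[focal] - csp_logits[focal])) > 1e-12
                ):
                    max_d = max(max_d, abs(j - focal))
    return 2 * max_d + 1


# ---------------------------------------------------------------------------
# k-mer context and 5-mer table baselines
# ---------------------------------------------------------------------------

def kmer_context(parent: str, i: int, k: int) -> str:
    """The k-mer centered at site i, N-padded beyond sequence boundaries."""
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be odd and positive, got {k}")
    half = k // 2
    padded = "N" * half + parent + "N" * half
    return padded[i : i + k]


def kmer_index(kmer: str) -> int:
    """Base-4 index of an unambiguous k-mer; len(4^k) if it contains N."""
    idx = 0
    for b in kmer:
        if b not in _BASE_INDEX:
            return 4 ** len(kmer)
        idx = 4 * idx + _BASE_INDEX[b]
    return idx


class FivemerModel(SHMModel):
    """Table-lookup 5-mer baseline: one rate and one CSP row per 5-mer.

    1024 unambiguous 5-mers plus one ambiguity token; the lookup is the
    entire forward pass, so the effective context width is exactly 5.
    Trained with the same likelihood as the convolutional models.
    """

    N_KMERS = 4 ** 5 + 1

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.params = {
            "log_rate": rng.normal(0.0, 0.01, size=(self.N_KMERS,)),
            "csp_logits": rng.normal(0.0, 0.01, size=(self.N_KMERS, CSP_WIDTH)),
        }

    def _config_dict(self) -> dict:
        return {}

    @classmethod
    def _from_config_dict(cls, d: dict) -> "FivemerModel":
        return cls(seed=0)

    def _tokens(self, parent: str) -> np.ndarray:
        return np.array(
            [kmer_index(kmer_context(parent, i, 5)) for i in range(len(parent))],
            dtype=np.int64,
        )

    def forward(self, parent: str, train: bool = False,
                rng: np.random.Generator | None = None):
        tokens = self._tokens(parent)
        log_rates = self.params["log_rate"][tokens]
        csp_logits = self.params["csp_logits"][tokens]
        return log_rates, csp_logits, tokens

    def backward(self, cache, dlog_rates, dcsp_logits):
        tokens = cache
        grads = self.zero_grads()
        np.add.at(grads["log_rate"], tokens, dlog_rates)
        np.add.at(grads["csp_logits"], tokens, dcsp_logits)
        return grads


class SitewiseFivemerModel(SHMModel):
    """5-mer mutabilities joined with a per-site log rate factor.

    rate(i) = exp(log gamma(5-mer at i) + log s_i) for sites inside the
    modeled range; sites beyond ``n_sites`` use s_i = 1.  The per-site
    factors carry a small squared-magnitude penalty (coefficient 1e-4)
    to suppress fit artifacts where a position is rarely observed.
    """

    SITE_PENALTY = 1e-4

    def __init__(self, n_sites: int = 500, seed: int = 0):
        self.n_sites = n_sites
        self.fivemer = FivemerModel(seed=seed)
        self.params = dict(self.fivemer.params)
        self.params["log_site"] = np.zeros(n_sites)
        self.fivemer.params = self.params  # share storage

    def _config_dict(self) -> dict:
        return {"n_sites": self.n_sites}

    @classmethod
    def _from_config_dict(cls, d: dict) -> "SitewiseFivemerModel":
        return cls(n_sites=int(d["n_sites"]), seed=0)

    def forward(self, parent: str, train: bool = False,
                rng: np.random.Generator | None = None):
        log_rates, csp_logits, tokens = self.fivemer.forward(parent, train, rng)
        L = len(parent)
        n = min(L, self.n_sites)
        log_rates = log_rates.copy()
        log_rates[:n] += self.params["log_site"][:n]
        return log_rates, csp_logits, (tokens, L)

    def backward(self, cache, dlog_rates, dcsp_logits):
        tokens, L = cache
        grads = self.fivemer.backward(tokens, dlog_rates, dcsp_logits)
        grads["log_site"] = np.zeros(self.n_sites)
        n = min(L, self.n_sites)
        grads["log_site"][:n] += dlog_rates[:n]
        return grads

    def regularization(self) -> tuple[float, dict[str, np.ndarray]]:
        s = self.params["log_site"]
        return (
            float(self.SITE_PENALTY * np.sum(s ** 2)),
            {"log_site": 2.0 * self.SITE_PENALTY * s},
        )
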