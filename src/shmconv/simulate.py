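"""Synthetic PCP generator from a known context-dependent SHM truth model.

The generator realizes the same stochastic process the models assume: each
site of a parent sequence carries an independent exponential mutation
clock whose rate depends on the site's k-mer context *in the parent*
(mutations are treated as simultaneous, so contexts never update), and a
mutated site draws its new base from the k-mer's CSP row.  This gives
desk-scale datasets with a fully known truth for calibration and
parameter-recovery tests.

What it deliberately does not emulate: selection, indels, clonal/
phylogenetic correlation between pairs, sequencing error, and the strong
5'-coverage gradient of real repertoire data.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .models import SHMModel, kmer_context, kmer_index
from .pcp import BASES, ParentChildPair, PcpDataset, normalized_mutation_count

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STOP_CODONS = {"TAA", "TAG", "TGA"}

# default branch-length law: log-uniform over a range whose normalized
# mutation counts bracket the few-mutations-per-pair regime of real
# clonal-family edges
DEFAULT_BRANCH_LAW = ("loguniform", 0.005, 0.1)


@dataclass
class TrueModel:
    """Generative k-mer rate and CSP tables.

    ``rates`` has one positive rate per unambiguous k-mer (base-4 order);
    ``csp`` one probability row over (A,C,G,T) per k-mer with zero mass on
    the center base.  Ambiguous or boundary contexts fall back to the
    geometric-mean rate and a uniform CSP over the non-parent bases.
    """

    k: int
    rates: np.ndarray
    csp: np.ndarray

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and positive")
        n = 4 ** self.k
        self.rates = np.asarray(self.rates, dtype=float)
        self.csp = np.asarray(self.csp, dtype=float)
        if self.rates.shape != (n,) or self.csp.shape != (n, 4):
            raise ValueError("table shapes must be (4^k,) and (4^k, 4)")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be strictly positive")
        if not np.allclose(self.csp.sum(axis=1), 1.0):
            raise ValueError("CSP rows must sum to 1")
        center = self.k // 2
        for idx in range(n):
            if self.csp[idx, (idx >> (2 * (self.k - 1 - center))) & 3] != 0:
                raise ValueError("CSP rows must put zero mass on the center base")

    @property
    def fallback_rate(self) -> float:
        """Geometric-mean rate, used for N-containing/boundary contexts."""
        return float(np.exp(np.mean(np.log(self.rates))))

    def site_rates(self, parent: str) -> np.ndarray:
        """Per-site rates for a parent sequence (with boundary fallback)."""
        out = np.empty(len(parent))
        for i in range(len(parent)):
            idx = kmer_index(kmer_context(parent, i, self.k))
            out[i] = self.rates[idx] if idx < 4 ** self.k else self.fallback_rate
        return out

    def csp_row(self, parent: str, i: int) -> np.ndarray:
        """CSP row over (A,C,G,T) for site i (uniform fallback)."""
        idx = kmer_index(kmer_context(parent, i, self.k))
        if idx < 4 ** self.k:
            return self.csp[idx]
        row = np.full(4, 1.0 / 3.0)
        if parent[i] in _BASE_INDEX:
            row[_BASE_INDEX[parent[i]]] = 0.0
        else:
            row[:] = 0.25
        return row


def _all_kmers(k: int) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [km + b for km in kmers for b in BASES]
    return kmers


def random_true_model(k: int = 3, seed: int = 0, log_rate_sd: float = 1.0) -> TrueModel:
    """A random truth: log-normal rates, Dirichlet(1,1,1) CSP rows.

    ``log_rate_sd`` = 1 gives roughly a 50-fold spread between hot and
    cold contexts, comparable to the dynamic range of published 5-mer
    mutability tables.
    """
    rng = np.random.default_rng(seed)
    n = 4 ** k
    rates = np.exp(rng.normal(0.0, log_rate_sd, size=n))
    rates /= rates.mean()  # fix the scale; only relative rates are identified
    csp = np.zeros((n, 4))
    center = k // 2
    for idx, kmer in enumerate(_all_kmers(k)):
        others = [j for j in range(4) if j != _BASE_INDEX[kmer[center]]]
        csp[idx, others] = rng.dirichlet(np.ones(3))
    return TrueModel(k=k, rates=rates, csp=csp)


def write_true_model(model: TrueModel, path) -> None:
    df = pd.DataFrame(
        {
            "kmer": _all_kmers(model.k),
            "rate": [repr(float(r)) for r in model.rates],
            **{
                f"csp_{b}": [repr(float(x)) for x in model.csp[:, j]]
                for j, b in enumerate(BASES)
            },
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_true_model(path) -> TrueModel:
    df = pd.read_csv(path, sep="\t", dtype={"kmer": str},
                     float_precision="round_trip")
    k = len(df["kmer"].iloc[0])
    order = np.argsort([kmer_index(km) for km in df["kmer"]])
    rates = df["rate"].to_numpy(float)[order]
    csp = np.column_stack([df[f"csp_{b}"].to_numpy(float) for b in BASES])[order]
    return TrueModel(k=k, rates=rates, csp=csp)


# ---------------------------------------------------------------------------
# sequence generation
# ---------------------------------------------------------------------------

def random_parent(length: int, seed: int | np.random.Generator = 0) -> str:
    """An i.i.d.-uniform A/C/G/T sequence, reproducible under the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "".join(rng.choice(list(BASES), size=length))


def random_in_frame_parent(length: int, seed: int | np.random.Generator = 0) -> str:
    """A start codon followed by uniform non-stop codons (length // 3 codons)."""
    if length < 3:
        raise ValueError("in-frame parent needs length >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = ["ATG"]
    while 3 * len(codons) + 2 < length:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOP_CODONS:
            codons.append(codon)
    seq = "".join(codons)
    return seq + random_parent(length - len(seq), rng) if len(seq) < length else seq


def simulate_child(
    parent: str,
    true_model: TrueModel,
    t: float,
    seed: int | np.random.Generator = 0,
) -> str:
    """Mutate a parent over branch length t under the truth model.

    Each site independently mutates with probability 1 - exp(-t * rate of
    its parent k-mer context); a mutated site draws its new base from the
    context's CSP row, which never returns the parent base.
    """
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = true_model.site_rates(parent)
    p_mut = -np.expm1(-t * rates)
    mutate = rng.random(len(parent)) < p_mut
    child = list(parent)
    for i in np.nonzero(mutate)[0]:
        child[i] = BASES[rng.choice(4, p=true_model.csp_row(parent, i))]
    return "".join(child)


@dataclass
class SimConfig:
    """Shape of a simulated dataset.

    ``branch_length_law`` is ("fixed", t) or ("loguniform", lo, hi);
    ``germline`` supplies a common parent sequence, else each pair draws an
    independent uniform-random parent.  ``in_frame`` makes parents begin
    with a start codon and contain no in-frame stops, for synonymous-
    masking fixtures.
    """

    n_pairs: int = 100
    length: int = 300
    branch_length_law: tuple = DEFAULT_BRANCH_LAW
    germline: str | None = None
    in_frame: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.branch_length_law[0] not in ("fixed", "loguniform"):
            raise ValueError(
                f"unknown branch-length law {self.branch_length_law[0]!r}"
            )


def _draw_branch_length(law: tuple, rng: np.random.Generator) -> float:
    if law[0] == "fixed":
        return float(law[1])
    lo, hi = float(law[1]), float(law[2])
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def simulate_dataset(config: SimConfig, true_model: TrueModel) -> PcpDataset:
    """Generate a PCP dataset from the truth model.

    Stored branch lengths are recomputed as normalized mutation counts to
    mimic the real pipeline's offsets; the drawn (true) branch lengths are
    kept on the returned dataset as ``true_branch_lengths``.
    """
    if config.length < true_model.k:
        raise ValueError("sequence length must be >= context width k")
    rng = np.random.default_rng(config.seed)
    pcps, true_ts = [], []
    for j in range(config.n_pairs):
        if config.germline is not None:
            parent = config.germline
        elif config.in_frame:
            parent = random_in_frame_parent(config.length, rng)
        else:
            parent = random_parent(config.length, rng)
        t = _draw_branch_length(config.branch_length_law, rng)
        child = simulate_child(parent, true_model, t, rng)
        pair = ParentChildPair(
            parent=parent,
            child=child,
            sample_id="sim",
            family_id=f"fam{j}",
        )
        pair.branch_length = normalized_mutation_count(pair)
        pcps.append(pair)
        true_ts.append(t)
    dataset = PcpDataset(
        pcps,
        provenance=f"simulated (k={true_model.k}, n={config.n_pairs}, "
        f"L={config.length}, law={config.branch_length_law}, seed={config.seed})",
    )
    dataset.true_branch_lengths = np.array(true_ts)
    return dataset


class TrueModelPredictor(SHMModel):
    """Adapter exposing a TrueModel through the prediction interface.

    Lets the generative truth be evaluated with the same metrics as fitted
    models (self-consistency checks, oracle baselines).  Not trainable.
    """

    def __init__(self, true_model: TrueModel):
        self.true_model = true_model
        self.params = {}

    def forward(self, parent: str, train: bool = False,
                rng: np.random.Generator | None = None):
        tm = self.true_model
        log_rates = np.log(tm.site_rates(parent))
        logits = np.full((len(parent), 5), -np.inf)
        with np.errstate(divide="ignore"):
            for i in range(len(parent)):
                logits[i, :4] = np.log(tm.csp_row(parent, i))
        return log_rates, logits, None

    def backward(self, cache, dlog_rates, dcsp_logits):
        raise NotImplementedError("the truth model is not trainable")


# ---------------------------------------------------------------------------
# parameter recovery
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    rate_rank_correlation: float
    mean_csp_tv: float
    n_sites: int


def parameter_recovery_report(
    true_model: TrueModel,
    fitted_model: SHMModel,
    probes: list[str],
) -> RecoveryReport:
    """Compare fitted against true predictions on probe sequences.

    Per-site rates are compared by Spearman rank correlation (the overall
    rate scale is not identified, ranks are); CSP rows by mean total-
    variation distance.  Boundary sites whose true context is N-padded are
    excluded.
    """
    if not probes:
        raise ValueError("probe set must be non-empty")
    half = true_model.k // 2
    true_rates, fit_rates, tvs = [], [], []
    for seq in probes:
        pred = fitted_model.predict_rates(seq)
        tr = true_model.site_rates(seq)
        for i in range(half, len(seq) - half):
            true_rates.append(tr[i])
            fit_rates.append(pred.rates[i])
            tvs.append(
                0.5 * float(np.abs(true_model.csp_row(seq, i) - pred.csp[i]).sum())
            )
    rho = spearmanr(true_rates, fit_rates).statistic
    return RecoveryReport(
        rate_rank_correlation=float(rho),
        mean_csp_tv=float(np.mean(tvs)),
        n_sites=len(tvs),
    )
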