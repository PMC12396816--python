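"""Parent–child pair (PCP) data model for somatic hypermutation analysis.

A PCP is one edge of a B-cell clonal-family phylogeny: an aligned, gap-free
(parent, child) pair of IgH nucleotide sequences together with a branch
length ``t`` on the expected-substitutions-per-site scale.  Sites where
either sequence carries the ambiguity symbol ``N`` (e.g. 5' positions with
missing reads) are excluded from likelihoods and metrics via a per-site
boolean ``loss_mask``.

The module also provides 3-mer tokenization for the convolutional models,
the fourfold-degenerate (synonymous) site mask, the mutation-count edge
filter, PCP extraction from trees, and delimited-text I/O.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

BASES = "ACGT"
ALPHABET = "ACGTN"
AMBIG_3MER_TOKEN = 64  # 64 unambiguous 3-mers + this ambiguity/boundary token

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_SYMBOL_CODE = {s: i for i, s in enumerate(ALPHABET)}  # N -> 4


def _fourfold_prefixes() -> frozenset[str]:
    """Codon prefixes b1 b2 such that b1 b2 * encodes one amino acid for all
    four third bases, under the standard genetic code."""
    out = set()
    for b1 in BASES:
        for b2 in BASES:
            aas = {str(Seq(b1 + b2 + b3).translate()) for b3 in BASES}
            if len(aas) == 1 and "*" not in aas:
                out.add(b1 + b2)
    return frozenset(out)


FOURFOLD_PREFIXES = _fourfold_prefixes()


def validate_sequence(symbols: str, name: str = "sequence") -> str:
    """Check a nucleotide string over {A,C,G,T,N}; returns it unchanged."""
    if not isinstance(symbols, str) or len(symbols) < 1:
        raise ValueError(f"{name} must be a non-empty string")
    for pos, sym in enumerate(symbols):
        if sym not in _SYMBOL_CODE:
            raise ValueError(
                f"{name} has illegal symbol {sym!r} at position {pos}"
            )
    return symbols


def sequence_codes(seq: str) -> np.ndarray:
    """Integer codes A,C,G,T,N -> 0..4 as a small array."""
    return np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGTN", bytes(range(5)))),
        dtype=np.uint8,
    ).astype(np.int64)


@dataclass
class ParentChildPair:
    """An aligned parent/child sequence pair with branch length and mask.

    ``loss_mask[i]`` is True where site ``i`` contributes to the loss and to
    evaluation metrics; it is always False where parent or child is ``N``.
    """

    parent: str
    child: str
    branch_length: float = 0.0
    sample_id: str = ""
    family_id: str = ""
    loss_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        validate_sequence(self.parent, "parent")
        validate_sequence(self.child, "child")
        if len(self.parent) != len(self.child):
            raise ValueError(
                f"parent length {len(self.parent)} != child length "
                f"{len(self.child)}: pairs must be aligned and gap-free"
            )
        if not self.branch_length >= 0:
            raise ValueError(f"branch length must be >= 0, got {self.branch_length}")
        informative = (sequence_codes(self.parent) < 4) & (
            sequence_codes(self.child) < 4
        )
        if self.loss_mask is None:
            self.loss_mask = informative
        else:
            self.loss_mask = np.asarray(self.loss_mask, dtype=bool)
            if self.loss_mask.shape != (len(self.parent),):
                raise ValueError("loss_mask length must equal sequence length")
            # an N site can never be unmasked
            self.loss_mask = self.loss_mask & informative

    def __len__(self) -> int:
        return len(self.parent)


@dataclass
class PcpDataset:
    """Ordered collection of ParentChildPair with free-text provenance."""

    pcps: list[ParentChildPair] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.pcps)

    def __iter__(self):
        return iter(self.pcps)

    def __getitem__(self, i):
        return self.pcps[i]


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

def tokenize_3mers(seq: str) -> np.ndarray:
    """Map each site to the index of its centered 3-mer.

    The 3-mer at site i is sites (i-1, i, i+1); an unambiguous 3-mer
    b1 b2 b3 gets index 16*v(b1) + 4*v(b2) + v(b3) with v(A,C,G,T) =
    (0,1,2,3).  Any 3-mer containing N or running off a sequence boundary
    maps to the ambiguity token 64, so positions 0 and L-1 are always 64.
    """
    validate_sequence(seq)
    codes = sequence_codes(seq)
    L = len(codes)
    tokens = np.full(L, AMBIG_3MER_TOKEN, dtype=np.int64)
    if L >= 3:
        left, mid, right = codes[:-2], codes[1:-1], codes[2:]
        ok = (left < 4) & (mid < 4) & (right < 4)
        inner = 16 * left + 4 * mid + right
        tokens[1:-1] = np.where(ok, inner, AMBIG_3MER_TOKEN)
    return tokens


# ---------------------------------------------------------------------------
# mutation indicators, branch lengths, filters
# ---------------------------------------------------------------------------

def mutation_indicators(pcp: ParentChildPair) -> tuple[np.ndarray, np.ndarray]:
    """Per-site mutation indicators and the informative-site mask.

    ``m[i]`` is True iff parent and child differ at site i and both are
    unambiguous bases.  The second array is the pair's loss mask.
    """
    p, c = sequence_codes(pcp.parent), sequence_codes(pcp.child)
    m = (p != c) & (p < 4) & (c < 4)
    return m, pcp.loss_mask.copy()


def mutation_count(pcp: ParentChildPair) -> int:
    """Number of substitutions at informative (unmasked) sites."""
    m, mask = mutation_indicators(pcp)
    return int(np.sum(m & mask))


def normalized_mutation_count(pcp: ParentChildPair) -> float:
    """Branch length t = substitutions / informative sites.

    Masked sites are excluded from numerator and denominator, so t is a
    per-informative-site quantity.  Raises if no site is informative.
    """
    m, mask = mutation_indicators(pcp)
    n_inf = int(mask.sum())
    if n_inf == 0:
        raise ValueError("pair has zero informative sites; t undefined")
    return float(np.sum(m & mask)) / n_inf


def filter_by_mutation_count(
    dataset: PcpDataset, max_exclusive: int = 10
) -> PcpDataset:
    """Keep pairs with fewer than ``max_exclusive`` substitutions.

    Long edges mostly reflect alignment problems rather than single rounds
    of hypermutation; the conventional cutoff keeps edges with < 10
    mutations.  Order is preserved; an empty result is allowed.
    """
    kept = [p for p in dataset if mutation_count(p) < max_exclusive]
    return PcpDataset(kept, provenance=dataset.provenance)


# ---------------------------------------------------------------------------
# fourfold-degenerate (synonymous) masking
# ---------------------------------------------------------------------------

def fourfold_degenerate_mask(
    pcp: ParentChildPair, frame_offset: int = 0
) -> ParentChildPair:
    """Restrict the loss mask to fourfold-degenerate third codon positions.

    Each complete codon of the parent (reading frame starting at
    ``frame_offset``) is classified against the standard genetic code: if
    its first two bases form a fourfold family (CT,GT,TC,CC,AC,GC,CG,GG),
    the third position stays unmasked; every other site — first and second
    codon positions, non-fourfold third positions, codons containing N,
    sites before the frame offset, and any trailing partial codon — is
    masked.  Mutations at the retained sites are synonymous by
    construction.  Idempotent, and never unmasks an ambiguity-masked site.
    """
    if frame_offset < 0:
        raise ValueError(f"frame_offset must be >= 0, got {frame_offset}")
    L = len(pcp)
    keep = np.zeros(L, dtype=bool)
    for start in range(frame_offset, L - 2, 3):
        codon = pcp.parent[start : start + 3]
        if "N" not in codon and codon[:2] in FOURFOLD_PREFIXES:
            keep[start + 2] = True
    return replace(pcp, loss_mask=pcp.loss_mask & keep)


# ---------------------------------------------------------------------------
# tree extraction
# ---------------------------------------------------------------------------

def extract_pcps_from_tree(
    newick: str, node_sequences: dict[str, str], naive_id: str
) -> PcpDataset:
    """One PCP per tree edge, excluding the naive-outgroup edge.

    Every node (internal and leaf) must be named and present in
    ``node_sequences``.  The parent of each PCP is the sequence at the
    rootward node of the edge; the edge incident to ``naive_id`` is
    omitted because the naive (germline) sequence is the outgroup used to
    root the tree, not an inferred ancestor.  Branch lengths are
    initialized by :func:`normalized_mutation_count`.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    names = set()
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon is not None else node.label
        if label is None:
            raise ValueError("tree contains an unnamed node")
        node.label = label
        names.add(label)
        if label not in node_sequences:
            raise ValueError(f"no sequence provided for tree node {label!r}")
    if naive_id not in names:
        raise ValueError(f"naive_id {naive_id!r} is not a node of the tree")

    pcps: list[ParentChildPair] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_label = node.parent_node.label
        if naive_id in (node.label, parent_label):
            continue
        pair = ParentChildPair(
            parent=node_sequences[parent_label],
            child=node_sequences[node.label],
            sample_id="",
            family_id="",
        )
        pair.branch_length = normalized_mutation_count(pair)
        pcps.append(pair)
    return PcpDataset(pcps, provenance=f"extracted from tree (naive={naive_id})")


def read_fasta_sequences(path_or_handle) -> dict[str, str]:
    """Name -> sequence map from a FASTA file (uppercased, validated)."""
    out = {}
    for rec in SeqIO.parse(path_or_handle, "fasta"):
        seq = str(rec.seq).upper()
        if "-" in seq:
            raise ValueError(
                f"sequence {rec.id!r} contains gaps; gapped sequences are rejected"
            )
        out[rec.id] = validate_sequence(seq, rec.id)
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["parent", "child", "sample_id", "family_id", "branch_length", "loss_mask"]


def write_pcp_table(dataset: PcpDataset, path, sep: str = "\t") -> None:
    """Write a PCP dataset as delimited text (header required on read).

    ``loss_mask`` is serialized as a 0/1 string so that a write/read round
    trip reproduces sequences, masks and branch lengths bit-exactly.
    """
    rows = [
        {
            "parent": p.parent,
            "child": p.child,
            "sample_id": p.sample_id,
            "family_id": p.family_id,
            "branch_length": repr(float(p.branch_length)),
            "loss_mask": "".join("1" if b else "0" for b in p.loss_mask),
        }
        for p in dataset
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep=sep, index=False)


def read_pcp_table(path, sep: str = "\t") -> PcpDataset:
    """Read a PCP table written by :func:`write_pcp_table` or hand-made.

    Requires ``parent`` and ``child`` columns; ``sample_id``, ``family_id``,
    ``branch_length`` and ``loss_mask`` are optional.  Sequences containing
    gap characters are rejected at load time.  Missing branch lengths are
    filled with the normalized mutation count.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "parent" not in df.columns or "child" not in df.columns:
        raise ValueError("PCP table must have 'parent' and 'child' columns")
    pcps = []
    for _, row in df.iterrows():
        parent, child = row["parent"].upper(), row["child"].upper()
        if "-" in parent or "-" in child:
            raise ValueError("gapped sequences are rejected at load time")
        mask = None
        if "loss_mask" in df.columns and row["loss_mask"]:
            mask = np.array([c == "1" for c in row["loss_mask"]], dtype=bool)
        pair = ParentChildPair(
            parent=parent,
            child=child,
            sample_id=row.get("sample_id", ""),
            family_id=row.get("family_id", ""),
            loss_mask=mask,
        )
        bl = row.get("branch_length", "")
        pair.branch_length = (
            float(bl) if bl else normalized_mutation_count(pair)
        )
        pcps.append(pair)
    return PcpDataset(pcps, provenance=str(path))
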