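"""Codon alignments evolved along the fixed 5-taxon tree (GY94-style).

Substitutions are simulated per codon as a continuous-time jump chain under
a Goldman-Yang style rate matrix: single-nucleotide codon changes only,
transition/transversion ratio kappa, branch-specific omega multiplying
nonsynonymous rates, and target-codon frequencies.  Rates are normalised so
a branch length is the expected number of substitutions per codon at
omega = 1 machinery's own stationary flow, and stop codons are unreachable
by construction.  The truth table records every realised substitution per
branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bkit.codons import (
    GENETIC_CODE,
    SENSE_CODONS,
    decode_codons,
    is_transition,
)
from bkit.phylo import TreeNode, five_taxon_tree


@dataclass
class CodonSimSpec:
    """Parameters for one alignment simulation.

    ``tree`` carries branch lengths (expected substitutions per codon) and a
    per-branch ``omega``; ``codon_freqs`` defaults to uniform over the 61
    sense codons.
    """

    tree: TreeNode
    n_codons: int = 500
    kappa: float = 2.0
    codon_freqs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        for node in self.tree.branches():
            if node.omega is None or node.omega < 0:
                raise ValueError(f"branch {node.name} needs omega >= 0")
        if self.codon_freqs is None:
            self.codon_freqs = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if len(self.codon_freqs) != len(SENSE_CODONS):
            raise ValueError("codon_freqs must have 61 entries")
        if not np.isclose(self.codon_freqs.sum(), 1.0):
            raise ValueError("codon_freqs must sum to 1")


def _rate_matrix(kappa: float, omega: float, freqs: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """GY94 rate matrix restricted to sense codons; returns (Q, syn_mask)."""
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            rate = freqs[j]
            if is_transition(ci[p], cj[p]):
                rate *= kappa
            if GENETIC_CODE[ci] != GENETIC_CODE[cj]:
                rate *= omega
            else:
                syn[i, j] = True
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, syn


def simulate_codon_alignment(spec: CodonSimSpec
                             ) -> tuple[dict[str, str], pd.DataFrame]:
    """Evolve an in-frame gap-free alignment down the tree.

    Returns (sequences by leaf name, truth table with realised per-branch
    synonymous/nonsynonymous substitution counts).  The root sequence is
    drawn from ``codon_freqs``.
    """
    rng = np.random.default_rng(spec.seed)
    n61 = len(SENSE_CODONS)

    # normalising flow: expected substitutions per codon per unit length
    # computed at omega = 1 so branch lengths mean the same on every branch
    Q1, _ = _rate_matrix(spec.kappa, 1.0, spec.codon_freqs)
    norm = float(-(spec.codon_freqs * np.diag(Q1)).sum())

    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def matrices(omega: float) -> tuple[np.ndarray, np.ndarray]:
        if omega not in cache:
            Q, syn = _rate_matrix(spec.kappa, omega, spec.codon_freqs)
            cache[omega] = (Q / norm, syn)
        return cache[omega]

    root_seq = rng.choice(n61, size=spec.n_codons, p=spec.codon_freqs)
    seqs: dict[str, np.ndarray] = {spec.tree.name: root_seq}
    records = []

    for node in spec.tree.preorder():
        if node.parent is None:
            continue
        Q, syn = matrices(float(node.omega))
        out_rate = -np.diag(Q)
        parent = seqs[node.parent.name]
        child = parent.copy()
        nd = sd = 0
        for c in range(spec.n_codons):
            t = 0.0
            cur = child[c]
            while True:
                r = out_rate[cur]
                if r <= 0:
                    break
                t += rng.exponential(1.0 / r)
                if t > node.length:
                    break
                probs = Q[cur].copy()
                probs[cur] = 0.0
                probs /= probs.sum()
                nxt = int(rng.choice(n61, p=probs))
                if syn[cur, nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            child[c] = cur
        seqs[node.name] = child
        records.append({"branch": node.name, "omega": float(node.omega),
                        "length": node.length, "n_nonsyn": nd, "n_syn": sd})

    leaves = {leaf.name: decode_codons(seqs[leaf.name])
              for leaf in spec.tree.leaves()}
    return leaves, pd.DataFrame.from_records(records)
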