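"""All-vs-all bit-score records with planted gene-family structure.

Self scores are fixed at 100, so a planted pair score equals the Hscore the
clustering will see.  Within-family and between-family scores are drawn
uniformly from the given ranges; aligned fractions are set comfortably above
the 1/3 edge rule so the Hscore threshold alone decides edge survival.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def simulate_similarity_graph(
    n_families: int,
    sizes: list[int],
    within_hscore: tuple[float, float] = (40.0, 90.0),
    between_hscore: tuple[float, float] = (0.0, 3.0),
    seed: int = 0,
    aligned_fraction: float = 0.9,
    species_cycle: tuple[str, ...] = ("cheetah", "cat", "tiger", "human"),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Emit bit-score records plus the truth partition.

    Returns ``(records, truth, info)``: records have columns query, target,
    bitscore, qalnfrac, talnfrac (self hits included, maximal); truth maps
    gene -> family id and a cycling species label; info records the seed and
    an ``overlapping_ranges`` warning flag.
    """
    if len(sizes) != n_families:
        raise ValueError("sizes must have one entry per family")
    if any(s < 1 for s in sizes):
        raise ValueError("family sizes must be >= 1")
    overlap = between_hscore[1] >= within_hscore[0]
    if overlap:
        warnings.warn("within/between Hscore ranges overlap; planted families "
                      "may not be recoverable", stacklevel=2)
    rng = np.random.default_rng(seed)

    genes: list[str] = []
    family_of: dict[str, int] = {}
    for f, size in enumerate(sizes):
        for g in range(size):
            name = f"fam{f}_g{g}"
            genes.append(name)
            family_of[name] = f

    rows = []
    for g in genes:
        rows.append((g, g, 100.0, 1.0, 1.0))
    for i, gi in enumerate(genes):
        for gj in genes[i + 1:]:
            lo, hi = (within_hscore if family_of[gi] == family_of[gj]
                      else between_hscore)
            score = float(rng.uniform(lo, hi))
            if score <= 0:
                continue
            rows.append((gi, gj, score, aligned_fraction, aligned_fraction))

    records = pd.DataFrame(rows, columns=["query", "target", "bitscore",
                                          "qalnfrac", "talnfrac"])
    truth = pd.DataFrame({
        "gene": genes,
        "family": [family_of[g] for g in genes],
        "species": [species_cycle[i % len(species_cycle)]
                    for i in range(len(genes))],
    })
    info = {"seed": seed, "overlapping_ranges": overlap}
    return records, truth, info
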