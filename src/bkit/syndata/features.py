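"""Masked references with planted repeats, copy-number gains and depth tracks.

The depth model is per-position read starts: Poisson with mean
``mean_depth * CN / 2`` (negative-binomial when overdispersed), zero inside
assembly gaps.  This is what the read-depth duplication caller consumes;
read-level simulation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from bkit.intervals import Interval, coverage_mask, merge_intervals

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedFeatureSet:
    """Reference sequences plus the truth intervals planted into them.

    All intervals are 0-based half-open.  ``duplications`` maps scaffold ->
    list of ``((start, end), true_cn)`` with integer true copy number >= 3.
    """

    sequences: dict[str, str]
    repeat_mask: dict[str, list[Interval]] = field(default_factory=dict)
    duplications: dict[str, list[tuple[Interval, int]]] = field(default_factory=dict)
    roh: dict[str, list[Interval]] = field(default_factory=dict)
    gaps: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scaf, dups in self.duplications.items():
            L = len(self.sequences[scaf])
            for (s, e), cn in dups:
                if not (0 <= s < e <= L):
                    raise ValueError(f"duplication {(s, e)} outside {scaf} bounds")
                if cn < 3:
                    raise ValueError("planted duplication copy number must be >= 3")
        for coll in (self.repeat_mask, self.roh, self.gaps):
            for scaf, ivs in coll.items():
                L = len(self.sequences[scaf])
                for s, e in ivs:
                    if not (0 <= s < e <= L):
                        raise ValueError(f"interval {(s, e)} outside {scaf} bounds")

    def scaffold_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def copy_number_track(self, scaffold: str) -> np.ndarray:
        """True per-position copy number (2 outside planted gains)."""
        cn = np.full(len(self.sequences[scaffold]), 2.0)
        for (s, e), c in self.duplications.get(scaffold, []):
            cn[s:e] = float(c)
        return cn


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def build_planted_reference(
    length: int = 1_000_000,
    seed: int = 0,
    scaffold: str = "scaf1",
    n_tandem: int = 5,
    tandem_monomer: int = 12,
    tandem_copies: int = 40,
    n_interspersed: int = 5,
    interspersed_length: int = 800,
    interspersed_copies: int = 4,
    duplications: Sequence[tuple[Interval, int]] = (),
    gaps: Sequence[Interval] = (),
    roh: Sequence[Interval] = (),
) -> PlantedFeatureSet:
    """Build one random scaffold with planted repeat structure.

    Tandem repeats are a repeated random monomer; interspersed repeats are a
    random element copied to several loci.  Planted intervals are recorded in
    the mask/truth sets; gap positions become ``N``.
    """
    rng = np.random.default_rng(seed)
    codes = _random_sequence(rng, length)
    mask: list[Interval] = []

    tandem_len = tandem_monomer * tandem_copies
    for _ in range(n_tandem):
        start = int(rng.integers(0, max(1, length - tandem_len)))
        monomer = _random_sequence(rng, tandem_monomer)
        arr = np.tile(monomer, tandem_copies)
        codes[start:start + tandem_len] = arr[: length - start][:tandem_len]
        mask.append((start, min(length, start + tandem_len)))

    if n_interspersed > 0:
        element = _random_sequence(rng, interspersed_length)
        for _ in range(n_interspersed * interspersed_copies):
            start = int(rng.integers(0, max(1, length - interspersed_length)))
            codes[start:start + interspersed_length] = element[: length - start]
            mask.append((start, min(length, start + interspersed_length)))

    seq = "".join(_BASES[codes])
    if gaps:
        chars = list(seq)
        for s, e in gaps:
            chars[s:e] = "N" * (e - s)
        seq = "".join(chars)

    return PlantedFeatureSet(
        sequences={scaffold: seq},
        repeat_mask={scaffold: merge_intervals(mask)},
        duplications={scaffold: [((int(s), int(e)), int(c)) for (s, e), c in duplications]},
        roh={scaffold: list(roh)},
        gaps={scaffold: list(gaps)},
    )


def simulate_depth_track(
    features: PlantedFeatureSet,
    mean_depth: float,
    dispersion: float = 0.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-position read-start counts for every scaffold.

    Counts are Poisson with mean ``mean_depth * CN / 2`` (CN = 2 outside
    planted gains); with ``dispersion`` a > 0 they are negative-binomial with
    variance ``mu + a * mu**2``.  Depth is exactly zero inside assembly gaps.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for scaf, seq in features.sequences.items():
        mu = mean_depth * features.copy_number_track(scaf) / 2.0
        if dispersion == 0:
            depth = rng.poisson(mu)
        else:
            # gamma-Poisson mixture: shape r = 1/a, Var = mu + a mu^2
            r = 1.0 / dispersion
            lam = rng.gamma(shape=r, scale=mu / r)
            depth = rng.poisson(lam)
        gap_mask = coverage_mask(features.gaps.get(scaf, []), len(seq))
        depth[gap_mask] = 0
        out[scaf] = depth.astype(np.int64)
    return out
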