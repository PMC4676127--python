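"""Genetic-code tables and Nei-Gojobori (1986) codon accounting.

Precomputes, for the standard code:

* per-codon synonymous/nonsynonymous site counts (stop-codon neighbours are
  excluded from the per-position fraction, so N + S = 3 per codon);
* for every codon pair, the synonymous/nonsynonymous difference counts
  averaged over all minimal mutational pathways that avoid stop codons.

These tables make pairwise NG86 and per-column branch attribution pure
lookups.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)

GENETIC_CODE: dict[str, str] = {}
for _i, _b1 in enumerate(BASES):
    for _j, _b2 in enumerate(BASES):
        for _k, _b3 in enumerate(BASES):
            GENETIC_CODE[_b1 + _b2 + _b3] = _AMINO[16 * _i + 4 * _j + _k]

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


def codon_sites(codon: str) -> tuple[float, float]:
    """NG86 nonsynonymous and synonymous site counts (N, S) for one codon.

    Each position contributes one site, split by the fraction of its
    non-stop single-nucleotide changes that are synonymous.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    aa = GENETIC_CODE[codon]
    n_sites = s_sites = 0.0
    for p in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[p]:
                continue
            alt = codon[:p] + b + codon[p + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if GENETIC_CODE[alt] == aa:
                syn += 1
        frac = syn / valid if valid else 0.0
        s_sites += frac
        n_sites += 1.0 - frac
    return n_sites, s_sites


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Nd, Sd) between two codons, averaged over minimal stop-free paths."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        nd = sd = 0.0
        ok = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((nd, sd))
    if not paths:
        # every path crosses a stop; fall back to counting through stops
        for order in permutations(diff):
            cur = c1
            nd = sd = 0.0
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1:]
                if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((nd, sd))
    nd = float(np.mean([p[0] for p in paths]))
    sd = float(np.mean([p[1] for p in paths]))
    return nd, sd


# lookup tables over the 61 sense codons
N_SITES = np.array([codon_sites(c)[0] for c in SENSE_CODONS])
S_SITES = np.array([codon_sites(c)[1] for c in SENSE_CODONS])
_n = len(SENSE_CODONS)
ND_TABLE = np.zeros((_n, _n))
SD_TABLE = np.zeros((_n, _n))
for _a in range(_n):
    for _b in range(_a + 1, _n):
        _nd, _sd = _path_counts(SENSE_CODONS[_a], SENSE_CODONS[_b])
        ND_TABLE[_a, _b] = ND_TABLE[_b, _a] = _nd
        SD_TABLE[_a, _b] = SD_TABLE[_b, _a] = _sd


def encode_codons(seq: str) -> np.ndarray:
    """Codon-index array for an in-frame sequence (no stops, no gaps)."""
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    seq = seq.upper()
    try:
        return np.array([CODON_INDEX[seq[i:i + 3]]
                         for i in range(0, len(seq), 3)], dtype=np.int16)
    except KeyError as exc:
        raise ValueError(f"unexpected codon {exc} (stop or ambiguity?)") from exc


def decode_codons(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def jukes_cantor(p: float) -> float:
    """JC correction d = -3/4 ln(1 - 4p/3); returns nan when saturated."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_pair(seq_a: str, seq_b: str, correct: bool = True
              ) -> dict[str, float]:
    """Nei-Gojobori (1986) pairwise counts and rates.

    Returns Nd, Sd (pathway-averaged difference counts), N, S (site counts
    averaged over the two sequences), pN, pS, and Jukes-Cantor corrected
    dN, dS when ``correct``.
    """
    a = encode_codons(seq_a)
    b = encode_codons(seq_b)
    if len(a) != len(b):
        raise ValueError("sequences differ in codon length")
    nd = float(ND_TABLE[a, b].sum())
    sd = float(SD_TABLE[a, b].sum())
    n = float((N_SITES[a] + N_SITES[b]).sum()) / 2.0
    s = float((S_SITES[a] + S_SITES[b]).sum()) / 2.0
    pn = nd / n if n > 0 else 0.0
    ps = sd / s if s > 0 else 0.0
    out = {"Nd": nd, "Sd": sd, "N": n, "S": s, "pN": pn, "pS": ps}
    if correct:
        out["dN"] = jukes_cantor(pn)
        out["dS"] = jukes_cantor(ps)
    else:
        out["dN"], out["dS"] = pn, ps
    return out
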