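"""Read-depth segmental-duplication pipeline.

Stages: extra k-mer masking, 36-bp padding around masked segments, windows
of exactly 1 kbp of unmasked sequence (genomic spans may be longer),
iterative control-region statistics, copy number CN = 2*RD/mean(control RD),
block calling (>= 5 consecutive windows above mean + 3 sd with one window
allowed in (mean + 2 sd, mean + 3 sd], span >= 10 kbp, CN ceiling 100),
cross-sample intersection, and gene overlap at >= 60 %.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from bkit.intervals import (
    Interval,
    coverage_mask,
    intersect_intervals,
    merge_intervals,
    subtract_intervals,
    total_length,
)

MIN_SCAFFOLD_BP = 10_000


@dataclass
class MaskedReference:
    """Sequences with the final mask (repeats + k-mer + padding) and gaps."""

    sequences: dict[str, str]
    mask: dict[str, list[Interval]] = field(default_factory=dict)
    gaps: dict[str, list[Interval]] = field(default_factory=dict)
    sex_scaffolds: frozenset[str] = frozenset()

    def usable_scaffolds(self) -> list[str]:
        return [name for name, seq in self.sequences.items()
                if len(seq) >= MIN_SCAFFOLD_BP and name not in self.sex_scaffolds]


@dataclass
class ControlStats:
    mean: float
    sd: float
    control_idx: np.ndarray
    iterations: int


@dataclass
class DuplicationBlock:
    sample: str
    scaffold: str
    start: int                       # 0-based half-open genomic span
    end: int
    window_idx: list[int]
    mean_cn: float
    gap_trimmed: bool = False
    intervals: list[Interval] = field(default_factory=list)  # span minus gaps

    @property
    def span(self) -> int:
        return self.end - self.start


# --- masking ---------------------------------------------------------------

def kmer_overmask(sequences: Mapping[str, str], k: int = 36, overlap: int = 5,
                  min_hits: int = 3) -> dict[str, list[Interval]]:
    """Mask sampled k-mers that occur ``min_hits`` or more times.

    Scaffolds are partitioned into k-mers of ``k`` bp with adjacent sampled
    k-mers overlapping by ``overlap`` bp (step k - overlap); each sampled
    k-mer is counted by exact forward-strand match over the whole assembly,
    and over-represented ones have their source interval masked.  k-mers
    containing ``N`` are skipped.
    """
    step = k - overlap
    counts: Counter[bytes] = Counter()
    for seq in sequences.values():
        b = seq.upper().encode()
        for i in range(len(b) - k + 1):
            counts[b[i:i + k]] += 1
    out: dict[str, list[Interval]] = {}
    for name, seq in sequences.items():
        b = seq.upper().encode()
        if len(b) < k:
            out[name] = []
            continue
        ivs = []
        for i in range(0, len(b) - k + 1, step):
            kmer = b[i:i + k]
            if b"N" in kmer:
                continue
            if counts[kmer] >= min_hits:
                ivs.append((i, i + k))
        out[name] = merge_intervals(ivs)
    return out


def add_padding(mask: Mapping[str, Sequence[Interval]],
                scaffold_lengths: Mapping[str, int],
                pad: int = 36) -> dict[str, list[Interval]]:
    """Extend every masked segment by ``pad`` bp on each flank, clipped."""
    out = {}
    for name, ivs in mask.items():
        L = scaffold_lengths[name]
        out[name] = merge_intervals(
            (max(0, s - pad), min(L, e + pad)) for s, e in ivs)
    return out


def prepare_reference(sequences: Mapping[str, str],
                      repeat_mask: Mapping[str, Sequence[Interval]],
                      gaps: Mapping[str, Sequence[Interval]] | None = None,
                      sex_scaffolds: Iterable[str] = (),
                      run_kmer_mask: bool = True, pad: int = 36
                      ) -> MaskedReference:
    """Assemble the final masked reference used for window building."""
    gaps = dict(gaps or {})
    lengths = {n: len(s) for n, s in sequences.items()}
    combined = {n: list(repeat_mask.get(n, ())) + list(gaps.get(n, ()))
                for n in sequences}
    if run_kmer_mask:
        extra = kmer_overmask(sequences)
        for n in sequences:
            combined[n] = combined[n] + extra.get(n, [])
    padded = add_padding({n: merge_intervals(v) for n, v in combined.items()},
                         lengths, pad=pad)
    return MaskedReference(sequences=dict(sequences), mask=padded,
                           gaps={n: merge_intervals(v) for n, v in gaps.items()},
                           sex_scaffolds=frozenset(sex_scaffolds))


# --- windows ---------------------------------------------------------------

def build_windows(ref: MaskedReference, unmasked_per_window: int = 1000
                  ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Windows of exactly ``unmasked_per_window`` unmasked positions.

    Unmasked positions are accumulated left to right into consecutive groups;
    the trailing deficient group is dropped.  A window's genomic span is
    [first, last + 1) of its member positions and may exceed 1 kbp.  Returns
    the window table and the per-scaffold unmasked-position arrays (window
    rows carry index ranges ``u_start:u_end`` into them).
    """
    rows = []
    unmasked: dict[str, np.ndarray] = {}
    for name in ref.usable_scaffolds():
        L = len(ref.sequences[name])
        m = coverage_mask(ref.mask.get(name, []), L)
        pos = np.flatnonzero(~m)
        unmasked[name] = pos
        n_win = len(pos) // unmasked_per_window
        for w in range(n_win):
            u0 = w * unmasked_per_window
            u1 = u0 + unmasked_per_window
            rows.append((name, int(pos[u0]), int(pos[u1 - 1]) + 1, u0, u1))
    windows = pd.DataFrame(rows, columns=["scaffold", "start", "end",
                                          "u_start", "u_end"])
    return windows, unmasked


def assign_depth(windows: pd.DataFrame, unmasked: Mapping[str, np.ndarray],
                 depth_track: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Sum per-position read starts over each window's unmasked positions."""
    rd = np.zeros(len(windows), dtype=np.float64)
    for scaf, grp in windows.groupby("scaffold"):
        if scaf not in depth_track:
            raise KeyError(f"depth track missing scaffold {scaf!r}")
        depth = np.asarray(depth_track[scaf])
        cum = np.concatenate([[0], np.cumsum(depth[unmasked[scaf]])])
        rd[grp.index] = (cum[grp["u_end"].to_numpy()]
                         - cum[grp["u_start"].to_numpy()])
    out = windows.copy()
    out["rd"] = rd
    return out


def split_read_starts(read_starts: np.ndarray, read_split: tuple[tuple[int, int], ...]
                      = ((10, 46), (46, 81))) -> np.ndarray:
    """Convert per-position full-read starts into split 36-mer placements.

    Each read contributes one placement per split k-mer, offset by the
    k-mer's start within the read.  Used when raw full-length read starts
    are supplied instead of an already-split track.
    """
    out = np.zeros_like(read_starts)
    for k_start, _k_end in read_split:
        shifted = np.zeros_like(read_starts)
        if k_start < len(read_starts):
            shifted[k_start:] = read_starts[:len(read_starts) - k_start]
        out += shifted
    return out


# --- control statistics and CN ---------------------------------------------

def estimate_controls(rd: np.ndarray, trim_sd: float = 3.0, tol: float = 1e-6,
                      max_iter: int = 50) -> ControlStats:
    """Iteratively trim extreme read-depth windows; the rest are controls.

    Repeat: compute mean/sd over the current set, drop windows farther than
    ``trim_sd`` standard deviations from the mean; stop when the set is
    unchanged, the mean moves less than ``tol``, or ``max_iter`` is reached.
    """
    rd = np.asarray(rd, dtype=np.float64)
    if len(rd) < 20:
        raise ValueError("need at least 20 windows for control estimation")
    idx = np.arange(len(rd))
    mean = float(rd.mean())
    for it in range(1, max_iter + 1):
        sd = float(rd[idx].std())
        keep = np.abs(rd[idx] - mean) <= trim_sd * sd
        if sd == 0 or keep.all():
            return ControlStats(mean=mean, sd=sd, control_idx=idx, iterations=it)
        new_idx = idx[keep]
        if len(new_idx) == 0:
            raise ValueError("control set became empty during trimming "
                             f"(iteration {it}, mean {mean:.2f}, sd {sd:.2f})")
        new_mean = float(rd[new_idx].mean())
        converged = abs(new_mean - mean) < tol
        idx, mean = new_idx, new_mean
        if converged:
            return ControlStats(mean=mean, sd=float(rd[idx].std()),
                                control_idx=idx, iterations=it)
    return ControlStats(mean=mean, sd=float(rd[idx].std()),
                        control_idx=idx, iterations=max_iter)


def compute_cn(windows: pd.DataFrame, controls: ControlStats) -> pd.DataFrame:
    """CN = 2 * RD / mean(control RD) per window."""
    if controls.mean <= 0:
        raise ValueError("control mean must be > 0")
    out = windows.copy()
    out["cn"] = 2.0 * out["rd"] / controls.mean
    return out


def control_mean_cn(windows: pd.DataFrame, controls: ControlStats) -> float:
    """Mean CN over control windows (centred at 2 for a uniform genome)."""
    return float(windows["cn"].to_numpy()[controls.control_idx].mean())


# --- block calling ----------------------------------------------------------

def call_blocks(windows: pd.DataFrame, controls: ControlStats,
                gaps: Mapping[str, Sequence[Interval]] | None = None,
                sample: str = "sample", min_windows: int = 5,
                hard_sd: float = 3.0, soft_sd: float = 2.0,
                soft_allowance: int = 1, min_span_bp: int = 10_000,
                cn_ceiling: float = 100.0) -> list[DuplicationBlock]:
    """Call duplication blocks from per-window copy numbers.

    Thresholds come from the control-window CN distribution: hard =
    mean + hard_sd * sd, soft = mean + soft_sd * sd.  A candidate run is a
    maximal stretch of consecutive windows above the hard threshold; two
    such stretches separated by a single window that still clears the soft
    threshold are bridged (left to right, at most ``soft_allowance`` bridges
    per run), so a run's windows are all above the hard cutoff except for
    the allowed dips.  A run qualifies when it has >= ``min_windows``
    windows, genomic span >= ``min_span_bp`` and no member CN above
    ``cn_ceiling``.  Gap intervals are subtracted from the reported spans.
    """
    gaps = gaps or {}
    cn = windows["cn"].to_numpy()
    ctrl_cn = cn[controls.control_idx]
    mean_cn = float(ctrl_cn.mean())
    sd_cn = float(ctrl_cn.std())
    hard = mean_cn + hard_sd * sd_cn
    soft = mean_cn + soft_sd * sd_cn

    blocks: list[DuplicationBlock] = []
    for scaf, grp in windows.groupby("scaffold", sort=False):
        c = grp["cn"].to_numpy()
        above = c > hard
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        runs = [[a, b] for a, b in zip(edges[::2], edges[1::2])]
        merged: list[list[int]] = []
        used = 0
        for run in runs:
            if (merged and used < soft_allowance
                    and run[0] == merged[-1][1] + 1
                    and c[merged[-1][1]] > soft):
                merged[-1][1] = run[1]
                used += 1
            else:
                merged.append(run)
                used = 0
        for a, b in merged:
            run = np.arange(a, b)
            if len(run) < min_windows:
                continue
            start = int(grp["start"].to_numpy()[a])
            end = int(grp["end"].to_numpy()[b - 1])
            if end - start < min_span_bp:
                continue
            if np.any(c[run] > cn_ceiling):
                continue
            scaffold_gaps = gaps.get(scaf, [])
            trimmed = subtract_intervals([(start, end)], scaffold_gaps)
            blocks.append(DuplicationBlock(
                sample=sample, scaffold=str(scaf), start=start, end=end,
                window_idx=[int(i) for i in grp.index.to_numpy()[run]],
                mean_cn=float(c[run].mean()),
                gap_trimmed=trimmed != [(start, end)],
                intervals=trimmed,
            ))
    return blocks


def blocks_to_intervals(blocks: Iterable[DuplicationBlock]
                        ) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for b in blocks:
        out.setdefault(b.scaffold, []).extend(b.intervals or [(b.start, b.end)])
    return {scaf: merge_intervals(ivs) for scaf, ivs in out.items()}


def shared_blocks(per_sample: Mapping[str, Mapping[str, Sequence[Interval]]]
                  ) -> tuple[dict[str, list[Interval]], dict]:
    """Base-pair-level intersection of duplication calls across samples.

    Returns the shared interval set plus a summary with per-sample totals
    and the union size.
    """
    samples = list(per_sample)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    scaffolds = {s for m in per_sample.values() for s in m}
    shared: dict[str, list[Interval]] = {}
    union: dict[str, list[Interval]] = {}
    for scaf in scaffolds:
        ivs = merge_intervals(per_sample[samples[0]].get(scaf, []))
        uni = list(ivs)
        for s in samples[1:]:
            ivs = intersect_intervals(ivs, per_sample[s].get(scaf, []))
            uni.extend(per_sample[s].get(scaf, []))
        if ivs:
            shared[scaf] = ivs
        union[scaf] = merge_intervals(uni)
    summary = {
        "per_sample_bp": {s: sum(total_length(m.get(sc, []))
                                 for sc in scaffolds)
                          for s, m in per_sample.items()},
        "shared_bp": sum(total_length(v) for v in shared.values()),
        "union_bp": sum(total_length(v) for v in union.values()),
    }
    return shared, summary


def gene_overlap(shared: Mapping[str, Sequence[Interval]], genes: pd.DataFrame,
                 min_fraction: float = 0.60) -> list[str]:
    """Genes whose span overlaps shared duplications by >= ``min_fraction``.

    ``genes`` columns: gene_id, scaffold, start, end (0-based half-open).
    """
    hits = []
    for row in genes.itertuples(index=False):
        length = row.end - row.start
        if length <= 0:
            continue
        ov = total_length(intersect_intervals(
            [(row.start, row.end)], shared.get(row.scaffold, [])))
        if ov / length >= min_fraction:
            hits.append(row.gene_id)
    return hits
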