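"""Genome-diversity battery: SNV filtering, rates, windows, ROH, repeats.

Coordinate dialects are the standard ones throughout: variant positions are
1-based points (VCF), mask and window intervals 0-based half-open (BED).  A
1-based position ``pos`` falls in interval (start, end) iff
``start < pos <= end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from bkit.intervals import Interval, points_in_intervals
from bkit.io import VariantTable


@dataclass
class MaskSet:
    """Labelled mask intervals per scaffold (0-based half-open)."""

    intervals: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    @classmethod
    def from_bed(cls, bed: Mapping[str, Sequence[Interval]],
                 label: str = "interspersed") -> "MaskSet":
        return cls({scaf: [(s, e, label) for s, e in ivs]
                    for scaf, ivs in bed.items()})

    def plain(self) -> dict[str, list[Interval]]:
        return {scaf: [(s, e) for s, e, _ in ivs]
                for scaf, ivs in self.intervals.items()}


# --- filters ----------------------------------------------------------------

def filter_by_depth(table: VariantTable, min_depth: int = 5,
                    max_depth: int = 30) -> tuple[VariantTable, dict]:
    """Keep sites where every sample's depth lies in [min_depth, max_depth].

    Bounds are inclusive.  Sites with a missing (zero-coded) depth in any
    sample are dropped and counted in the filter log.
    """
    d = table.depth
    in_range = (d >= min_depth) & (d <= max_depth)
    keep = in_range.all(axis=1)
    missing = (d <= 0).any(axis=1)
    log = {
        "input_sites": int(table.n_sites),
        "kept_sites": int(keep.sum()),
        "dropped_missing_depth": int((missing & ~keep).sum()),
    }
    return table.subset(keep), log


def filter_by_mask(table: VariantTable, mask: MaskSet, digits: int = 0
                   ) -> tuple[VariantTable, VariantTable, float]:
    """Remove sites inside repeat-mask intervals.

    Returns (kept, removed, retention percent).  The retention percent is
    rounded to ``digits`` decimals, matching how such numbers are printed.
    Mask scaffolds absent from the table are ignored.
    """
    plain = mask.plain()
    removed_flags = np.zeros(table.n_sites, dtype=bool)
    for scaf in np.unique(table.scaffold.astype(str)):
        sel = table.scaffold.astype(str) == scaf
        ivs = plain.get(scaf, [])
        if ivs:
            # 1-based point pos in (start, end] <=> 0-based pos-1 in [start, end)
            removed_flags[sel] = points_in_intervals(table.pos[sel] - 1, ivs)
    kept = table.subset(~removed_flags)
    removed = table.subset(removed_flags)
    retention = retention_percent(table.n_sites, kept.n_sites, digits)
    return kept, removed, retention


def retention_percent(n_input: int, n_kept: int, digits: int = 0) -> float:
    """100 * kept / input, rounded to the printed precision."""
    if n_input == 0:
        return 100.0
    return round(100.0 * n_kept / n_input, digits)


# --- rates ------------------------------------------------------------------

def snv_rate(table: VariantTable, genome_length: int) -> pd.Series:
    """Per-individual SNV rate: variant (non-hom-ref) positions per bp."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    counts = table.is_non_ref().sum(axis=0)
    return pd.Series(counts / genome_length, index=table.samples, name="snv_rate")


def heterozygosity_rate(n_het_sites: int, callable_length: int) -> float:
    """Percent of callable positions that are heterozygous in an individual."""
    if callable_length <= 0:
        raise ValueError("callable_length must be > 0")
    return 100.0 * n_het_sites / callable_length


def heterozygosity_rates(table: VariantTable, callable_length: int) -> pd.Series:
    het = table.is_het().sum(axis=0)
    return pd.Series([heterozygosity_rate(int(h), callable_length) for h in het],
                     index=table.samples, name="het_percent")


# --- windows ----------------------------------------------------------------

def _tile(scaffold_lengths: Mapping[str, int], window: int) -> pd.DataFrame:
    rows = []
    for scaf, length in scaffold_lengths.items():
        n_win = int(length) // window
        for w in range(n_win):
            rows.append((scaf, w * window, (w + 1) * window))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def window_density(scaffold: np.ndarray, pos: np.ndarray,
                   scaffold_lengths: Mapping[str, int],
                   window: int = 50_000) -> tuple[pd.DataFrame, dict]:
    """Per-window SNV counts over fixed non-overlapping windows.

    Scaffolds shorter than the window contribute no windows; qualifying
    scaffolds are tiled from position 0 and the trailing partial window is
    dropped.  Returns the window table and a coverage summary (fraction of
    total genome length inside windows, scaffolds excluded).
    """
    wins = _tile(scaffold_lengths, window)
    counts = np.zeros(len(wins), dtype=np.int64)
    index = {scaf: grp.index.to_numpy()
             for scaf, grp in wins.groupby("scaffold")}
    for scaf in np.unique(np.asarray(scaffold, dtype=str)):
        if scaf not in index:
            continue
        sel = np.asarray(scaffold, dtype=str) == scaf
        w = (np.asarray(pos)[sel] - 1) // window  # 1-based pos -> window idx
        n_win = len(index[scaf])
        w = w[(w >= 0) & (w < n_win)]
        np.add.at(counts, index[scaf][0] + w, 1)
    wins["snv_count"] = counts
    total = sum(scaffold_lengths.values())
    covered = len(wins) * window
    summary = {
        "n_windows": len(wins),
        "covered_bp": int(covered),
        "fraction_covered": covered / total if total else 0.0,
        "excluded_scaffolds": sum(1 for L in scaffold_lengths.values() if L < window),
    }
    return wins, summary


def classify_het_hom(scaffold: np.ndarray, pos: np.ndarray,
                     scaffold_lengths: Mapping[str, int],
                     window: int = 100_000, threshold: int = 40
                     ) -> tuple[pd.DataFrame, dict]:
    """Label 100-kbp windows heterozygous (count > threshold) or homozygous.

    The input stream should be one individual's heterozygous sites.  The
    summary reports percent homozygous over classified windows and, as an
    alternative denominator, over the whole genome length (short excluded
    scaffolds counted as unclassified).
    """
    wins, _ = window_density(scaffold, pos, scaffold_lengths, window)
    wins["label"] = np.where(wins["snv_count"] > threshold,
                             "heterozygous", "homozygous")
    n_hom = int((wins["label"] == "homozygous").sum())
    n_win = len(wins)
    total = sum(scaffold_lengths.values())
    summary = {
        "percent_homozygous": 100.0 * n_hom / n_win if n_win else float("nan"),
        "percent_homozygous_of_genome": (100.0 * n_hom * window / total
                                         if total else float("nan")),
        "n_windows": n_win,
        "n_homozygous": n_hom,
    }
    return wins, summary


# --- runs of homozygosity ---------------------------------------------------

@dataclass
class ROHSegment:
    scaffold: str
    start: int      # 1-based position of first SNV in the run
    end: int        # 1-based position of last SNV in the run
    n_snvs: int
    n_het: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def detect_roh(scaffold: np.ndarray, pos: np.ndarray, is_het: np.ndarray,
               window_snp: int = 20, density_kb_per_snp: float = 50.0,
               min_kb: float = 10.0, het_allowance: int = 1,
               hit_proportion: float = 0.05) -> tuple[list[ROHSegment], float]:
    """PLINK-style run-of-homozygosity scan for one individual.

    Windows of ``window_snp`` consecutive SNVs slide along each scaffold; a
    window is a hit when it contains at most ``het_allowance`` heterozygous
    calls.  A SNV is in ROH state when the proportion of windows overlapping
    it that hit exceeds ``hit_proportion``.  Maximal runs of ROH-state SNVs
    become segments, kept when their span is at least ``min_kb`` kbp and
    their SNV density is at least one per ``density_kb_per_snp`` kbp.
    Returns the segments and the median segment length (bp, nan if none).
    """
    pos = np.asarray(pos, dtype=np.int64)
    scaf = np.asarray(scaffold, dtype=str)
    het = np.asarray(is_het, dtype=bool)
    segments: list[ROHSegment] = []
    for name in pd.unique(scaf):
        sel = scaf == name
        p = pos[sel]
        h = het[sel]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"positions on {name} are not sorted")
        n = len(p)
        if n < window_snp:
            continue
        het_cum = np.concatenate([[0], np.cumsum(h)])
        n_win = n - window_snp + 1
        starts = np.arange(n_win)
        hits = (het_cum[starts + window_snp] - het_cum[starts]) <= het_allowance
        hit_cum = np.concatenate([[0], np.cumsum(hits)])
        j = np.arange(n)
        lo = np.maximum(0, j - window_snp + 1)
        hi = np.minimum(j, n_win - 1)
        n_overlap = hi - lo + 1
        n_hits = hit_cum[hi + 1] - hit_cum[lo]
        state = (n_hits / n_overlap) > hit_proportion
        # maximal runs of ROH-state SNVs
        edges = np.flatnonzero(np.diff(np.concatenate([[0], state.view(np.int8), [0]])))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            span = int(p[run_end - 1] - p[run_start] + 1)
            n_snvs = int(run_end - run_start)
            if span < min_kb * 1000:
                continue
            if n_snvs < span / (density_kb_per_snp * 1000):
                continue
            segments.append(ROHSegment(
                scaffold=name, start=int(p[run_start]), end=int(p[run_end - 1]),
                n_snvs=n_snvs, n_het=int(h[run_start:run_end].sum())))
    median = float(np.median([s.span for s in segments])) if segments else float("nan")
    return segments, median


# --- tandem repeats ---------------------------------------------------------

def classify_tandem_repeats(records: pd.DataFrame) -> pd.DataFrame:
    """Label tandem-repeat records as microsatellite / complex / large.

    Expected columns: monomer (bp), array_length (bp), copy_number,
    gc_percent, entropy, perfect (bool); optional cn_variation_bp (derived
    from the fractional copy number when absent).  Classes follow the
    published rules: microsatellites have monomer < 5 bp; complex repeats
    have monomer > 4 bp, GC in [20, 80] %, array > 100 bp, entropy > 1.76,
    copy-number variation > 4 bp and imperfect organisation; large repeats
    are subgrouped by array length at 1, 3 and 10 kbp.  Complex and large
    flags are not mutually exclusive.  Records missing a needed field are
    flagged unclassifiable.
    """
    df = records.copy()
    needed = ["monomer", "array_length", "copy_number", "gc_percent",
              "entropy", "perfect"]
    present = [c for c in needed if c in df.columns]
    df["unclassifiable"] = df[present].isna().any(axis=1) if present else True
    for col in needed:
        if col not in df.columns:
            df["unclassifiable"] = True
            df[col] = np.nan
    if "cn_variation_bp" not in df.columns:
        frac = df["copy_number"] - np.floor(df["copy_number"])
        df["cn_variation_bp"] = frac * df["monomer"]

    ok = ~df["unclassifiable"]
    df["is_microsatellite"] = ok & (df["monomer"] < 5)
    df["is_complex"] = (
        ok
        & (df["monomer"] > 4)
        & df["gc_percent"].between(20, 80)
        & (df["array_length"] > 100)
        & (df["entropy"] > 1.76)
        & (df["cn_variation_bp"] > 4)
        & (~df["perfect"].astype("boolean").fillna(True).astype(bool))
    )
    df["is_large"] = ok & (df["array_length"] >= 1000)
    df["large_subgroup"] = pd.cut(
        df["array_length"], bins=[1000, 3000, 10_000, np.inf],
        labels=["1kbp", "3kbp", "10kbp"], right=False, include_lowest=True,
    )
    df.loc[~df["is_large"].astype(bool), "large_subgroup"] = np.nan
    return df
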