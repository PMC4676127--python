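"""Read-depth duplication pipeline, each stage against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from bkit import sdcall
from bkit.intervals import coverage_mask, total_length
from bkit.syndata import build_planted_reference, simulate_depth_track


def brute_force_kmer_mask(sequences, k=36, overlap=5, min_hits=3):
    """Count every sampled k-mer by exhaustive string search."""
    step = k - overlap
    genome = {name: seq.upper() for name, seq in sequences.items()}
    out = {}
    for name, seq in genome.items():
        ivs = []
        for i in range(0, len(seq) - k + 1, step):
            kmer = seq[i:i + k]
            if "N" in kmer:
                continue
            count = sum(s.count(kmer) for s in genome.values())
            # count() misses overlapping occurrences; do a sliding check
            count = sum(1 for s in genome.values()
                        for j in range(len(s) - k + 1) if s[j:j + k] == kmer)
            if count >= min_hits:
                ivs.append((i, i + k))
        out[name] = ivs
    return out


class TestKmerMask:
    def test_distinct_sequence_unmasked(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 5000))
        masks = sdcall.kmer_overmask({"s": seq})
        # random 5-kb sequence: repeated 36-mers essentially impossible
        assert masks["s"] == []

    def test_planted_triplet_masked(self, rng):
        # plant three copies of one 36-mer at sampled offsets (multiples of
        # the 31-bp sampling step) so each copy is itself a sampled k-mer
        base = "".join(rng.choice(list("ACGT"), 3000))
        kmer = "".join(rng.choice(list("ACGT"), 36))
        starts = (465, 1550, 2480)  # 31*15, 31*50, 31*80
        seq = base[:465] + kmer
        seq += base[501:501 + (1550 - len(seq))] + kmer
        seq += base[1586:1586 + (2480 - len(seq))] + kmer
        seq += base[2516:3000]
        for s in starts:
            assert seq[s:s + 36] == kmer
        masks = sdcall.kmer_overmask({"s": seq})
        masked = coverage_mask(masks["s"], len(seq))
        for s in starts:
            assert masked[s:s + 36].all()

    def test_matches_exhaustive_search(self, rng):
        base = "".join(rng.choice(list("ACGT"), 4000))
        repeat = "".join(rng.choice(list("ACGT"), 150))
        seq = base[:1000] + repeat + base[1000:2000] + repeat + base[2000:3000] + repeat + base[3000:]
        got = sdcall.kmer_overmask({"s": seq})
        expect = brute_force_kmer_mask({"s": seq})
        from bkit.intervals import merge_intervals
        assert got["s"] == merge_intervals(expect["s"])


class TestPadding:
    def test_padding_is_36_each_side_clipped(self):
        padded = sdcall.add_padding({"s": [(10, 50), (0, 5)]}, {"s": 1000})
        assert padded["s"] == [(0, 86)]
        padded = sdcall.add_padding({"s": [(980, 1000)]}, {"s": 1000})
        assert padded["s"] == [(944, 1000)]


class TestWindows:
    def make_ref(self, length, mask=None, gaps=None):
        seq = "A" * length
        return sdcall.MaskedReference(sequences={"s": seq},
                                      mask={"s": mask or []},
                                      gaps={"s": gaps or []})

    def test_unmasked_sequence_gives_1kb_windows(self):
        wins, _ = sdcall.build_windows(self.make_ref(5000 + 10_000)[0]
                                       if False else self.make_ref(15_000))
        assert len(wins) == 15
        assert ((wins["end"] - wins["start"]) == 1000).all()

    def test_mask_stretches_genomic_span(self):
        # 1500 unmasked bp around a 2-kb mask -> one window spanning > 1 kbp
        ref = self.make_ref(13_500, mask=[(10_750, 12_750)])
        wins, unmasked = sdcall.build_windows(ref)
        spans = (wins["end"] - wins["start"]).to_numpy()
        assert (spans[:-1] > 0).all()
        assert spans.max() > 1000  # the window straddling the mask

    def test_scaffold_below_10kb_excluded(self):
        wins, _ = sdcall.build_windows(self.make_ref(9_999))
        assert len(wins) == 0

    def test_positions_match_brute_force_accumulation(self, rng):
        length = 30_000
        mask = []
        p = 0
        while p < length - 200:
            p += int(rng.integers(50, 2000))
            w = int(rng.integers(10, 300))
            mask.append((p, min(length, p + w)))
            p += w
        ref = self.make_ref(length, mask=mask)
        wins, unmasked = sdcall.build_windows(ref)
        is_masked = coverage_mask(ref.mask["s"], length)
        free = [i for i in range(length) if not is_masked[i]]
        for k, row in enumerate(wins.itertuples()):
            group = free[k * 1000:(k + 1) * 1000]
            assert row.start == group[0]
            assert row.end == group[-1] + 1


class TestDepthAssignment:
    def test_uniform_depth_sums(self):
        ref = sdcall.MaskedReference(sequences={"s": "A" * 20_000},
                                     mask={"s": []}, gaps={"s": []})
        wins, unmasked = sdcall.build_windows(ref)
        depth = {"s": np.full(20_000, 10)}
        wins = sdcall.assign_depth(wins, unmasked, depth)
        assert (wins["rd"] == 10_000).all()

    def test_hand_built_three_windows(self):
        ref = sdcall.MaskedReference(sequences={"s": "A" * 12_000},
                                     mask={"s": [(1000, 2000)]}, gaps={"s": []})
        wins, unmasked = sdcall.build_windows(ref)
        depth = np.zeros(12_000)
        depth[:1000] = 2          # first window
        depth[2000:3000] = 5      # second window (shifted by mask)
        wins = sdcall.assign_depth(wins, unmasked, {"s": depth})
        assert wins.iloc[0]["rd"] == 2 * 1000
        assert wins.iloc[1]["rd"] == 5 * 1000

    def test_missing_scaffold_raises(self):
        ref = sdcall.MaskedReference(sequences={"s": "A" * 12_000},
                                     mask={"s": []}, gaps={"s": []})
        wins, unmasked = sdcall.build_windows(ref)
        with pytest.raises(KeyError):
            sdcall.assign_depth(wins, unmasked, {"other": np.zeros(12_000)})

    def test_split_read_starts_offsets(self):
        starts = np.zeros(200)
        starts[100] = 3
        split = sdcall.split_read_starts(starts)
        assert split[110] == 3 and split[146] == 3 and split.sum() == 6


class TestControls:
    def test_poisson_windows_keep_most(self, rng):
        rd = rng.poisson(10_000, size=5000).astype(float)
        stats = sdcall.estimate_controls(rd)
        assert len(stats.control_idx) > 0.95 * len(rd)
        assert abs(stats.mean - 10_000) < 50

    def test_inflated_windows_excluded(self, rng):
        rd = rng.poisson(10_000, size=2000).astype(float)
        rd[:100] *= 10
        stats = sdcall.estimate_controls(rd)
        assert not np.isin(np.arange(100), stats.control_idx).any()

    def test_constant_rd_converges_immediately(self):
        stats = sdcall.estimate_controls(np.full(100, 500.0))
        assert stats.iterations == 1 and stats.sd == 0
        assert len(stats.control_idx) == 100

    def test_too_few_windows_raise(self):
        with pytest.raises(ValueError):
            sdcall.estimate_controls(np.ones(10))


class TestCopyNumber:
    def test_formula(self):
        wins = pd.DataFrame({"scaffold": ["s"] * 3, "start": [0, 1, 2],
                             "end": [1, 2, 3], "rd": [100.0, 300.0, 100.0]})
        ctrl = sdcall.ControlStats(mean=100.0, sd=5.0,
                                   control_idx=np.array([0, 2]), iterations=1)
        out = sdcall.compute_cn(wins, ctrl)
        assert out["cn"].tolist() == [2.0, 6.0, 2.0]
        assert sdcall.control_mean_cn(out, ctrl) == 2.0


def brute_force_blocks(cn, soft, hard, min_windows=5, soft_allowance=1,
                       starts=None, ends=None, min_span=10_000, ceiling=100.0):
    """Direct left-to-right evaluation of the calling rule: runs of windows
    above the hard cutoff, bridged across at most ``soft_allowance`` single
    windows that still clear the soft cutoff, then validated."""
    n = len(cn)
    runs = []
    i = 0
    while i < n:
        if cn[i] <= hard:
            i += 1
            continue
        j = i
        bridges = 0
        while True:
            while j + 1 < n and cn[j + 1] > hard:
                j += 1
            # try to bridge a single soft dip followed by more hard windows
            if (bridges < soft_allowance and j + 2 < n
                    and soft < cn[j + 1] <= hard and cn[j + 2] > hard):
                bridges += 1
                j += 2
            else:
                break
        runs.append((i, j))
        i = j + 1
    out = []
    for a, b in runs:
        members = list(range(a, b + 1))
        if len(members) < min_windows:
            continue
        if max(cn[k] for k in members) > ceiling:
            continue
        span = ends[b] - starts[a]
        if span < min_span:
            continue
        out.append((a, b))
    return out


class TestCallBlocks:
    def _windows(self, cn, spacing=2000):
        n = len(cn)
        return pd.DataFrame({
            "scaffold": ["s"] * n,
            "start": np.arange(n) * spacing,
            "end": np.arange(n) * spacing + 1000,
            "rd": np.asarray(cn) * 100.0,
            "cn": np.asarray(cn, dtype=float),
        })

    def _controls(self, wins):
        idx = np.arange(len(wins))
        cn = wins["cn"].to_numpy()
        return sdcall.ControlStats(mean=100.0, sd=1.0, control_idx=idx,
                                   iterations=1)

    def test_five_qualifying_windows_make_a_block(self):
        cn = np.full(30, 2.0)
        cn[10:15] = 10.0
        wins = self._windows(cn, spacing=3000)
        ctrl = sdcall.ControlStats(mean=100.0, sd=1.0,
                                   control_idx=np.flatnonzero(cn == 2.0),
                                   iterations=1)
        blocks = sdcall.call_blocks(wins, ctrl)
        assert len(blocks) == 1
        assert blocks[0].window_idx == list(range(10, 15))

    def test_four_windows_insufficient(self):
        cn = np.full(30, 2.0)
        cn[10:14] = 10.0
        wins = self._windows(cn, spacing=3000)
        ctrl = sdcall.ControlStats(mean=100.0, sd=1.0,
                                   control_idx=np.flatnonzero(cn == 2.0),
                                   iterations=1)
        assert sdcall.call_blocks(wins, ctrl) == []

    def test_cn_ceiling_excludes_region(self):
        cn = np.full(30, 2.0)
        cn[10:15] = 10.0
        cn[12] = 150.0
        wins = self._windows(cn, spacing=3000)
        ctrl = sdcall.ControlStats(mean=100.0, sd=1.0,
                                   control_idx=np.flatnonzero(cn == 2.0),
                                   iterations=1)
        assert sdcall.call_blocks(wins, ctrl) == []

    def test_randomized_tracks_match_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            cn = rng.choice([2.0, 2.2, 4.5, 5.5, 8.0], size=n,
                            p=[0.5, 0.15, 0.15, 0.1, 0.1])
            ctrl_cn = np.full(40, 2.0) + rng.normal(0, 0.1, 40)
            wins = self._windows(np.concatenate([ctrl_cn, cn]), spacing=2500)
            ctrl = sdcall.ControlStats(mean=100.0, sd=1.0,
                                       control_idx=np.arange(40), iterations=1)
            blocks = sdcall.call_blocks(wins, ctrl)
            mean_cn = ctrl_cn.mean()
            sd_cn = ctrl_cn.std()
            starts = wins["start"].to_numpy()
            ends = wins["end"].to_numpy()
            expect = brute_force_blocks(
                wins["cn"].to_numpy(), soft=mean_cn + 2 * sd_cn,
                hard=mean_cn + 3 * sd_cn, starts=starts, ends=ends)
            got = [(b.window_idx[0], b.window_idx[-1]) for b in blocks]
            assert got == expect

    def test_gap_subtraction_flags(self):
        cn = np.full(30, 2.0)
        cn[10:16] = 10.0
        wins = self._windows(cn, spacing=3000)
        ctrl = sdcall.ControlStats(mean=100.0, sd=1.0,
                                   control_idx=np.flatnonzero(cn == 2.0),
                                   iterations=1)
        gap = (31_000, 32_000)
        blocks = sdcall.call_blocks(wins, ctrl, gaps={"s": [gap]})
        assert blocks[0].gap_trimmed
        assert total_length(blocks[0].intervals) == blocks[0].span - 1000


class TestSharedBlocks:
    def test_identical_sets(self):
        ivs = {"s": [(0, 100), (200, 300)]}
        shared, summary = sdcall.shared_blocks({"a": ivs, "b": ivs})
        assert shared == {"s": [(0, 100), (200, 300)]}
        assert summary["shared_bp"] == summary["union_bp"] == 200

    def test_disjoint_sets_empty(self):
        shared, summary = sdcall.shared_blocks(
            {"a": {"s": [(0, 100)]}, "b": {"s": [(100, 200)]}})
        assert shared == {} and summary["shared_bp"] == 0

    def test_random_sets_match_per_base(self, rng):
        samples = {}
        for name in "abc":
            ivs = []
            for _ in range(5):
                s = int(rng.integers(0, 900))
                ivs.append((s, s + int(rng.integers(10, 120))))
            samples[name] = {"s": ivs}
        shared, _ = sdcall.shared_blocks(samples)
        base_sets = [set(p for s, e in m["s"] for p in range(s, e))
                     for m in samples.values()]
        expect = set.intersection(*base_sets)
        got = set(p for s, e in shared.get("s", []) for p in range(s, e))
        assert got == expect

    def test_fewer_than_two_samples_raise(self):
        with pytest.raises(ValueError):
            sdcall.shared_blocks({"a": {"s": [(0, 1)]}})


class TestGeneOverlap:
    genes = pd.DataFrame({
        "gene_id": ["inside", "at59", "at60"],
        "scaffold": ["s"] * 3,
        "start": [10, 1000, 2000],
        "end": [110, 1100, 2100],
    })

    def test_overlap_threshold(self):
        shared = {"s": [(0, 200), (1000, 1059), (2000, 2060)]}
        hits = sdcall.gene_overlap(shared, self.genes)
        assert hits == ["inside", "at60"]

    def test_random_matches_arithmetic(self, rng):
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(30)],
            "scaffold": ["s"] * 30,
            "start": rng.integers(0, 900, 30),
        })
        genes["end"] = genes["start"] + rng.integers(10, 120, 30)
        shared = {"s": [(100, 300), (500, 700)]}
        hits = sdcall.gene_overlap(shared, genes)
        shared_set = set(range(100, 300)) | set(range(500, 700))
        expect = [r.gene_id for r in genes.itertuples()
                  if len(set(range(r.start, r.end)) & shared_set)
                  / (r.end - r.start) >= 0.6]
        assert hits == expect


class TestEndToEnd:
    def test_cn_estimates_unbiased_in_planted_segments(self):
        dups = [((500_000, 530_000), 4), ((1_200_000, 1_220_000), 6)]
        feats = build_planted_reference(length=2_000_000, seed=21,
                                        duplications=dups)
        depth = simulate_depth_track(feats, mean_depth=10.0, seed=22)
        ref = sdcall.prepare_reference(feats.sequences, feats.repeat_mask,
                                       feats.gaps, run_kmer_mask=False)
        wins, unmasked = sdcall.build_windows(ref)
        wins = sdcall.assign_depth(wins, unmasked, depth)
        ctrl = sdcall.estimate_controls(wins["rd"].to_numpy())
        wins = sdcall.compute_cn(wins, ctrl)
        for (s, e), cn_true in dups:
            inside = wins[(wins["start"] >= s) & (wins["end"] <= e)]
            assert abs(inside["cn"].mean() - cn_true) <= 0.1 * cn_true

    def test_calling_invariant_to_scaffold_order_and_chunking(self):
        feats = build_planted_reference(length=500_000, seed=31,
                                        duplications=[((200_000, 230_000), 6)])
        depth = simulate_depth_track(feats, mean_depth=10.0, seed=32)
        ref = sdcall.prepare_reference(feats.sequences, feats.repeat_mask,
                                       feats.gaps, run_kmer_mask=False)
        wins, unmasked = sdcall.build_windows(ref)
        wins = sdcall.assign_depth(wins, unmasked, depth)
        ctrl = sdcall.estimate_controls(wins["rd"].to_numpy())
        wins = sdcall.compute_cn(wins, ctrl)
        blocks = sdcall.call_blocks(wins, ctrl, sample="x")
        # a second scaffold added before the first must not change the calls
        seq2 = feats.sequences["scaf1"][:100_000]
        ref2 = sdcall.MaskedReference(
            sequences={"alpha": seq2, "scaf1": feats.sequences["scaf1"]},
            mask={"alpha": [], "scaf1": ref.mask["scaf1"]},
            gaps={"alpha": [], "scaf1": []})
        wins2, unmasked2 = sdcall.build_windows(ref2)
        depth2 = {"alpha": depth["scaf1"][:100_000].copy(),
                  "scaf1": depth["scaf1"]}
        wins2 = sdcall.assign_depth(wins2, unmasked2, depth2)
        sel = wins2["scaffold"] == "scaf1"
        got = wins2[sel]["rd"].to_numpy()
        assert np.array_equal(got, wins["rd"].to_numpy())
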