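"""Readers/writers for the formats the pipeline consumes and emits.

Variant tables travel as :class:`VariantTable` (numpy-backed), written as
plain-text VCF 4.2 with per-sample ``GT`` and ``DP`` and read back through
cyvcf2.  Masks/gaps are BED (0-based half-open), depth tracks are TSV
(scaffold, 1-based position, depth), references are FASTA via Biopython.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1


@dataclass
class VariantTable:
    """Multi-sample diploid variant sites.

    gt has shape (n_sites, n_samples, 2) with allele codes 0 (ref),
    1 (alt) or -1 (missing); depth has shape (n_sites, n_samples).
    """

    samples: list[str]
    scaffold: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    depth: np.ndarray
    ancestral: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.gt = np.asarray(self.gt, dtype=np.int8)
        self.depth = np.asarray(self.depth, dtype=np.int32)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_het(self) -> np.ndarray:
        """(sites, samples) True where the genotype is heterozygous."""
        called = np.all(self.gt >= 0, axis=2)
        return called & (self.gt[:, :, 0] != self.gt[:, :, 1])

    def is_non_ref(self) -> np.ndarray:
        """(sites, samples) True where at least one called allele is non-ref."""
        called = np.all(self.gt >= 0, axis=2)
        return called & np.any(self.gt > 0, axis=2)

    def derived_counts(self, sample_idx: Iterable[int]) -> np.ndarray:
        """Per-site derived-allele count over the given samples.

        Requires ancestral alleles; sites where the ancestral allele matches
        neither REF nor ALT yield -1.
        """
        if self.ancestral is None:
            raise ValueError("variant table carries no ancestral alleles")
        idx = list(sample_idx)
        sub = self.gt[:, idx, :]
        alt_count = (sub == 1).sum(axis=(1, 2))
        ref_count = (sub == 0).sum(axis=(1, 2))
        anc_is_ref = self.ancestral == self.ref
        anc_is_alt = self.ancestral == self.alt
        out = np.full(self.n_sites, -1, dtype=np.int64)
        out[anc_is_ref] = alt_count[anc_is_ref]
        out[anc_is_alt] = ref_count[anc_is_alt]
        return out

    def subset(self, keep: np.ndarray) -> "VariantTable":
        keep = np.asarray(keep)
        return VariantTable(
            samples=list(self.samples),
            scaffold=self.scaffold[keep],
            pos=self.pos[keep],
            ref=self.ref[keep],
            alt=self.alt[keep],
            gt=self.gt[keep],
            depth=self.depth[keep],
            ancestral=None if self.ancestral is None else self.ancestral[keep],
        )

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.samples == other.samples
            and np.array_equal(self.scaffold, other.scaffold)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.gt, other.gt)
            and np.array_equal(self.depth, other.depth)
        )


def write_vcf(table: VariantTable, path: str | os.PathLike,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a VariantTable as uncompressed VCF 4.2 (GT and DP per sample)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={int(length)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_sites):
            cells = []
            for s in range(table.n_samples):
                a, b = table.gt[i, s]
                gt = "./." if a < 0 or b < 0 else f"{a}/{b}"
                cells.append(f"{gt}:{int(table.depth[i, s])}")
            fh.write(
                f"{table.scaffold[i]}\t{int(table.pos[i])}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t.\tPASS\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str | os.PathLike) -> VariantTable:
    """Read a VCF (first ALT allele only) into a VariantTable via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    scaffold, pos, ref, alt, gts, dps = [], [], [], [], [], []
    for v in vcf:
        scaffold.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        g = np.array(v.genotypes, dtype=np.int64)[:, :2]
        g[g < 0] = MISSING
        gts.append(g)
        d = v.format("DP")
        dps.append(np.zeros(len(samples), dtype=np.int32) if d is None
                   else d.reshape(-1).astype(np.int32))
    vcf.close()
    n = len(pos)
    return VariantTable(
        samples=samples,
        scaffold=np.array(scaffold, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        gt=(np.stack(gts) if n else np.zeros((0, len(samples), 2))).astype(np.int8),
        depth=(np.stack(dps) if n else np.zeros((0, len(samples)))).astype(np.int32),
    )


def write_ancestral_tsv(table: VariantTable, path: str | os.PathLike) -> None:
    if table.ancestral is None:
        raise ValueError("no ancestral alleles to write")
    pd.DataFrame({
        "scaffold": table.scaffold,
        "pos": table.pos,
        "ancestral": table.ancestral,
    }).to_csv(path, sep="\t", index=False)


def read_ancestral_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"scaffold": str, "pos": np.int64,
                                              "ancestral": str})


def attach_ancestral(table: VariantTable, anc: pd.DataFrame) -> VariantTable:
    """Join an ancestral-allele sidecar onto a variant table (in place)."""
    key = {(str(s), int(p)): a for s, p, a in
           zip(anc["scaffold"], anc["pos"], anc["ancestral"])}
    table.ancestral = np.array(
        [key.get((str(s), int(p)), "N") for s, p in zip(table.scaffold, table.pos)],
        dtype=object,
    )
    return table


# --- BED -------------------------------------------------------------------

def write_bed(intervals_by_scaffold: Mapping[str, Iterable[tuple[int, int]]],
              path: str | os.PathLike, label: str | None = None) -> None:
    with open(path, "w") as fh:
        for scaf, ivs in intervals_by_scaffold.items():
            for s, e in ivs:
                row = f"{scaf}\t{int(s)}\t{int(e)}"
                if label is not None:
                    row += f"\t{label}"
                fh.write(row + "\n")


def read_bed(path: str | os.PathLike) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return out


# --- FASTA -----------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# --- depth track -----------------------------------------------------------

def write_depth_tsv(depth_by_scaffold: Mapping[str, np.ndarray],
                    path: str | os.PathLike) -> None:
    """TSV depth track: scaffold, 1-based position, read-start count."""
    with open(path, "w") as fh:
        fh.write("scaffold\tpos\tdepth\n")
        for scaf, arr in depth_by_scaffold.items():
            for i, d in enumerate(np.asarray(arr)):
                fh.write(f"{scaf}\t{i + 1}\t{int(d)}\n")


def read_depth_tsv(path: str | os.PathLike,
                   scaffold_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    out = {name: np.zeros(int(length), dtype=np.int64)
           for name, length in scaffold_lengths.items()}
    for scaf, grp in df.groupby("scaffold"):
        if str(scaf) in out:
            out[str(scaf)][grp["pos"].to_numpy() - 1] = grp["depth"].to_numpy()
    return out
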