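"""Readers and writers for the pipeline's on-disk formats.

Phased genotypes travel as uncompressed VCF (GT "0|1" style, 1-based
positions); the transmitted / non-transmitted datasets reuse the same layout
with "." for missing alleles.  Tables (pedigree, phenotypes, weights, marker
map, transmission truth) are tab-separated UTF-8 with a header row.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simfam import GeneticMap, TransmissionTruth

__all__ = [
    "write_phased_vcf",
    "read_phased_vcf",
    "write_map_tsv",
    "read_map_tsv",
    "write_table",
    "read_table",
    "write_truth_tsv",
    "read_truth_tsv",
]

REF, ALT = "A", "B"


def write_phased_vcf(path, gmap: GeneticMap, haps: dict, sample_order=None) -> None:
    """Write phased haplotypes as VCF; allele code -1 becomes '.'."""
    samples = list(sample_order) if sample_order is not None else list(haps)
    t = gmap.table
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gmap.chroms:
            sl = gmap.chrom_slice(chrom)
            max_pos = int(t["pos"].iloc[sl.stop - 1]) + 1
            fh.write(f"##contig=<ID={chrom},length={max_pos}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        chroms = t["chrom"].to_numpy()
        poss = t["pos"].to_numpy()
        ids = t["marker_id"].to_numpy()
        mats = [haps[s] for s in samples]
        for j in range(len(t)):
            gts = "\t".join(
                f"{_a(m[0, j])}|{_a(m[1, j])}" for m in mats
            )
            fh.write(f"{chroms[j]}\t{poss[j]}\t{ids[j]}\t{REF}\t{ALT}\t.\t.\t.\tGT\t{gts}\n")


def _a(code) -> str:
    return "." if code < 0 else str(int(code))


def read_phased_vcf(path):
    """Read a phased VCF back into (marker table, dict id -> (2, M) int8).

    Uses cyvcf2; missing alleles come back as -1.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    allele_rows = []
    for var in vcf:
        rows.append((var.ID, var.CHROM, var.POS))
        g = np.asarray(var.genotypes, dtype=np.int16)[:, :2]
        allele_rows.append(g)
    vcf.close()
    table = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"])
    arr = np.stack(allele_rows)  # (M, S, 2)
    haps = {
        s: np.ascontiguousarray(arr[:, i, :].T).astype(np.int8)
        for i, s in enumerate(samples)
    }
    return table, haps


def write_map_tsv(path, gmap: GeneticMap) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t"))


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_tsv(path, truth: TransmissionTruth, gmap: GeneticMap) -> None:
    chroms = gmap.table["chrom"].to_numpy()
    local = gmap.table["local_index"].to_numpy()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("offspring_id\tparent_role\tchrom\tmarker_index\tsource_hap\n")
        for oid, per_role in truth.source.items():
            for role, src in per_role.items():
                for j in range(len(src)):
                    fh.write(f"{oid}\t{role}\t{chroms[j]}\t{local[j]}\t{src[j]}\n")


def read_truth_tsv(path, gmap: GeneticMap) -> TransmissionTruth:
    df = pd.read_csv(path, sep="\t")
    truth = TransmissionTruth()
    order = {
        (c, i): j
        for j, (c, i) in enumerate(
            zip(gmap.table["chrom"], gmap.table["local_index"])
        )
    }
    for (oid, role), sub in df.groupby(["offspring_id", "parent_role"], sort=False):
        src = np.zeros(gmap.n_markers, dtype=np.int8)
        idx = [order[(c, i)] for c, i in zip(sub["chrom"], sub["marker_index"])]
        src[idx] = sub["source_hap"].to_numpy(np.int8)
        truth.source.setdefault(oid, {})[role] = src
    return truth
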