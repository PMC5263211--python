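"""Plain-text readers and writers (TSV throughout, optional minimal VCF)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GenomicRelationship, MarkerMatrix
from .simulate import TRIAL_COLUMNS, TruthSet

__all__ = [
    "write_marker_tsv", "read_marker_tsv",
    "write_trial_tsv", "read_trial_tsv",
    "write_blue_tsv", "read_blue_tsv",
    "write_kinship_tsv", "read_kinship_tsv",
    "write_truth_tsv", "read_truth_tsv",
    "write_vcf", "read_vcf",
]

_FLOAT_FMT = "%.10g"


def write_marker_tsv(markers: MarkerMatrix, path) -> None:
    """Lines x markers table: header of marker ids, first column line_id,
    entries -1/0/1 (or fractional after imputation), NA for missing."""
    df = markers.to_frame()
    df.index.name = "line_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format=_FLOAT_FMT)


def read_marker_tsv(path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return MarkerMatrix.from_frame(df)


def write_trial_tsv(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False,
                                 float_format=_FLOAT_FMT)


def read_trial_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_check"] = df["is_check"].astype(bool)
    return df[TRIAL_COLUMNS]


def write_blue_tsv(blues: pd.DataFrame, path) -> None:
    blues.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_blue_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_kinship_tsv(K: GenomicRelationship, path) -> None:
    df = pd.DataFrame(K.K, index=K.line_ids, columns=K.line_ids)
    df.index.name = "line_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_kinship_tsv(path) -> GenomicRelationship:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenomicRelationship(df.index.to_numpy(object), df.to_numpy(float),
                               np.array([]))


def write_truth_tsv(truth: TruthSet, path) -> None:
    df = truth.true_bv.copy()
    df.index.name = "line_id"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_vcf(markers: MarkerMatrix, path) -> None:
    """Minimal diploid VCF: -1 -> 0/0, 0 -> 0/1, +1 -> 1/1, NA -> ./.

    Fractional (imputed) codes are rounded to the nearest genotype class.
    Markers are placed on a single synthetic contig at 1-based positions.
    """
    gt_map = {-1: "0/0", 0: "0/1", 1: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=chr1>\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(str(l) for l in markers.line_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, mid in enumerate(markers.marker_ids):
            col = markers.codes[:, j]
            gts = [
                "./." if np.isnan(v) else gt_map[int(np.rint(v))] for v in col
            ]
            fh.write(
                f"chr1\t{j + 1}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> MarkerMatrix:
    """Read biallelic genotypes from a VCF (0/0 -> -1, het -> 0, 1/1 -> +1)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids = []
    cols = []
    for var in vcf:
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        # gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        g = var.gt_types
        col = np.where(g == 0, -1.0, np.where(g == 1, 0.0,
                       np.where(g == 3, 1.0, np.nan)))
        cols.append(col)
    codes = np.column_stack(cols) if cols else np.empty((len(line_ids), 0))
    return MarkerMatrix(line_ids, marker_ids, codes)
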