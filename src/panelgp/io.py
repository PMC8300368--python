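"""Readers and writers for the plain-text formats the pipeline touches.

PLINK-style .ped/.map text for genotypes, BED4 for gene intervals, TSV for
phenotype tables and marker panels.  Parsing and validation only — the
recoding of alleles to minor-allele dosages is the single computation here
because the code semantics (2 = minor homozygote) are part of the format
contract.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (FormatError, GeneAnnotation, GenotypeMatrix,
                        MarkerMap, TraitTable)

MISSING_ALLELE = "0"

__all__ = [
    "read_genotypes", "write_genotypes", "read_gene_intervals",
    "read_trait_table", "write_trait_table", "write_panel", "read_panel",
]


def _read_map(map_path) -> pd.DataFrame:
    df = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chromosome", "marker_id", "cm", "position_bp"],
                     dtype={"chromosome": np.int64, "marker_id": str,
                            "position_bp": np.int64})
    return df


def read_genotypes(ped_path, map_path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read PLINK text .ped/.map into dosage codes and a marker map.

    Alleles at each site are recoded so that 2 counts copies of the *minor*
    allele given the observed frequencies in this file ("0 0" = missing).
    When the two alleles are exactly equifrequent the lexicographically
    smaller allele is counted, for determinism.
    """
    mp = _read_map(map_path)
    m = len(mp)
    ids, rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * m} fields "
                    f"({m} markers), got {len(fields)}")
            ids.append(fields[1])
            rows.append(fields[6:])
    alleles = np.asarray(rows, dtype=object).reshape(len(rows), m, 2)

    values = np.zeros((len(rows), m), dtype=np.int8)
    missing = np.zeros((len(rows), m), dtype=bool)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    for j in range(m):
        site = alleles[:, j, :]
        miss = (site == MISSING_ALLELE).any(axis=1)
        obs = np.unique(site[~miss])
        if len(obs) > 2:
            raise FormatError(
                f"marker {mp.marker_id.iloc[j]!r} has {len(obs)} alleles: "
                f"{sorted(obs.tolist())}")
        if len(obs) == 0:
            obs = np.array(["N", "N"], dtype=object)
        if len(obs) == 1:
            obs = np.array([obs[0], obs[0]], dtype=object)
        # counted (minor) allele by observed frequency; ties -> smaller string
        counts = [(site[~miss] == a).sum() for a in obs]
        order = sorted(range(2), key=lambda k: (counts[k], str(obs[k])))
        minor, major = obs[order[0]], obs[order[1]]
        values[:, j] = (site == minor).sum(axis=1)
        values[miss, j] = 0
        missing[:, j] = miss
        allele_a[j], allele_b[j] = major, minor

    marker_map = MarkerMap(mp.marker_id.to_numpy(dtype=object),
                           mp.chromosome.to_numpy(), mp.position_bp.to_numpy(),
                           allele_a, allele_b)
    return GenotypeMatrix(values, missing, np.asarray(ids, dtype=object)), marker_map


def write_genotypes(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                    ped_path, map_path) -> None:
    """Write .ped/.map text; inverse of :func:`read_genotypes` on clean data."""
    with open(map_path, "w") as fh:
        for c, mid, pos in zip(marker_map.chromosome, marker_map.marker_id,
                               marker_map.position_bp):
            fh.write(f"{c}\t{mid}\t0\t{pos}\n")
    major = marker_map.allele_a
    minor = marker_map.allele_b
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(genotypes.individual_ids):
            parts = [str(ind), str(ind), "0", "0", "0", "-9"]
            for j in range(genotypes.n_markers):
                if genotypes.missing[i, j]:
                    parts += [MISSING_ALLELE, MISSING_ALLELE]
                else:
                    code = genotypes.values[i, j]
                    parts += {0: [major[j]] * 2,
                              1: [major[j], minor[j]],
                              2: [minor[j]] * 2}[int(code)]
            fh.write(" ".join(map(str, parts)) + "\n")


def read_gene_intervals(bed_path) -> GeneAnnotation:
    """Parse BED4+ rows (0-based half-open) into a GeneAnnotation."""
    gene_id, chrom, start, end = [], [], [], []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{bed_path} line {lineno}: BED4 needs >=4 columns")
            c = fields[0].removeprefix("chr")
            s, e = int(fields[1]), int(fields[2])
            if s > e:
                raise FormatError(f"{bed_path} line {lineno}: start {s} > end {e}")
            chrom.append(int(c))
            start.append(s)
            end.append(e)
            gene_id.append(fields[3])
    return GeneAnnotation(np.asarray(gene_id, dtype=object), np.asarray(chrom, dtype=np.int64),
                          np.asarray(start, dtype=np.int64), np.asarray(end, dtype=np.int64))


def write_gene_intervals(annotation: GeneAnnotation, bed_path) -> None:
    with open(bed_path, "w") as fh:
        for g, c, s, e in zip(annotation.gene_id, annotation.chromosome,
                              annotation.start_bp, annotation.end_bp):
            fh.write(f"{c}\t{s}\t{e}\t{g}\n")


def read_trait_table(path, traits=None) -> TraitTable:
    df = pd.read_csv(path, sep="\t")
    kwargs = {} if traits is None else {"traits": tuple(traits)}
    return TraitTable(df, **kwargs)


def write_trait_table(table: TraitTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="individual_id")


PROVENANCE_FLAGS = ("gwas", "bayesb", "window", "gene")


def write_panel(panel, path) -> None:
    """Serialize a Panel as TSV: id, chrom, pos, MAF, one 0/1 provenance column per strategy."""
    panel.to_dataframe().to_csv(path, sep="\t", index=False)


def read_panel(path, marker_map: MarkerMap):
    """Read a panel TSV back; every id must exist in ``marker_map``."""
    from .preselect import Panel  # local import to avoid a cycle
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    known = set(marker_map.marker_id.astype(str))
    unknown = [m for m in df.marker_id if m not in known]
    if unknown:
        raise FormatError(f"panel contains unknown marker ids: {unknown[:5]}")
    prov = {flag: set(df.marker_id[df[flag] == 1]) for flag in PROVENANCE_FLAGS
            if flag in df.columns}
    return Panel.from_provenance(prov, marker_map,
                                 mafs=dict(zip(df.marker_id, df.get("maf", np.nan))))
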