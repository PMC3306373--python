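"""Readers and writers for the pipeline's on-disk formats.

Formats (all plain text):

* marker panel — TSV with columns ``marker_id, chromosome, genetic_pos,
  physical_pos, pE, pA`` (genetic positions in Morgans, sorted within
  chromosome; physical positions 1-based);
* genotypes — TSV, one row per individual (first column ``id``), one
  column per marker id, values 0/1/2 or ``NA``;
* cohort table — CSV preceded by ``#key=value`` header-dictionary lines;
* VCF 4.2 subset — biallelic SNPs with GT only, allele frequencies and the
  genetic position carried in INFO (AF_EUR, AF_AFR, GD), missing ``./.``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .errors import SchemaError

PANEL_COLUMNS = ["marker_id", "chromosome", "genetic_pos", "physical_pos", "pE", "pA"]


def write_marker_panel(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_marker_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in PANEL_COLUMNS:
        if col not in df.columns:
            raise SchemaError("marker panel is missing a required column", column=col)
    if df["marker_id"].duplicated().any():
        dup = df["marker_id"][df["marker_id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate marker id {dup!r}", column="marker_id")
    for col in ("pE", "pA"):
        bad = ~df[col].between(0, 1)
        if bad.any():
            raise SchemaError(
                "allele frequency outside [0, 1]", column=col, line=int(bad.idxmax()) + 2
            )
    for _chrom, sub in df.groupby("chromosome"):
        pos = sub["genetic_pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            i = int(sub.index[np.argmax(np.diff(pos) < 0) + 1])
            raise SchemaError("genetic positions not sorted", column="genetic_pos", line=i + 2)
    return df


def write_genotypes(genotypes: np.ndarray, marker_ids, individual_ids, path) -> None:
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    df = pd.DataFrame(G, columns=list(marker_ids))
    df.insert(0, "id", list(individual_ids))
    with np.errstate(invalid="ignore"):
        for c in df.columns[1:]:
            df[c] = df[c].map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Returns (matrix with NaN missing, individual ids, marker ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    if df.columns[0] != "id":
        raise SchemaError("genotype TSV must start with an 'id' column", column=df.columns[0])
    ids = df["id"].tolist()
    markers = list(df.columns[1:])
    raw = df[markers].to_numpy(dtype=object)
    valid = {"NA": np.nan, "0": 0.0, "1": 1.0, "2": 2.0}
    bad = ~np.isin(raw, list(valid))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise SchemaError(
            f"invalid genotype value {raw[i, j]!r}", column=markers[j], line=int(i) + 2
        )
    out = np.vectorize(valid.get, otypes=[float])(raw)
    return out, ids, markers


COHORT_HEADER_KEYS = ("format", "version")


def write_cohort(cohort: pd.DataFrame, path, header: dict | None = None) -> None:
    header = {"format": "admixscan-cohort", "version": "1", **(header or {})}
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"#{k}={v}\n")
        cohort.to_csv(fh, index=False)


def read_cohort(path) -> tuple[pd.DataFrame, dict]:
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                header[k] = v
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        df = pd.read_csv(fh)
    if "id" not in df.columns:
        raise SchemaError("cohort CSV is missing the 'id' column", column="id")
    return df, header


# ---------------------------------------------------------------------------
# VCF (4.2 subset, GT only)

_GT_BY_DOSE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(panel: pd.DataFrame, genotypes: np.ndarray, individual_ids, path) -> None:
    """Markers as biallelic SNPs; the counted allele is ALT, dose = ALT copies."""
    G = np.atleast_2d(np.asarray(genotypes, dtype=float))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF_EUR,Number=1,Type=Float,Description="European allele frequency">\n')
        fh.write('##INFO=<ID=AF_AFR,Number=1,Type=Float,Description="African allele frequency">\n')
        fh.write('##INFO=<ID=GD,Number=1,Type=Float,Description="Genetic position in Morgans">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(panel["chromosome"].unique()):
            maxpos = int(panel.loc[panel["chromosome"] == chrom, "physical_pos"].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1}>\n")
        cols = "\t".join(str(s) for s in individual_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j, row in enumerate(panel.itertuples()):
            info = f"AF_EUR={row.pE:.6f};AF_AFR={row.pA:.6f};GD={row.genetic_pos:.8f}"
            gts = "\t".join(
                "./." if np.isnan(G[i, j]) else _GT_BY_DOSE[int(G[i, j])]
                for i in range(G.shape[0])
            )
            fh.write(
                f"{row.chromosome}\t{int(row.physical_pos)}\t{row.marker_id}\tA\tG\t.\t.\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a GT-only VCF back into (panel, genotype matrix, individual ids)."""
    vf = pysam.VariantFile(str(path))
    ids = list(vf.header.samples)
    panel_rows, geno_rows = [], []
    for rec in vf:
        info = rec.info
        panel_rows.append(
            {
                "marker_id": rec.id,
                "chromosome": int(rec.chrom),
                "genetic_pos": float(info.get("GD", np.nan)),
                "physical_pos": int(rec.pos),
                "pE": float(info.get("AF_EUR", np.nan)),
                "pA": float(info.get("AF_AFR", np.nan)),
            }
        )
        row = np.empty(len(ids))
        for i, s in enumerate(ids):
            gt = rec.samples[s]["GT"]
            row[i] = np.nan if gt is None or None in gt else float(sum(gt))
        geno_rows.append(row)
    vf.close()
    panel = pd.DataFrame(panel_rows)
    G = np.column_stack(geno_rows) if geno_rows else np.empty((len(ids), 0))
    return panel, G, ids


def write_ancestry_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_ancestry_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("id", "african_ancestry"):
        if col not in df.columns:
            raise SchemaError("ancestry table is missing a required column", column=col)
    return df


def write_posterior_matrix(local_european_mean: np.ndarray, individual_ids, marker_ids, path) -> None:
    df = pd.DataFrame(np.atleast_2d(local_european_mean), columns=list(marker_ids))
    df.insert(0, "id", list(individual_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
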