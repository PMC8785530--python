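"""Reading and writing genotype/phenotype files.

Supported genotype formats:

* VCF 4.2 with per-sample ``GT`` and ``DS`` fields and a per-variant
  ``DR2`` INFO field (imputation dosage R^2).  Reading goes through
  cyvcf2; writing emits the same dialect as plain text.
* a rectangular dosage TSV: header ``animal_id`` followed by variant ids
  ``chrom:pos:ref:alt``, one animal per row, ``NA`` for missing; the
  variant map (with DR2) travels in a companion TSV.

Multi-allelic records are rejected.  When both GT and DS are present the
preference is configurable; under DS preference the stored hard call is
the nearest integer and the fractional dose is retained for output only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, PhenotypeTable, variant_ids


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write a genotype matrix as an uncompressed VCF 4.2 file."""
    frac = G.fractional
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DR2,Number=1,Type=Float,Description="Imputation dosage R-squared">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n')
        for c in pd.unique(G.variants["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, G.animals)) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        ids = G.ids
        for j in range(G.n_variants):
            v = G.variants.iloc[j]
            fields = [
                str(v["chrom"]), str(v["pos"]), ids[j], str(v["ref"]), str(v["alt"]),
                ".", "PASS", f"DR2={v['dr2']:.4g}", "GT:DS",
            ]
            col = G.dosage[:, j]
            ds = frac[:, j] if frac is not None else col
            cells = [
                f"{gt_codes[int(c)]}:{'.' if c == MISSING else format(float(d), '.3g')}"
                for c, d in zip(col, ds)
            ]
            fh.write("\t".join(fields) + "\t" + "\t".join(cells) + "\n")


def read_vcf(path: str, prefer_ds: bool = True) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix via cyvcf2.

    Multi-allelic records raise with the record coordinates.  With
    ``prefer_ds`` the hard call is the DS rounded to the nearest integer
    (fractional doses kept separately); otherwise GT is used.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    animals = np.array(vcf.samples)
    rows = []
    dosage_cols = []
    frac_cols = []
    any_ds = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}); split or remove it first"
            )
        dr2 = rec.INFO.get("DR2")
        chrom = rec.CHROM
        try:
            chrom = int(chrom)
        except (TypeError, ValueError):
            pass
        rows.append({
            "chrom": chrom, "pos": rec.POS, "ref": rec.REF, "alt": rec.ALT[0],
            "dr2": float(dr2) if dr2 is not None else 1.0,
        })
        ds = None
        if prefer_ds:
            try:
                ds = rec.format("DS")
            except KeyError:
                ds = None
        if ds is not None:
            ds = np.asarray(ds, dtype=float).reshape(-1)
            hard = np.where(np.isnan(ds), MISSING, np.clip(np.rint(ds), 0, 2)).astype(np.int8)
            dosage_cols.append(hard)
            frac_cols.append(ds)
            any_ds = True
        else:
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(rec.gt_types)
            hard = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING).astype(np.int8)
            dosage_cols.append(hard)
            frac_cols.append(hard.astype(float))
    variants = pd.DataFrame(rows)
    dosage = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(animals), 0), np.int8)
    frac = np.column_stack(frac_cols) if any_ds else None
    return GenotypeMatrix(animals=animals, variants=variants, dosage=dosage, fractional=frac)


def write_dosage_tsv(G: GenotypeMatrix, matrix_path: str, map_path: str | None = None,
                     header_comment: str | None = None) -> None:
    """Write the dosage matrix and (optionally) the variant map as TSVs."""
    df = pd.DataFrame(
        np.where(G.dosage == MISSING, np.nan, G.dosage), columns=G.ids,
    )
    df.insert(0, "animal_id", G.animals)
    with open(matrix_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.0f")
    if map_path is not None:
        with open(map_path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            G.variants.to_csv(fh, sep="\t", index=False)


def _parse_variant_id(vid: str) -> tuple:
    chrom, pos, ref, alt = vid.split(":")
    try:
        chrom = int(chrom)
    except ValueError:
        pass
    return chrom, int(pos), ref, alt


def read_dosage_tsv(matrix_path: str, map_path: str | None = None) -> GenotypeMatrix:
    """Read a dosage TSV (plus optional map TSV carrying DR2/panel labels)."""
    df = pd.read_csv(matrix_path, sep="\t", comment="#")
    animals = df["animal_id"].to_numpy()
    vids = [c for c in df.columns if c != "animal_id"]
    vals = df[vids].to_numpy(dtype=float)
    dosage = np.where(np.isnan(vals), MISSING, vals).astype(np.int8)
    parsed = pd.DataFrame(
        [_parse_variant_id(v) for v in vids], columns=["chrom", "pos", "ref", "alt"]
    )
    if map_path is not None:
        vm = pd.read_csv(map_path, sep="\t", comment="#")
        merged = parsed.merge(vm, on=["chrom", "pos", "ref", "alt"], how="left", validate="1:1")
    else:
        merged = parsed
    return GenotypeMatrix(animals=animals, variants=merged, dosage=dosage)


def read_genotypes(path: str, fmt: str = "vcf", map_path: str | None = None,
                   prefer_ds: bool = True) -> GenotypeMatrix:
    """Unified genotype reader dispatching on format ('vcf' or 'tsv')."""
    if fmt == "vcf":
        return read_vcf(path, prefer_ds=prefer_ds)
    if fmt == "tsv":
        return read_dosage_tsv(path, map_path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_phenotypes(phen: PhenotypeTable, path: str, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        phen.table.to_csv(fh, sep="\t", index=False)


def read_phenotypes(path: str) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", comment="#"))
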