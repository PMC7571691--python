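"""Variant table I/O: flat TSV (canonical) and VCF (via cyvcf2 when present).

The TSV dialect has one row per variant with columns ``chrom``, ``pos``,
``ref``, ``alt``, ``gene``, ``pop_af``, ``n_healthy_hom`` (empty meaning
"not reported") followed by one genotype column per sample (``0/0``,
``0/1``, ``1/1``, ``./.``). VCF input reads GT per sample plus the INFO
keys ``POPAF`` and ``NHOM``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from dcm_phenolink.linkage.varfilter import VariantRecord

__all__ = ["read_variants_tsv", "write_variants_tsv", "read_variants_vcf"]

_FIXED = ["chrom", "pos", "ref", "alt", "gene", "pop_af", "n_healthy_hom"]


def write_variants_tsv(variants: list[VariantRecord], path: str | Path) -> None:
    samples = sorted({s for v in variants for s in v.genotypes})
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "pop_af": "" if v.pop_af is None else v.pop_af,
            "n_healthy_hom": "" if v.n_healthy_homozygotes is None else v.n_healthy_homozygotes,
        }
        for s in samples:
            row[s] = v.genotypes.get(s, "./.")
        rows.append(row)
    pd.DataFrame(rows, columns=_FIXED + samples).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = [c for c in df.columns if c not in _FIXED]
    out = []
    for _, row in df.iterrows():
        out.append(
            VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=str(row["gene"]),
                genotypes={s: str(row[s]) for s in samples},
                pop_af=None if pd.isna(row["pop_af"]) else float(row["pop_af"]),
                n_healthy_homozygotes=(
                    None if pd.isna(row["n_healthy_hom"]) else int(row["n_healthy_hom"])
                ),
            )
        )
    return out


def read_variants_vcf(path: str | Path, gene_info_key: str = "GENE") -> list[VariantRecord]:
    """Read variants from a (plain-text or bgzipped) VCF file.

    Requires ``cyvcf2``. Per-sample GT is translated to the TSV genotype
    dialect; population frequency and healthy-homozygote counts come from
    the INFO keys ``POPAF`` and ``NHOM`` when present.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = {0: "0/0", 1: "0/1", 2: "./.", 3: "1/1"}
    for rec in vcf:
        genotypes = {s: gt_map.get(t, "./.") for s, t in zip(samples, rec.gt_types)}
        pop_af = rec.INFO.get("POPAF")
        nhom = rec.INFO.get("NHOM")
        out.append(
            VariantRecord(
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                ref=str(rec.REF),
                alt=str(rec.ALT[0]) if rec.ALT else ".",
                gene=str(rec.INFO.get(gene_info_key, "")),
                genotypes=genotypes,
                pop_af=None if pop_af is None else float(pop_af),
                n_healthy_homozygotes=None if nhom is None else int(nhom),
            )
        )
    return out
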