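"""Synthetic candidate-variant tables with one planted causal variant.

Emulates the candidate list produced by exome sequencing within a linkage
interval: one variant segregates perfectly with the recessive phenotype
(homozygous-alt in all affected, heterozygous in obligate carriers, absent
from population databases), while every decoy violates at least one of the
recessive filter criteria by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dcm_phenolink.linkage.pedigree import Pedigree
from dcm_phenolink.linkage.varfilter import VariantRecord

__all__ = ["VariantSimSpec", "generate_variant_table"]

_DECOY_FAILURES = (
    "outside_interval",
    "not_hom_in_affected",
    "hom_in_unaffected",
    "common_in_population",
    "healthy_homozygotes",
)


@dataclass(frozen=True)
class VariantSimSpec:
    n_variants: int = 100
    interval: tuple[str, float, float] = ("2", 218.0, 228.0)
    causal_index: int | None = None  # position in the output list; random if None
    pop_af_beta: tuple[float, float] = (0.5, 20.0)  # Beta params for decoy frequencies
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 2:
            raise ValueError("need at least 2 variants (one causal plus decoys)")
        if self.interval[2] <= self.interval[1]:
            raise ValueError("interval end must exceed start")
        if self.causal_index is not None and not 0 <= self.causal_index < self.n_variants:
            raise ValueError("causal_index out of range")

    @property
    def interval_scaled(self) -> tuple[str, int, int]:
        """The interval on the integer position scale of the generated records.

        Record positions are cM x 1e4 rounded to integers (variant
        containers require integral positions); use this interval when
        filtering generated tables.
        """
        chrom, start, end = self.interval
        return (chrom, int(round(start * 1e4)), int(round(end * 1e4)))


def generate_variant_table(
    spec: VariantSimSpec,
    pedigree: Pedigree,
    affections: dict[str, str] | None = None,
) -> list[VariantRecord]:
    """Generate ``n_variants`` records, exactly one of which passes the filter.

    ``affections`` overrides the pedigree's recorded statuses (e.g. from a
    gene-drop replicate). Obligate carriers — parents of affected
    individuals — are heterozygous for the causal variant.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if affections is None:
        affections = {m.id: m.affection for m in pedigree}
    affected = [i for i, a in affections.items() if a == "affected"]
    unaffected = [i for i, a in affections.items() if a == "unaffected"]
    if not affected:
        raise ValueError("pedigree has no affected members; nothing to segregate")
    carriers = set()
    for iid in affected:
        ind = pedigree.members[iid]
        if ind.father_id:
            carriers.update((ind.father_id, ind.mother_id))
    carriers -= set(affected)

    chrom, start, end = spec.interval
    causal_idx = (
        int(rng.integers(spec.n_variants)) if spec.causal_index is None else spec.causal_index
    )
    members = [m.id for m in pedigree]

    records = []
    for i in range(spec.n_variants):
        pos = float(rng.uniform(start, end))
        if i == causal_idx:
            gts = {}
            for iid in members:
                if iid in affected:
                    gts[iid] = "1/1"
                elif iid in carriers:
                    gts[iid] = "0/1"
                else:
                    gts[iid] = rng.choice(["0/0", "0/1"], p=[0.7, 0.3])
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=int(round(pos * 1e4)),
                    ref="G",
                    alt="A",
                    gene=f"GENE{i}",
                    genotypes=gts,
                    pop_af=0.0,
                    n_healthy_homozygotes=0,
                    annotations={"causal": True, "pos_cM": pos},
                )
            )
            continue

        failure = _DECOY_FAILURES[int(rng.integers(len(_DECOY_FAILURES)))]
        gts = {iid: "1/1" if iid in affected else str(rng.choice(["0/0", "0/1"])) for iid in members}
        pop_af: float | None = float(rng.beta(*spec.pop_af_beta))
        pop_af = min(pop_af, 0.01)
        n_hom = 0
        v_chrom, v_pos = chrom, pos
        if failure == "outside_interval":
            v_pos = end + float(rng.uniform(1.0, 50.0))
        elif failure == "not_hom_in_affected":
            gts[str(rng.choice(affected))] = str(rng.choice(["0/0", "0/1"]))
        elif failure == "hom_in_unaffected":
            if unaffected:
                gts[str(rng.choice(unaffected))] = "1/1"
            else:
                v_pos = end + float(rng.uniform(1.0, 50.0))
        elif failure == "common_in_population":
            pop_af = float(rng.uniform(0.02, 1.0))
        elif failure == "healthy_homozygotes":
            n_hom = int(rng.integers(1, 20))
        records.append(
            VariantRecord(
                chrom=v_chrom,
                pos=int(round(v_pos * 1e4)),
                ref=str(rng.choice(["A", "C", "G", "T"])),
                alt=str(rng.choice(["A", "C", "G", "T"])),
                gene=f"GENE{i}",
                genotypes=gts,
                pop_af=pop_af,
                n_healthy_homozygotes=n_hom,
                annotations={"causal": False, "pos_cM": v_pos, "planted_failure": failure},
            )
        )
    return records
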