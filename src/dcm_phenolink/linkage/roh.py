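"""Shared runs of homozygosity across affected members of a family.

In a consanguineous family segregating a recessive disease, all affected
members are expected to be homozygous by descent across the interval
containing the causal variant. This module scans an ordered marker map for
maximal runs where every affected individual is homozygous for the same
allele, drops runs below a minimum genetic length (4 cM by convention) and
annotates each surviving run with any unaffected member who shares the
homozygous haplotype across the whole span — evidence for excluding the
segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dcm_phenolink.linkage.pedigree import GenotypeTable

__all__ = ["ROHSegment", "shared_roh"]


@dataclass
class ROHSegment:
    chrom: str
    start_cM: float
    end_cM: float
    start_index: int  # marker indices into the chromosome's ordered map
    end_index: int  # inclusive
    marker_ids: list[str]
    carriers: tuple[str, ...]
    shared_alleles: list[int] = field(default_factory=list)  # per marker in run
    unaffected_sharing: tuple[str, ...] = ()  # exclusion evidence

    def __post_init__(self) -> None:
        if self.end_cM < self.start_cM:
            raise ValueError("segment end must not precede start")

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM


def shared_roh(
    table: GenotypeTable,
    affected_ids: list[str],
    min_cM: float = 4.0,
    unaffected_ids: list[str] = (),
    require_same_allele: bool = True,
) -> list[ROHSegment]:
    """Maximal shared-homozygosity segments of at least ``min_cM``.

    At each marker the shared-homozygosity condition holds when every
    affected individual is homozygous (both alleles equal, non-missing)
    and — unless ``require_same_allele`` is disabled — all affected carry
    the *same* allele (homozygosity-by-descent proxy). Markers must be
    ordered by cM within each chromosome.
    """
    if not affected_ids:
        raise ValueError("affected_ids must be non-empty")
    for iid in list(affected_ids) + list(unaffected_ids):
        if iid not in table.genotypes:
            raise KeyError(f"no genotypes for individual {iid}")

    segments: list[ROHSegment] = []
    markers = table.markers.reset_index(drop=True)
    for chrom, sub in markers.groupby("chrom", sort=False):
        cm = sub["cM"].to_numpy(dtype=float)
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"markers on chromosome {chrom} are not ordered by cM")
        idx = sub.index.to_numpy()
        n = len(idx)

        shared = np.zeros(n, dtype=bool)
        allele = np.zeros(n, dtype=int)
        for k in range(n):
            j = idx[k]
            alleles = set()
            ok = True
            for iid in affected_ids:
                a, b = table.genotypes[iid][j]
                if a == 0 or b == 0 or a != b:
                    ok = False
                    break
                alleles.add(int(a))
            if ok and require_same_allele and len(alleles) != 1:
                ok = False
            shared[k] = ok
            if ok:
                allele[k] = alleles.pop() if len(alleles) == 1 else -1

        # maximal runs of consecutive shared markers
        k = 0
        while k < n:
            if not shared[k]:
                k += 1
                continue
            k2 = k
            while k2 + 1 < n and shared[k2 + 1]:
                k2 += 1
            length = cm[k2] - cm[k]
            if length >= min_cM:
                run_slice = slice(k, k2 + 1)
                sharing = []
                for uid in unaffected_ids:
                    g = table.genotypes[uid][idx[run_slice]]
                    same = all(
                        int(a) == int(b) == al != 0
                        for (a, b), al in zip(g, allele[run_slice])
                    )
                    if same:
                        sharing.append(uid)
                segments.append(
                    ROHSegment(
                        chrom=str(chrom),
                        start_cM=float(cm[k]),
                        end_cM=float(cm[k2]),
                        start_index=int(k),
                        end_index=int(k2),
                        marker_ids=[str(m) for m in sub["marker_id"].iloc[run_slice]],
                        carriers=tuple(affected_ids),
                        shared_alleles=[int(a) for a in allele[run_slice]],
                        unaffected_sharing=tuple(sharing),
                    )
                )
            k = k2 + 1
    return segments
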