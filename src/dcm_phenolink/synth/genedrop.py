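"""Gene-dropping: forward simulation of genotypes through a pedigree.

Founders draw phased two-locus genotypes (biallelic disease locus at
frequency q; one multi-allelic marker) from Hardy-Weinberg and
linkage-equilibrium priors; each non-founder receives one haplotype per
parent, recombinant between the disease and marker loci with probability
theta; affection status is a penetrance draw given the disease genotype.
The simulated disease genotypes are kept as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dcm_phenolink.linkage.pedigree import GenotypeTable, Individual, Pedigree

__all__ = ["PedigreeSimSpec", "GeneDropResult", "gene_drop", "random_pedigree", "planted_roh_panel"]


@dataclass(frozen=True)
class PedigreeSimSpec:
    pedigree: Pedigree
    disease_allele_freq: float = 0.001
    penetrance: tuple[float, float, float] = (0.0, 0.0, 0.99)
    theta: float = 0.0
    marker_allele_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    n_replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("disease_allele_freq must be in (0, 1)")
        if any(not 0.0 <= p <= 1.0 for p in self.penetrance):
            raise ValueError("penetrance entries must lie in [0, 1]")
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError("theta must lie in [0, 0.5]")
        if abs(sum(self.marker_allele_freqs) - 1.0) > 1e-9:
            raise ValueError("marker_allele_freqs must sum to 1 (tolerance 1e-9)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


@dataclass
class GeneDropResult:
    """One gene-drop replicate: marker genotypes, phenotypes, ground truth."""

    genotypes: GenotypeTable  # single marker, allele codes 1..k
    affections: dict[str, str]
    disease_genotypes: dict[str, tuple[int, int]]  # phased (paternal, maternal) counts
    truth: dict = field(default_factory=dict)


def gene_drop(spec: PedigreeSimSpec) -> list[GeneDropResult]:
    """Simulate ``n_replicates`` independent gene drops through the pedigree."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    order = spec.pedigree.topological_order()
    q = spec.disease_allele_freq
    mk_freqs = np.asarray(spec.marker_allele_freqs, dtype=float)
    k = len(mk_freqs)
    markers = pd.DataFrame({"chrom": ["1"], "marker_id": ["M1"], "cM": [0.0]})

    out = []
    for _ in range(spec.n_replicates):
        haps: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}
        affections: dict[str, str] = {}
        for iid in order:
            ind = spec.pedigree.members[iid]
            if ind.is_founder:
                d = rng.random(2) < q
                m = rng.choice(k, size=2, p=mk_freqs) + 1
                hp, hm = (int(d[0]), int(m[0])), (int(d[1]), int(m[1]))
            else:
                hp = _transmit(haps[ind.father_id], spec.theta, rng)
                hm = _transmit(haps[ind.mother_id], spec.theta, rng)
            haps[iid] = (hp, hm)
            n_disease = hp[0] + hm[0]
            affections[iid] = (
                "affected" if rng.random() < spec.penetrance[n_disease] else "unaffected"
            )
        genotypes = {
            iid: np.array([[haps[iid][0][1], haps[iid][1][1]]]) for iid in order
        }
        out.append(
            GeneDropResult(
                genotypes=GenotypeTable(markers=markers.copy(), genotypes=genotypes),
                affections=affections,
                disease_genotypes={iid: (haps[iid][0][0], haps[iid][1][0]) for iid in order},
                truth={"theta": spec.theta, "spec": spec},
            )
        )
    return out


def _transmit(
    parent: tuple[tuple[int, int], tuple[int, int]], theta: float, rng: np.random.Generator
) -> tuple[int, int]:
    hp, hm = parent
    first = rng.random() < 0.5
    d_src, m_src = (hp, hp) if first else (hm, hm)
    if rng.random() < theta:  # recombinant: marker from the other haplotype
        m_src = hm if first else hp
    return (d_src[0], m_src[1])


# ---------------------------------------------------------------------------
# helper constructors used by simulations and tests
# ---------------------------------------------------------------------------


def random_pedigree(rng: np.random.Generator, max_members: int = 10, p_cousin_loop: float = 0.3) -> Pedigree:
    """A random small pedigree, optionally containing a first-cousin marriage loop.

    With probability ``p_cousin_loop`` the pedigree is a 9-member family in
    which two first cousins marry and have a child (a consanguinity loop);
    otherwise it is a nuclear family of 2 parents and 1 to
    ``max_members - 2`` children. Affection statuses are assigned at random
    (affected/unaffected/unknown).
    """
    def aff() -> str:
        return rng.choice(["affected", "unaffected", "unknown"], p=[0.25, 0.6, 0.15])

    if rng.random() < p_cousin_loop and max_members >= 9:
        ids = [f"I{i}" for i in range(1, 10)]
        inds = [
            Individual("I1", affection=aff(), sex="male"),
            Individual("I2", affection=aff(), sex="female"),
            Individual("I3", "I1", "I2", "male", aff()),
            Individual("I4", "I1", "I2", "female", aff()),
            Individual("I5", affection=aff(), sex="female"),
            Individual("I6", affection=aff(), sex="male"),
            Individual("I7", "I3", "I5", "male", aff()),
            Individual("I8", "I6", "I4", "female", aff()),
            Individual("I9", "I7", "I8", sex="male", affection=aff()),
        ]
        del ids
        return Pedigree(inds)
    n_children = int(rng.integers(1, max(2, max_members - 1)))
    inds = [
        Individual("F", affection=aff(), sex="male"),
        Individual("M", affection=aff(), sex="female"),
    ]
    for c in range(n_children):
        inds.append(Individual(f"C{c + 1}", "F", "M", "unknown", aff()))
    return Pedigree(inds)


def planted_roh_panel(
    n_markers: int = 60,
    spacing_cM: float = 0.5,
    run_start_cM: float = 10.0,
    run_length_cM: float = 10.0,
    affected_ids: tuple[str, ...] = ("A1", "A2"),
    unaffected_ids: tuple[str, ...] = ("U1",),
    n_alleles: int = 4,
    shared_allele: int = 1,
    chrom: str = "2",
    seed: int = 0,
) -> GenotypeTable:
    """A marker panel with a shared homozygous run planted in all affected.

    Outside the run, affected individuals are made heterozygous (so the run
    boundaries are sharp to within one marker); unaffected individuals get
    random genotypes everywhere and are heterozygous inside the run.
    """
    rng = np.random.default_rng(seed)
    cm = np.arange(n_markers) * spacing_cM
    markers = pd.DataFrame(
        {"chrom": chrom, "marker_id": [f"M{i + 1}" for i in range(n_markers)], "cM": cm}
    )
    in_run = (cm >= run_start_cM) & (cm <= run_start_cM + run_length_cM)
    genotypes: dict[str, np.ndarray] = {}
    for iid in affected_ids:
        g = np.empty((n_markers, 2), dtype=int)
        for j in range(n_markers):
            if in_run[j]:
                g[j] = (shared_allele, shared_allele)
            else:
                a = int(rng.integers(1, n_alleles + 1))
                b = int(rng.integers(1, n_alleles))
                b = b if b < a else b + 1  # heterozygous by construction
                g[j] = (a, b)
        genotypes[iid] = g
    for iid in unaffected_ids:
        g = np.empty((n_markers, 2), dtype=int)
        for j in range(n_markers):
            if in_run[j]:
                other = shared_allele % n_alleles + 1
                g[j] = (shared_allele, other)
            else:
                g[j] = rng.integers(1, n_alleles + 1, size=2)
        genotypes[iid] = g
    table = GenotypeTable(markers=markers, genotypes=genotypes)
    if in_run.any():
        table.meta["truth"] = {
            "run_start_cM": float(cm[in_run][0]),
            "run_end_cM": float(cm[in_run][-1]),
            "chrom": chrom,
        }
    else:
        table.meta["truth"] = None
    return table
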