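"""Pedigree and marker-genotype containers (PLINK PED/MAP dialect)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["Individual", "Pedigree", "GenotypeTable"]

AFFECTIONS = ("affected", "unaffected", "unknown")


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"  # 'male' | 'female' | 'unknown'
    affection: str = "unknown"

    def __post_init__(self) -> None:
        if self.affection not in AFFECTIONS:
            raise ValueError(f"affection must be one of {AFFECTIONS}")
        if (self.father_id is None) != (self.mother_id is None):
            raise ValueError(
                f"individual {self.id} has exactly one recorded parent; "
                "record both parents or none"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """A family as a parent-child digraph; marriage loops are allowed.

    Validates that parent references resolve, that every individual has
    both parents recorded or none, and that nobody is their own ancestor.
    """

    def __init__(self, individuals: list[Individual]):
        self.members: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.members:
                raise ValueError(f"duplicate individual id {ind.id}")
            self.members[ind.id] = ind
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for ind in individuals:
            for parent in (ind.father_id, ind.mother_id):
                if parent is not None:
                    if parent not in self.members:
                        raise ValueError(f"parent {parent} of {ind.id} not in pedigree")
                    g.add_edge(parent, ind.id)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("pedigree contains an ancestry cycle")
        self.graph = g

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members.values())

    @property
    def founders(self) -> list[str]:
        return [i for i, ind in self.members.items() if ind.is_founder]

    @property
    def affected(self) -> list[str]:
        return [i for i, ind in self.members.items() if ind.affection == "affected"]

    @property
    def unaffected(self) -> list[str]:
        return [i for i, ind in self.members.items() if ind.affection == "unaffected"]

    def topological_order(self) -> list[str]:
        """Member ids with every parent preceding its children."""
        return list(nx.topological_sort(self.graph))

    def with_affections(self, affections: dict[str, str]) -> "Pedigree":
        """A copy with affection statuses replaced (e.g. from a simulation)."""
        return Pedigree(
            [
                Individual(
                    id=m.id,
                    father_id=m.father_id,
                    mother_id=m.mother_id,
                    sex=m.sex,
                    affection=affections.get(m.id, m.affection),
                )
                for m in self
            ]
        )


@dataclass
class GenotypeTable:
    """Marker genotypes for pedigree members.

    ``markers`` is a DataFrame with columns ``chrom``, ``marker_id``, ``cM``
    (one row per marker, ordered within chromosome); ``genotypes`` maps an
    individual id to an ``(n_markers, 2)`` integer array of allele codes,
    with 0 meaning missing (PLINK convention).
    """

    markers: pd.DataFrame
    genotypes: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "marker_id", "cM"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"markers must have columns {sorted(required)}")
        n = len(self.markers)
        for iid, g in self.genotypes.items():
            g = np.asarray(g, dtype=int)
            if g.shape != (n, 2):
                raise ValueError(f"genotypes for {iid} must have shape ({n}, 2)")
            self.genotypes[iid] = g

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker_id: str) -> int:
        idx = self.markers.index[self.markers["marker_id"] == marker_id]
        if len(idx) != 1:
            raise KeyError(f"marker {marker_id} not found (or duplicated)")
        return int(self.markers.index.get_loc(idx[0]))

    def marker_genotypes(self, marker_id: str) -> dict[str, tuple[int, int] | None]:
        """Per-individual unordered allele pair at one marker; None if untyped."""
        j = self.marker_index(marker_id)
        out: dict[str, tuple[int, int] | None] = {}
        for iid, g in self.genotypes.items():
            a, b = int(g[j, 0]), int(g[j, 1])
            out[iid] = None if a == 0 or b == 0 else (a, b)
        return out

    # ---- PLINK-style text I/O -------------------------------------------

    def to_ped_map(self, ped: Pedigree, prefix: str | Path, family_id: str = "FAM1") -> None:
        """Write ``<prefix>.ped`` and ``<prefix>.map`` (cM in MAP column 3)."""
        prefix = Path(prefix)
        sex_code = {"male": "1", "female": "2", "unknown": "0"}
        aff_code = {"unaffected": "1", "affected": "2", "unknown": "0"}
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for ind in ped:
                g = self.genotypes.get(ind.id)
                alleles = (
                    " ".join(f"{a} {b}" for a, b in g)
                    if g is not None
                    else " ".join("0 0" for _ in range(self.n_markers))
                )
                fh.write(
                    f"{family_id} {ind.id} {ind.father_id or 0} {ind.mother_id or 0} "
                    f"{sex_code[ind.sex]} {aff_code[ind.affection]} {alleles}\n"
                )
        with open(prefix.with_suffix(".map"), "w") as fh:
            for _, row in self.markers.iterrows():
                fh.write(f"{row['chrom']} {row['marker_id']} {row['cM']} 0\n")

    @classmethod
    def from_ped_map(cls, prefix: str | Path) -> tuple["Pedigree", "GenotypeTable"]:
        """Read a PED/MAP pair written by :meth:`to_ped_map` (or PLINK)."""
        prefix = Path(prefix)
        rows = []
        with open(prefix.with_suffix(".map")) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                rows.append({"chrom": parts[0], "marker_id": parts[1], "cM": float(parts[2])})
        markers = pd.DataFrame(rows)
        sex_decode = {"1": "male", "2": "female"}
        aff_decode = {"1": "unaffected", "2": "affected"}
        individuals = []
        genotypes = {}
        with open(prefix.with_suffix(".ped")) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                _, iid, fid, mid, sex, aff = parts[:6]
                individuals.append(
                    Individual(
                        id=iid,
                        father_id=None if fid == "0" else fid,
                        mother_id=None if mid == "0" else mid,
                        sex=sex_decode.get(sex, "unknown"),
                        affection=aff_decode.get(aff, "unknown"),
                    )
                )
                alleles = np.array([int(a) for a in parts[6:]], dtype=int)
                genotypes[iid] = alleles.reshape(-1, 2)
        return Pedigree(individuals), cls(markers=markers, genotypes=genotypes)
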