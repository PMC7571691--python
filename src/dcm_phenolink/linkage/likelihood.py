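"""Exact two-locus pedigree likelihoods and two-point Lod scores.

The model is the classic parametric linkage setup: a biallelic disease
locus with allele frequency q and a penetrance triple (P(affected | 0, 1, 2
disease alleles)), plus a multi-allelic marker at recombination fraction
theta from the disease locus. Founders draw phased two-locus genotypes from
Hardy-Weinberg and linkage-equilibrium priors; each child receives one
haplotype per parent, recombinant with probability theta; phenotypes are
penetrance draws and marker genotypes are observed.

The likelihood is computed exactly by peeling, implemented as variable
elimination on the pedigree factor graph over phased per-individual states.
Variable elimination generalizes Elston-Stewart peeling to looped
(consanguineous) pedigrees without loop-breaking approximations; the
configured state bound guards against pathological state-space blowup
(many untyped members of a large family).

The two-point Lod score is ``log10 L(theta) - log10 L(1/2)`` on a grid of
recombination fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from dcm_phenolink.linkage.pedigree import GenotypeTable, Individual, Pedigree

__all__ = [
    "LinkageModel",
    "LodResult",
    "pedigree_likelihood",
    "two_point_lod",
    "transmission_probability",
]

DEFAULT_THETA_GRID = (0.00, 0.01, 0.05, 0.10, 0.20, 0.30, 0.40)


@dataclass(frozen=True)
class LinkageModel:
    """Recessive (by default) single-locus disease model for linkage.

    ``penetrance`` is P(affected) given 0, 1 or 2 copies of the disease
    allele; the default (0, 0, 0.99) is a fully recessive model with 99%
    penetrance and no phenocopies. ``disease_allele_freq`` defaults to
    0.001 (0.01 being the conventional alternative for a commoner allele).
    """

    disease_allele_freq: float = 0.001
    penetrance: tuple[float, float, float] = (0.0, 0.0, 0.99)
    theta_grid: tuple[float, ...] = DEFAULT_THETA_GRID

    def __post_init__(self) -> None:
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("disease_allele_freq must be in (0, 1)")
        if any(not 0.0 <= p <= 1.0 for p in self.penetrance):
            raise ValueError("penetrance entries must lie in [0, 1]")
        if any(not 0.0 <= t <= 0.5 for t in self.theta_grid):
            raise ValueError("theta grid entries must lie in [0, 0.5]")

    def phenotype_probability(self, affection: str, n_disease_alleles: int) -> float:
        pen = self.penetrance[n_disease_alleles]
        if affection == "affected":
            return pen
        if affection == "unaffected":
            return 1.0 - pen
        return 1.0  # unknown phenotype carries no information


@dataclass
class LodResult:
    marker_id: str
    theta: np.ndarray
    lod: np.ndarray
    theta_hat: float

    def __post_init__(self) -> None:
        i_half = np.nonzero(np.isclose(self.theta, 0.5))[0]
        for i in i_half:
            if abs(self.lod[i]) > 1e-9:
                raise ValueError("Lod(0.5) must be 0")


# ---------------------------------------------------------------------------
# state machinery: a phased two-locus state is (dp, mp, dm, mm) where the
# first haplotype (dp, mp) is of paternal origin; d in {0, 1} counts the
# disease allele, m is a marker allele code.
# ---------------------------------------------------------------------------

State = tuple[int, int, int, int]


def transmission_probability(parent_state: State, hap: tuple[int, int], theta: float) -> float:
    """P(parent transmits haplotype ``hap``) under recombination ``theta``.

    The transmitted gamete takes both alleles from one parental haplotype
    (no recombination, probability (1-theta)/2 per haplotype) or the
    disease allele from one and the marker allele from the other
    (recombinant, theta/2 per phase).
    """
    dp, mp, dm, mm = parent_state
    d, m = hap
    p = 0.0
    if (d, m) == (dp, mp):
        p += 0.5 * (1.0 - theta)
    if (d, m) == (dp, mm):
        p += 0.5 * theta
    if (d, m) == (dm, mm):
        p += 0.5 * (1.0 - theta)
    if (d, m) == (dm, mp):
        p += 0.5 * theta
    return p


def _feasible_states(
    ind: Individual,
    observed: tuple[int, int] | None,
    alleles: list[int],
    model: LinkageModel,
) -> list[State]:
    states = []
    obs = None if observed is None else tuple(sorted(observed))
    for dp, dm in product((0, 1), repeat=2):
        if model.phenotype_probability(ind.affection, dp + dm) <= 0.0:
            continue
        for mp, mm in product(alleles, repeat=2):
            if obs is not None and tuple(sorted((mp, mm))) != obs:
                continue
            states.append((dp, mp, dm, mm))
    return states


def _founder_prior(state: State, q: float, marker_freqs: dict[int, float]) -> float:
    dp, mp, dm, mm = state
    pd_ = (1.0 - q, q)
    return pd_[dp] * pd_[dm] * marker_freqs.get(mp, 0.0) * marker_freqs.get(mm, 0.0)


class _Factor:
    __slots__ = ("vars", "values")

    def __init__(self, vars_: tuple[str, ...], values: np.ndarray):
        self.vars = vars_
        self.values = values

    def multiply(self, other: "_Factor") -> "_Factor":
        out_vars = list(self.vars) + [v for v in other.vars if v not in self.vars]
        a = _expand(self, out_vars)
        b = _expand(other, out_vars)
        return _Factor(tuple(out_vars), a * b)

    def sum_out(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        new_vars = tuple(v for v in self.vars if v != var)
        return _Factor(new_vars, self.values.sum(axis=axis))


def _expand(f: _Factor, out_vars: list[str]) -> np.ndarray:
    # permute existing axes into out_vars order, inserting singleton axes
    perm = [f.vars.index(v) for v in out_vars if v in f.vars]
    arr = np.transpose(f.values, perm)
    shape = []
    j = 0
    for v in out_vars:
        if v in f.vars:
            shape.append(arr.shape[j])
            j += 1
        else:
            shape.append(1)
    return arr.reshape(shape)


def pedigree_likelihood(
    ped: Pedigree,
    marker_genotypes: dict[str, tuple[int, int] | None],
    model: LinkageModel,
    theta: float,
    marker_allele_freqs: dict[int, float] | None = None,
    state_bound: int = 10**7,
) -> float:
    """Exact joint likelihood of phenotypes and marker genotypes at ``theta``.

    ``marker_genotypes`` maps each member id to an unordered allele pair or
    None for untyped members. Marker allele frequencies default to uniform
    over the alleles observed in the family (an explicit assumption on the
    founder priors). Mendelian-inconsistent data yield likelihood 0.

    Raises ``MemoryError``-style ``ValueError`` when an intermediate factor
    would exceed ``state_bound`` entries.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    observed_alleles = sorted(
        {a for g in marker_genotypes.values() if g is not None for a in g}
    )
    if marker_allele_freqs is None:
        if not observed_alleles:
            raise ValueError("no marker genotypes observed; supply marker_allele_freqs")
        marker_allele_freqs = {a: 1.0 / len(observed_alleles) for a in observed_alleles}
    else:
        total = sum(marker_allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("marker_allele_freqs must sum to 1")
    alleles = sorted(marker_allele_freqs)

    states: dict[str, list[State]] = {}
    for ind in ped:
        s = _feasible_states(ind, marker_genotypes.get(ind.id), alleles, model)
        if not s:
            return 0.0  # observed data impossible under the model
        states[ind.id] = s

    factors: list[_Factor] = []
    q = model.disease_allele_freq
    for ind in ped:
        s_i = states[ind.id]
        pen = np.array(
            [model.phenotype_probability(ind.affection, st[0] + st[2]) for st in s_i]
        )
        if ind.is_founder:
            prior = np.array([_founder_prior(st, q, marker_allele_freqs) for st in s_i])
            factors.append(_Factor((ind.id,), prior * pen))
        else:
            s_f = states[ind.father_id]
            s_m = states[ind.mother_id]
            size = len(s_i) * len(s_f) * len(s_m)
            if size > state_bound:
                raise ValueError(
                    f"transmission factor for {ind.id} needs {size} states "
                    f"(> bound {state_bound}); type more members or raise the bound"
                )
            tf = np.empty((len(s_i), len(s_f), len(s_m)))
            for a, st in enumerate(s_i):
                hap_pat = (st[0], st[1])
                hap_mat = (st[2], st[3])
                tp = np.array([transmission_probability(fs, hap_pat, theta) for fs in s_f])
                tm = np.array([transmission_probability(ms, hap_mat, theta) for ms in s_m])
                tf[a] = np.outer(tp, tm) * pen[a]
            factors.append(_Factor((ind.id, ind.father_id, ind.mother_id), tf))

    # greedy variable elimination: repeatedly eliminate the variable whose
    # combined factor is smallest
    remaining = set(states)
    while remaining:
        best_var, best_size = None, None
        for v in remaining:
            involved = [f for f in factors if v in f.vars]
            vars_union = set().union(*(f.vars for f in involved))
            size = int(np.prod([len(states[u]) for u in vars_union]))
            if best_size is None or size < best_size:
                best_var, best_size = v, size
        if best_size is not None and best_size > state_bound:
            raise ValueError(
                f"elimination of {best_var} needs {best_size} states (> bound {state_bound})"
            )
        involved = [f for f in factors if best_var in f.vars]
        rest = [f for f in factors if best_var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.sum_out(best_var)]
        remaining.discard(best_var)

    out = 1.0
    for f in factors:
        out *= float(f.values)  # all axes summed out: 0-d arrays
    return out


def two_point_lod(
    ped: Pedigree,
    genotypes: GenotypeTable | dict[str, tuple[int, int] | None],
    model: LinkageModel,
    marker_id: str | None = None,
    marker_allele_freqs: dict[int, float] | None = None,
) -> LodResult:
    """Two-point Lod score across the model's theta grid for one marker.

    ``genotypes`` may be a :class:`GenotypeTable` (with ``marker_id``
    naming the marker) or a plain per-individual genotype dict.
    """
    if isinstance(genotypes, GenotypeTable):
        if marker_id is None:
            if genotypes.n_markers != 1:
                raise ValueError("marker_id required when the table has several markers")
            marker_id = str(genotypes.markers["marker_id"].iloc[0])
        geno = genotypes.marker_genotypes(marker_id)
    else:
        geno = genotypes
        marker_id = marker_id or "marker"

    grid = np.asarray(model.theta_grid, dtype=float)
    l_half = pedigree_likelihood(ped, geno, model, 0.5, marker_allele_freqs)
    if l_half <= 0.0:
        raise ValueError("likelihood at theta=0.5 is zero: data inconsistent with pedigree")
    lods = np.empty(len(grid))
    for i, th in enumerate(grid):
        l_th = pedigree_likelihood(ped, geno, model, float(th), marker_allele_freqs)
        lods[i] = -np.inf if l_th <= 0.0 else np.log10(l_th) - np.log10(l_half)
    theta_hat = float(grid[int(np.argmax(lods))])
    return LodResult(marker_id=marker_id, theta=grid, lod=lods, theta_hat=theta_hat)
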