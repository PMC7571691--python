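"""Independent reference implementations used to cross-check the package.

These deliberately re-derive results by the most direct route available —
depth-first enumeration over genotype configurations, nested-loop block
matching — and share no code with the implementations they check.
"""

from __future__ import annotations

import numpy as np

from dcm_phenolink.linkage import LinkageModel, Pedigree


def enumeration_likelihood(
    ped: Pedigree,
    marker_genotypes: dict,
    model: LinkageModel,
    theta: float,
    marker_allele_freqs: dict[int, float] | None = None,
) -> float:
    """Brute-force pedigree likelihood: depth-first sum over all phased
    two-locus genotype configurations in topological order."""
    observed = sorted({a for g in marker_genotypes.values() if g is not None for a in g})
    if marker_allele_freqs is None:
        marker_allele_freqs = {a: 1.0 / len(observed) for a in observed}
    alleles = sorted(marker_allele_freqs)
    q = model.disease_allele_freq
    order = ped.topological_order()

    def states_for(iid):
        ind = ped.members[iid]
        obs = marker_genotypes.get(iid)
        obs = None if obs is None else tuple(sorted(obs))
        out = []
        for dp in (0, 1):
            for dm in (0, 1):
                for mp in alleles:
                    for mm in alleles:
                        if obs is not None and tuple(sorted((mp, mm))) != obs:
                            continue
                        out.append((dp, mp, dm, mm))
        return out

    states = {iid: states_for(iid) for iid in order}

    def transmit(parent_state, hap):
        dp, mp, dm, mm = parent_state
        p = 0.0
        if hap == (dp, mp):
            p += 0.5 * (1 - theta)
        if hap == (dp, mm):
            p += 0.5 * theta
        if hap == (dm, mm):
            p += 0.5 * (1 - theta)
        if hap == (dm, mp):
            p += 0.5 * theta
        return p

    def rec(i, assign):
        if i == len(order):
            return 1.0
        iid = order[i]
        ind = ped.members[iid]
        total = 0.0
        for st in states[iid]:
            pen = model.phenotype_probability(ind.affection, st[0] + st[2])
            if pen == 0.0:
                continue
            if ind.is_founder:
                pd_ = (1 - q, q)
                p = (
                    pd_[st[0]]
                    * pd_[st[2]]
                    * marker_allele_freqs[st[1]]
                    * marker_allele_freqs[st[3]]
                    * pen
                )
            else:
                p = (
                    transmit(assign[ind.father_id], (st[0], st[1]))
                    * transmit(assign[ind.mother_id], (st[2], st[3]))
                    * pen
                )
            if p == 0.0:
                continue
            assign[iid] = st
            total += p * rec(i + 1, assign)
            del assign[iid]
        return total

    return rec(0, {})


def naive_block_match(frames: np.ndarray, block_px: int = 16, search_px: int = 8, min_variance: float = 1e-6):
    """Nested-loop NCC block matcher with the smallest-displacement tie-break.

    Returns (vectors, valid) for the first frame pair only.
    """
    f1, f2 = np.asarray(frames[0], float), np.asarray(frames[1], float)
    ny, nx = f1.shape
    nby, nbx = ny // block_px, nx // block_px
    vectors = np.zeros((nby, nbx, 2))
    valid = np.zeros((nby, nbx), dtype=bool)
    shifts = sorted(
        ((dy, dx) for dy in range(-search_px, search_px + 1) for dx in range(-search_px, search_px + 1)),
        key=lambda s: (s[0] ** 2 + s[1] ** 2, s[0], s[1]),
    )
    for by in range(nby):
        for bx in range(nbx):
            r0, c0 = by * block_px, bx * block_px
            ref = f1[r0 : r0 + block_px, c0 : c0 + block_px]
            if ref.var() < min_variance:
                continue
            best, best_v = -np.inf, None
            a = ref - ref.mean()
            na = np.sqrt((a * a).sum())
            for dy, dx in shifts:
                r, c = r0 + dy, c0 + dx
                if r < 0 or c < 0 or r + block_px > ny or c + block_px > nx:
                    continue
                tgt = f2[r : r + block_px, c : c + block_px]
                b = tgt - tgt.mean()
                nb = np.sqrt((b * b).sum())
                if na == 0 or nb == 0:
                    continue
                score = float((a * b).sum() / (na * nb))
                if score > best:
                    best, best_v = score, (dy, dx)
            if best_v is not None:
                vectors[by, bx] = best_v
                valid[by, bx] = True
    return vectors, valid
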