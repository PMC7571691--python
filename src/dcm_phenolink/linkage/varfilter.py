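"""Recessive candidate-variant filtering with a per-rule audit trail.

Given a candidate interval from linkage/homozygosity mapping, a variant
survives when it (in documented rule order):

1. lies inside the interval (``in_interval``),
2. is homozygous-alt in every affected individual (``hom_in_affected``),
3. is not homozygous-alt in any unaffected individual
   (``not_hom_in_unaffected``),
4. has a population allele frequency at most ``max_pop_af`` — a missing
   frequency means "not reported in the databases" and passes
   (``pop_af``),
5. has at most ``max_healthy_hom`` reported healthy homozygous carriers,
   missing counts passing likewise (``healthy_hom``).

Each rejected variant is logged with the *first* failing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["VariantRecord", "FilterAudit", "filter_variants", "RULE_ORDER"]

VALID_GT = {"0/0", "0/1", "1/1", "./."}

RULE_ORDER = (
    "in_interval",
    "hom_in_affected",
    "not_hom_in_unaffected",
    "pop_af",
    "healthy_hom",
)


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    genotypes: dict[str, str]  # sample -> '0/0' | '0/1' | '1/1' | './.'
    pop_af: float | None = None
    n_healthy_homozygotes: int | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError("pos must be positive")
        bad = {g for g in self.genotypes.values() if g not in VALID_GT}
        if bad:
            raise ValueError(f"invalid genotype strings {bad}; expected one of {VALID_GT}")

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class FilterAudit:
    variant: VariantRecord
    passed: bool
    failed_rule: str | None = None


def filter_variants(
    variants: list[VariantRecord],
    interval: tuple[str, float, float],
    affected_ids: list[str],
    unaffected_ids: list[str] = (),
    max_pop_af: float = 0.01,
    max_healthy_hom: int = 0,
) -> tuple[list[VariantRecord], list[FilterAudit]]:
    """Apply the recessive filter; returns (survivors, per-variant audit).

    ``interval`` is (chrom, start, end) on the same coordinate scale as the
    variant positions (inclusive bounds). The result is independent of the
    input order, and each rejection is attributed to exactly the first
    failing rule in :data:`RULE_ORDER`.
    """
    chrom, start, end = interval
    survivors: list[VariantRecord] = []
    audit: list[FilterAudit] = []
    for v in variants:
        rule = _first_failure(v, chrom, start, end, affected_ids, unaffected_ids, max_pop_af, max_healthy_hom)
        if rule is None:
            survivors.append(v)
            audit.append(FilterAudit(v, True))
        else:
            audit.append(FilterAudit(v, False, rule))
    return survivors, audit


def _first_failure(
    v: VariantRecord,
    chrom: str,
    start: float,
    end: float,
    affected_ids: list[str],
    unaffected_ids: list[str],
    max_pop_af: float,
    max_healthy_hom: int,
) -> str | None:
    if v.chrom != chrom or not start <= v.pos <= end:
        return "in_interval"
    for iid in affected_ids:
        if v.genotypes.get(iid, "./.") != "1/1":
            return "hom_in_affected"
    for iid in unaffected_ids:
        if v.genotypes.get(iid) == "1/1":
            return "not_hom_in_unaffected"
    if v.pop_af is not None and v.pop_af > max_pop_af:
        return "pop_af"
    if v.n_healthy_homozygotes is not None and v.n_healthy_homozygotes > max_healthy_hom:
        return "healthy_hom"
    return None
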