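"""Weight value (Wv) scoring of candidate genes from domain interactions.

Each candidate protein P_i carries one or more Pfam domains; for each such
parent domain D_i, every interaction partner D_j in the domain network is
scored against four binary evidence classes:

  a) D_j occurs in a protein carrying disease-associated non-synonymous
     variants (a curated domain list, T_a entries);
  b) D_j maps, via Pfam2GO, to a disease-relevant GO biological process
     (T_b processes);
  c) some protein harboring D_j lies inside a disease-linked chromosomal
     region (T_c regions);
  d) some protein harboring D_j is a known disease gene (an OMIM-style
     list of T_d proteins, deduplicated against class a).

Per-partner components are the binary indicator divided by the class total
(a_j = D_ja / T_a, ..., d_j = P_jd / T_d), the parent's raw weight is the sum
over its N distinct partners (optionally the per-partner mean), raw weights
are min-max normalized across the run's parent domains, and each protein is
assigned the highest normalized Wv among its domains.  Proteins with
Wv > 0.5 are High Weight Elements (HWEs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .core_model import (
    DomainProteinMap,
    MarkerRegion,
    Protein,
    region_overlap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClassCatalog",
    "PartnerScore",
    "WvScore",
    "CandidateScore",
    "HWE_THRESHOLD",
    "score_partner",
    "weight_value",
    "normalize_scores",
    "assign_protein_scores",
    "score_candidates",
]

HWE_THRESHOLD = 0.5  # strict: Wv > 0.5


@dataclass(frozen=True)
class ClassCatalog:
    """The four evidence classes and their totals.

    ``t_d_raw`` keeps the pre-deduplication disease-gene count for reporting;
    scoring always uses ``t_d`` (class-d proteins already counted under
    class a removed).
    """

    class_a_domains: frozenset[str]
    class_b_processes: frozenset[str]
    pfam2go: Mapping[str, frozenset[str]]
    class_c_regions: tuple[MarkerRegion, ...]
    class_d_proteins: frozenset[str]
    t_a: int
    t_b: int
    t_c: int
    t_d: int
    t_d_raw: int | None = None

    def __post_init__(self) -> None:
        for name in ("t_a", "t_b", "t_c", "t_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"class total {name} must be positive")

    @classmethod
    def from_members(
        cls,
        class_a_domains: Iterable[str],
        class_b_processes: Iterable[str],
        pfam2go: Mapping[str, frozenset[str]],
        class_c_regions: Sequence[MarkerRegion],
        class_d_proteins: Iterable[str],
        totals: tuple[int, int, int, int] | None = None,
    ) -> "ClassCatalog":
        """Build a catalog; totals default to observed membership sizes.

        ``totals`` overrides them when the catalogs are samples of a larger
        curated universe (e.g. the published totals 60, 15, 64, 1746).
        """
        a = frozenset(class_a_domains)
        b = frozenset(class_b_processes)
        d = frozenset(class_d_proteins)
        t = totals or (len(a), len(b), len(class_c_regions), len(d))
        return cls(
            class_a_domains=a,
            class_b_processes=b,
            pfam2go=dict(pfam2go),
            class_c_regions=tuple(class_c_regions),
            class_d_proteins=d,
            t_a=t[0],
            t_b=t[1],
            t_c=t[2],
            t_d=t[3],
            t_d_raw=len(d),
        )

    def deduplicate_class_d(self, dp_map: DomainProteinMap) -> "ClassCatalog":
        """Drop class-d proteins that harbor a class-a domain; shrink T_d.

        Mirrors the curation step that removes disease genes already counted
        under the variant-domain class so no protein is double-counted.
        """
        overlap = {
            p
            for p in self.class_d_proteins
            if dp_map.domains_of(p) & self.class_a_domains
        }
        if not overlap:
            return self
        kept = self.class_d_proteins - overlap
        if not kept:
            logger.warning(
                "class d would be empty after class-a deduplication; kept as-is"
            )
            return self
        return replace(
            self,
            class_d_proteins=frozenset(kept),
            t_d=self.t_d - len(overlap),
            t_d_raw=self.t_d_raw or len(self.class_d_proteins),
        )


@dataclass(frozen=True)
class PartnerScore:
    """Binary evidence of one partner domain, as indicator/total components."""

    partner: str
    d_ja: int
    d_jb: int
    p_jc: int
    p_jd: int
    a_j: float
    b_j: float
    c_j: float
    d_j: float

    @property
    def total(self) -> float:
        return self.a_j + self.b_j + self.c_j + self.d_j


@dataclass
class WvScore:
    """Raw and normalized weight value of one parent domain."""

    parent: str
    n_partners: int
    raw: float
    normalized: float | None = None


@dataclass
class CandidateScore:
    """Protein-level outcome: best domain's normalized Wv and its C_i."""

    protein: str
    gene_symbol: str | None
    best_domain: str
    n_partners: int
    raw_wv: float
    wv: float
    ci: float
    is_hwe: bool
    is_hwec: bool = False


def score_partner(
    partner: str,
    catalog: ClassCatalog,
    dp_map: DomainProteinMap,
    annotation: Mapping[str, Protein],
    cd_mode: str = "binary",
) -> PartnerScore:
    """Score one partner domain against the four evidence classes.

    Classes c and d look at *all* proteins harboring the partner and, in
    the default ``cd_mode="binary"``, fire if any qualifies (logical OR).
    ``cd_mode="count"`` instead counts the qualifying harboring proteins,
    giving c_j = count/T_c and d_j = count/T_d.  A partner absent from the
    mapping simply scores zero on those classes.
    """
    if cd_mode not in ("binary", "count"):
        raise ValueError(f"unknown cd_mode {cd_mode!r}")
    d_ja = 1 if partner in catalog.class_a_domains else 0
    d_jb = (
        1
        if catalog.pfam2go.get(partner, frozenset()) & catalog.class_b_processes
        else 0
    )
    p_jc = 0
    p_jd = 0
    binary = cd_mode == "binary"
    for prot in dp_map.proteins_of(partner):
        if prot in catalog.class_d_proteins:
            p_jd += 1
        protein = annotation.get(prot)
        if protein is not None and region_overlap(
            protein, catalog.class_c_regions
        ):
            p_jc += 1
        if binary and p_jc and p_jd:
            break
    if binary:
        p_jc = min(p_jc, 1)
        p_jd = min(p_jd, 1)
    return PartnerScore(
        partner=partner,
        d_ja=d_ja,
        d_jb=d_jb,
        p_jc=p_jc,
        p_jd=p_jd,
        a_j=d_ja / catalog.t_a,
        b_j=d_jb / catalog.t_b,
        c_j=p_jc / catalog.t_c,
        d_j=p_jd / catalog.t_d,
    )


def weight_value(
    parent: str,
    network: nx.Graph,
    catalog: ClassCatalog,
    dp_map: DomainProteinMap,
    annotation: Mapping[str, Protein],
    aggregation: str = "sum",
    cd_mode: str = "binary",
    _partner_cache: dict[str, PartnerScore] | None = None,
) -> WvScore:
    """Raw weight value of one parent domain over its N network partners.

    ``aggregation='sum'`` (default) adds the four components over all
    distinct partners; ``'mean'`` divides that sum by N.  A parent with no
    partners scores 0.
    """
    if aggregation not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    partners = sorted(network.neighbors(parent)) if parent in network else []
    total = 0.0
    for partner in partners:
        if _partner_cache is not None and partner in _partner_cache:
            ps = _partner_cache[partner]
        else:
            ps = score_partner(partner, catalog, dp_map, annotation, cd_mode)
            if _partner_cache is not None:
                _partner_cache[partner] = ps
        total += ps.total
    n = len(partners)
    if n == 0:
        logger.debug("parent %s has no partners; raw Wv = 0", parent)
    raw = total if aggregation == "sum" or n == 0 else total / n
    return WvScore(parent=parent, n_partners=n, raw=raw)


def normalize_scores(
    scores: Iterable[WvScore], method: str = "minmax"
) -> list[WvScore]:
    """Fill the ``normalized`` field across the run's parent domains.

    ``minmax`` (default) maps the run's minimum raw score to 0 and maximum
    to 1; ``maxscale`` divides by the maximum instead.  If all raw values
    coincide there is no information to rank on: everything normalizes to 0
    with a warning.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to normalize")
    raws = [s.raw for s in scores]
    lo, hi = min(raws), max(raws)
    if hi == lo or (method == "maxscale" and hi == 0):
        logger.warning("all raw weight values equal (%g); normalized to 0", lo)
        for s in scores:
            s.normalized = 0.0
        return scores
    if method == "minmax":
        for s in scores:
            s.normalized = (s.raw - lo) / (hi - lo)
    elif method == "maxscale":
        for s in scores:
            s.normalized = s.raw / hi
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return scores


def assign_protein_scores(
    annotation: Mapping[str, Protein],
    dp_map: DomainProteinMap,
    wv_scores: Mapping[str, WvScore],
    network: nx.Graph,
    hwe_threshold: float = HWE_THRESHOLD,
) -> tuple[list[CandidateScore], list[str]]:
    """Assign each protein the highest normalized Wv among its domains.

    Ties between domains break toward the lower clustering coefficient
    (the quantity the next stage filters on), then lexicographically.
    Proteins with no assigned domain are excluded and returned separately.
    Returns ``(candidates, excluded_protein_ids)``.
    """
    ci = {n: float(c) for n, c in nx.clustering(network).items()}
    candidates: list[CandidateScore] = []
    excluded: list[str] = []
    for acc in sorted(annotation):
        domains = [d for d in dp_map.domains_of(acc) if d in wv_scores]
        if not domains:
            excluded.append(acc)
            continue
        best = min(
            domains,
            key=lambda d: (
                -(wv_scores[d].normalized or 0.0),
                ci.get(d, 0.0),
                d,
            ),
        )
        score = wv_scores[best]
        wv = score.normalized if score.normalized is not None else 0.0
        candidates.append(
            CandidateScore(
                protein=acc,
                gene_symbol=annotation[acc].gene_symbol,
                best_domain=best,
                n_partners=score.n_partners,
                raw_wv=score.raw,
                wv=wv,
                ci=ci.get(best, 0.0),
                is_hwe=wv > hwe_threshold,
            )
        )
    if excluded:
        logger.info(
            "excluded %d proteins without any scored domain", len(excluded)
        )
    return candidates, excluded


def score_candidates(
    network: nx.Graph,
    catalog: ClassCatalog,
    dp_map: DomainProteinMap,
    annotation: Mapping[str, Protein],
    aggregation: str = "sum",
    normalization: str = "minmax",
    cd_mode: str = "binary",
) -> tuple[list[CandidateScore], list[str]]:
    """End-to-end scoring: every annotated protein's domains become parents,
    each parent is weighted over its partners, weights are normalized across
    the run, and protein-level candidate scores are assigned.
    """
    parents = sorted(
        {
            d
            for acc in annotation
            for d in dp_map.domains_of(acc)
        }
    )
    if not parents:
        raise ValueError("no candidate protein has an assigned domain")
    cache: dict[str, PartnerScore] = {}
    raw = [
        weight_value(
            p, network, catalog, dp_map, annotation, aggregation, cd_mode, cache
        )
        for p in parents
    ]
    normalized = normalize_scores(raw, normalization)
    wv_by_parent = {s.parent: s for s in normalized}
    return assign_protein_scores(annotation, dp_map, wv_by_parent, network)
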