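"""HRC prioritization: filter High Weight Elements by clustering coefficient.

Disease genes have been observed to avoid densely clustered network
neighborhoods, with an average local clustering coefficient near 0.015 in
disease-gene interaction networks.  The HRC step ("high weight elements
ranked by clustering coefficient") therefore keeps, among the candidates
with normalized Wv > 0.5 (HWEs), exactly those whose best domain has
C_i < 0.015 in the domain interaction network; these are the final
prioritized candidates (HWEc).

Both thresholds are strict inequalities and both are configurable; the
defaults are the published values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .wv_scoring import CandidateScore, HWE_THRESHOLD

__all__ = [
    "CI_THRESHOLD",
    "PrioritizationResult",
    "prioritize",
    "table3_check",
]

CI_THRESHOLD = 0.015  # strict: C_i < 0.015


@dataclass
class PrioritizationResult:
    """Outcome of the HWE → HWEc filtering over one candidate set."""

    candidates: list[CandidateScore]
    hwe_count: int
    hwec_count: int
    wv_threshold: float
    ci_threshold: float

    @property
    def hwec(self) -> list[CandidateScore]:
        return [c for c in self.candidates if c.is_hwec]

    @property
    def hwe(self) -> list[CandidateScore]:
        return [c for c in self.candidates if c.is_hwe]


def prioritize(
    candidates: Iterable[CandidateScore],
    wv_threshold: float = HWE_THRESHOLD,
    ci_threshold: float = CI_THRESHOLD,
) -> PrioritizationResult:
    """Flag HWEs (wv > wv_threshold) and HWEc (additionally ci < ci_threshold).

    Output is sorted by wv descending, then ci ascending, then protein ID,
    so runs diff cleanly; the ordering itself is a reporting convention, not
    part of the method.
    """
    ranked: list[CandidateScore] = []
    for c in candidates:
        c.is_hwe = c.wv > wv_threshold
        c.is_hwec = c.is_hwe and c.ci < ci_threshold
        ranked.append(c)
    ranked.sort(key=lambda c: (-c.wv, c.ci, c.protein))
    return PrioritizationResult(
        candidates=ranked,
        hwe_count=sum(c.is_hwe for c in ranked),
        hwec_count=sum(c.is_hwec for c in ranked),
        wv_threshold=wv_threshold,
        ci_threshold=ci_threshold,
    )


def table3_check(
    rows: Sequence,
    wv_threshold: float = HWE_THRESHOLD,
    ci_threshold: float = CI_THRESHOLD,
) -> tuple[int, int, dict[str, bool]]:
    """Apply the HWE/HWEc rules to benchmark rows carrying (gene, wv, ci).

    Used as a regression check against the packaged 19-gene comparison
    table: returns ``(hwe_count, hwec_count, {gene: prioritized})``.
    """
    candidates = [
        CandidateScore(
            protein=r.gene,
            gene_symbol=r.gene,
            best_domain="-",
            n_partners=0,
            raw_wv=r.wv,
            wv=r.wv,
            ci=r.ci,
            is_hwe=False,
        )
        for r in rows
    ]
    result = prioritize(candidates, wv_threshold, ci_threshold)
    flags = {c.protein: c.is_hwec for c in result.candidates}
    return result.hwe_count, result.hwec_count, flags
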