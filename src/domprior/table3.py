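"""Packaged benchmark table: 19 GWA-established T2D genes with their
published normalized weight values (Wv), local clustering coefficients
(C_i), prioritization flag, and the rank assigned by the GeneWanderer
random-walk method ('-' in the source, ``None`` here, where the gene was
not ranked).

The rows are immutable regression data: they let the HWE (Wv > 0.5) and
HWEc (additionally C_i < 0.015) decision rules be checked against the
published per-gene outcomes without rebuilding the full-scale network.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Table3Row", "table3_fixture"]


@dataclass(frozen=True)
class Table3Row:
    gene: str
    wv: float
    ci: float
    prioritized: bool
    genewanderer_rank: int | None


_ROWS: tuple[Table3Row, ...] = (
    Table3Row("ADAMTS9", 1.00, 0.000, True, 35),
    Table3Row("NOTCH2", 0.93, 0.000, True, 9),
    Table3Row("HNF1B", 0.87, 1.000, False, None),
    Table3Row("PPARG", 0.77, 0.667, False, 1),
    Table3Row("KCNQ1", 0.73, 0.033, False, 4),
    Table3Row("CDKL1", 0.63, 0.005, True, 16),
    Table3Row("CAMK1D", 0.63, 0.005, True, 30),
    Table3Row("IGF2BP2", 0.59, 0.010, True, 71),
    Table3Row("LGR5", 0.56, 0.286, False, 41),
    Table3Row("CDKN2B", 0.53, 0.016, False, 1),
    Table3Row("CDKN2A", 0.53, 0.016, False, 3),
    Table3Row("HHEX", 0.53, 0.053, False, 16),
    Table3Row("TSPAN8", 0.51, 0.000, True, 10),
    Table3Row("TCF7L2", 0.48, 0.030, False, None),
    Table3Row("CDC123", 0.46, 0.000, False, 21),
    Table3Row("MTNR1B", 0.44, 0.000, False, 1),
    Table3Row("SLC30A8", 0.37, 0.055, False, 42),
    Table3Row("HDAC2", 0.21, 0.067, False, 9),
    Table3Row("KCNJ11", 0.00, 0.000, False, None),
)


def table3_fixture() -> tuple[Table3Row, ...]:
    """The packaged 19-gene benchmark table, in published order."""
    return _ROWS
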