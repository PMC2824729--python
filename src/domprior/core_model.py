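"""Shared domain types and input-file data model.

The prioritization pipeline consumes six plain-text inputs: a domain-domain
interaction edge list with per-edge confidence scores, a domain-to-protein
mapping, a gene/protein annotation table with chromosomal coordinates, a
BED-like file of disease-linked marker regions, the four evidence-class
catalogs, and (for benchmarking) positive/negative gene label lists.  This
module defines the in-memory records for those inputs, the parsers/writers
for each dialect, and the cross-reference validation that ties them together.

Coordinate convention: 1-based, closed intervals throughout (the Ensembl
convention); the BED-like region file is 0-based half-open on disk and is
converted at ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Protein",
    "DomainInteraction",
    "MarkerRegion",
    "DomainProteinMap",
    "InputBundle",
    "InputFormatError",
    "normalize_id",
    "region_overlap",
    "load_edges",
    "load_domain_protein_map",
    "load_annotation",
    "load_regions",
    "load_id_list",
    "load_pfam2go",
    "load_inputs",
    "write_edges",
    "write_domain_protein_map",
    "write_annotation",
    "write_regions",
    "write_id_list",
    "write_pfam2go",
]


class InputFormatError(ValueError):
    """Raised when an input file is malformed; message names file and line."""


def normalize_id(accession: str) -> str:
    """Normalize an identifier: strip whitespace, upper-case.

    Idempotent by construction; Pfam accessions and protein IDs share the
    same rule so a mapping file and a catalog file agree on keys.
    """
    return accession.strip().upper()


@dataclass(frozen=True)
class Protein:
    """A candidate protein/gene with optional chromosomal coordinates."""

    accession: str
    gene_symbol: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.has_coordinates():
            if self.start > self.end:  # type: ignore[operator]
                raise ValueError(
                    f"{self.accession}: start {self.start} > end {self.end}"
                )

    def has_coordinates(self) -> bool:
        return (
            self.chrom is not None
            and self.start is not None
            and self.end is not None
        )


@dataclass(frozen=True)
class DomainInteraction:
    """An undirected domain-domain interaction with a confidence score."""

    dom_a: str
    dom_b: str
    confidence: float

    def __post_init__(self) -> None:
        if self.confidence < 0:
            raise ValueError(
                f"negative confidence {self.confidence} for "
                f"{self.dom_a}-{self.dom_b}"
            )

    @property
    def key(self) -> tuple[str, str]:
        """Order-independent edge key."""
        return (min(self.dom_a, self.dom_b), max(self.dom_a, self.dom_b))


@dataclass(frozen=True)
class MarkerRegion:
    """A disease-linked chromosomal window (1-based, closed) around a marker."""

    marker_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError(
                f"region {self.marker_id}: end {self.end} must exceed start "
                f"{self.start}"
            )

    @classmethod
    def around_marker(
        cls, marker_id: str, chrom: str, position: int, half_width: int = 5_000_000
    ) -> "MarkerRegion":
        """Window of ``position`` ± ``half_width``, clipped at 1."""
        return cls(marker_id, chrom, max(1, position - half_width), position + half_width)


class DomainProteinMap:
    """Bidirectional domain ↔ protein mapping.

    Both directions are kept in sync: ``proteins_of(d)`` and ``domains_of(p)``
    always agree.  Iteration orders are sorted for deterministic output.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._dom_to_prot: dict[str, set[str]] = {}
        self._prot_to_dom: dict[str, set[str]] = {}
        for domain, protein in pairs:
            self.add(domain, protein)

    def add(self, domain: str, protein: str) -> None:
        domain = normalize_id(domain)
        protein = normalize_id(protein)
        self._dom_to_prot.setdefault(domain, set()).add(protein)
        self._prot_to_dom.setdefault(protein, set()).add(domain)

    def proteins_of(self, domain: str) -> frozenset[str]:
        return frozenset(self._dom_to_prot.get(normalize_id(domain), ()))

    def domains_of(self, protein: str) -> frozenset[str]:
        return frozenset(self._prot_to_dom.get(normalize_id(protein), ()))

    @property
    def domains(self) -> frozenset[str]:
        return frozenset(self._dom_to_prot)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self._prot_to_dom)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(
            (d, p) for d, prots in self._dom_to_prot.items() for p in prots
        )

    def __len__(self) -> int:
        return sum(len(v) for v in self._dom_to_prot.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DomainProteinMap):
            return NotImplemented
        return self._dom_to_prot == other._dom_to_prot


def region_overlap(
    protein: Protein, regions: Sequence[MarkerRegion]
) -> bool:
    """True iff the protein interval intersects any region on its chromosome.

    Closed-interval intersection: a single shared boundary base counts.
    Proteins without coordinates are unlocatable and score as non-overlap
    (logged once per call).
    """
    if not protein.has_coordinates():
        logger.warning(
            "protein %s has no coordinates; treated as non-overlapping",
            protein.accession,
        )
        return False
    for r in regions:
        if (
            r.chrom == protein.chrom
            and protein.start <= r.end  # type: ignore[operator]
            and r.start <= protein.end  # type: ignore[operator]
        ):
            return True
    return False


# ---------------------------------------------------------------------------
# Parsers.  All dialects are TSV with optional '#'-prefixed header/comment
# lines; malformed rows raise InputFormatError naming the file and line.
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _require_nonempty(path: str | Path, rows: list, what: str) -> None:
    if not rows:
        raise InputFormatError(f"{path}: no {what} records found (empty file?)")


def load_edges(path: str | Path) -> list[DomainInteraction]:
    """Parse `domain_a  domain_b  confidence` TSV.

    Self-interactions are dropped here (with a logged count): the local
    clustering coefficient downstream is undefined for self-loops.  Duplicate
    edges, including reversed order, are merged keeping the maximum
    confidence (the network is undirected).
    """
    best: dict[tuple[str, str], DomainInteraction] = {}
    n_self = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise InputFormatError(
                f"{path}:{lineno}: expected 3 columns "
                f"(domain_a, domain_b, confidence), got {len(fields)}"
            )
        a, b = normalize_id(fields[0]), normalize_id(fields[1])
        try:
            conf = float(fields[2])
        except ValueError as exc:
            raise InputFormatError(
                f"{path}:{lineno}: confidence {fields[2]!r} is not a number"
            ) from exc
        if not a or not b:
            raise InputFormatError(f"{path}:{lineno}: empty domain identifier")
        if a == b:
            n_self += 1
            continue
        edge = DomainInteraction(a, b, conf)
        prev = best.get(edge.key)
        if prev is None or conf > prev.confidence:
            best[edge.key] = edge
    if n_self:
        logger.info("%s: dropped %d self-interactions", path, n_self)
    edges = [best[k] for k in sorted(best)]
    _require_nonempty(path, edges, "interaction")
    return edges


def load_domain_protein_map(path: str | Path) -> DomainProteinMap:
    """Parse `domain  protein` TSV (one pair per line)."""
    dp = DomainProteinMap()
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise InputFormatError(
                f"{path}:{lineno}: expected 2 columns (domain, protein)"
            )
        dp.add(fields[0], fields[1])
    _require_nonempty(path, dp.pairs(), "domain-protein")
    return dp


def load_annotation(path: str | Path) -> dict[str, Protein]:
    """Parse `protein  gene_symbol  chrom  start  end` TSV.

    Coordinates may be missing ('-' or empty); such proteins are kept but
    flagged unlocatable for region overlap.
    """
    out: dict[str, Protein] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 5:
            raise InputFormatError(
                f"{path}:{lineno}: expected 5 columns "
                "(protein, gene_symbol, chrom, start, end)"
            )
        acc = normalize_id(fields[0])
        symbol = fields[1].strip()
        symbol = None if symbol in ("", "-") else symbol
        chrom = fields[2].strip()
        if chrom in ("", "-", "."):
            out[acc] = Protein(acc, symbol)
            continue
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise InputFormatError(
                f"{path}:{lineno}: non-integer coordinates "
                f"{fields[3]!r}/{fields[4]!r}"
            ) from exc
        try:
            out[acc] = Protein(acc, symbol, chrom, start, end)
        except ValueError as exc:
            raise InputFormatError(f"{path}:{lineno}: {exc}") from exc
    _require_nonempty(path, list(out), "annotation")
    return out


def load_regions(path: str | Path) -> list[MarkerRegion]:
    """Parse BED-like `chrom  start  end  marker_id` (0-based half-open).

    Converted to the internal 1-based closed convention: start+1, end.
    """
    regions = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise InputFormatError(
                f"{path}:{lineno}: expected 4 columns (chrom, start, end, name)"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise InputFormatError(
                f"{path}:{lineno}: non-integer BED coordinates"
            ) from exc
        try:
            regions.append(
                MarkerRegion(fields[3].strip(), fields[0].strip(), start + 1, end)
            )
        except ValueError as exc:
            raise InputFormatError(f"{path}:{lineno}: {exc}") from exc
    _require_nonempty(path, regions, "region")
    return regions


def load_id_list(path: str | Path) -> set[str]:
    """Parse a plain one-ID-per-line list (classes a and d, benchmark labels)."""
    ids = set()
    for _lineno, fields in _data_lines(path):
        ids.add(normalize_id(fields[0]))
    _require_nonempty(path, sorted(ids), "identifier")
    return ids


def load_pfam2go(path: str | Path) -> dict[str, frozenset[str]]:
    """Parse Pfam2GO lines: ``Pfam:PFxxxxx name > GO:term ; GO:0000000``.

    Returns domain accession → set of GO IDs.  Lines starting with '!' (the
    upstream comment convention) or '#' are skipped.
    """
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("!", "#")):
                continue
            if ">" not in line or ";" not in line or not line.startswith("Pfam:"):
                raise InputFormatError(
                    f"{path}:{lineno}: not a Pfam2GO line: {line!r}"
                )
            left, _, right = line.partition(">")
            pfam_token = left.split()[0]  # "Pfam:PF00001"
            accession = normalize_id(pfam_token.split(":", 1)[1])
            go_id = normalize_id(right.rsplit(";", 1)[1])
            if not go_id.startswith("GO:"):
                raise InputFormatError(
                    f"{path}:{lineno}: trailing field {go_id!r} is not a GO ID"
                )
            mapping.setdefault(accession, set()).add(go_id)
    _require_nonempty(path, sorted(mapping), "Pfam2GO")
    return {k: frozenset(v) for k, v in mapping.items()}


# ---------------------------------------------------------------------------
# Writers (mirror dialects exactly; used by the simulator and for round-trips)
# ---------------------------------------------------------------------------


def write_edges(edges: Iterable[DomainInteraction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#domain_a\tdomain_b\tconfidence\n")
        for e in sorted(edges, key=lambda e: e.key):
            fh.write(f"{e.dom_a}\t{e.dom_b}\t{e.confidence:g}\n")


def write_domain_protein_map(dp: DomainProteinMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#domain\tprotein\n")
        for d, p in dp.pairs():
            fh.write(f"{d}\t{p}\n")


def write_annotation(proteins: Mapping[str, Protein], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein\tgene_symbol\tchrom\tstart\tend\n")
        for acc in sorted(proteins):
            p = proteins[acc]
            if p.has_coordinates():
                fh.write(
                    f"{p.accession}\t{p.gene_symbol or '-'}\t{p.chrom}"
                    f"\t{p.start}\t{p.end}\n"
                )
            else:
                fh.write(f"{p.accession}\t{p.gene_symbol or '-'}\t-\t-\t-\n")


def write_regions(regions: Iterable[MarkerRegion], path: str | Path) -> None:
    """Write BED-like 0-based half-open rows (inverse of :func:`load_regions`)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.marker_id}\n")


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in sorted(set(ids)):
            fh.write(f"{i}\n")


def write_pfam2go(mapping: Mapping[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for domain in sorted(mapping):
            for go in sorted(mapping[domain]):
                fh.write(f"Pfam:{domain} {domain} > GO:process ; {go}\n")


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


@dataclass
class InputBundle:
    """All validated inputs for one prioritization run."""

    edges: list[DomainInteraction]
    dp_map: DomainProteinMap
    annotation: dict[str, Protein]
    regions: list[MarkerRegion]
    class_a_domains: set[str] = field(default_factory=set)
    class_b_processes: set[str] = field(default_factory=set)
    pfam2go: dict[str, frozenset[str]] = field(default_factory=dict)
    class_d_proteins: set[str] = field(default_factory=set)
    validation_report: dict = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InputBundle):
            return NotImplemented
        return (
            self.edges == other.edges
            and self.dp_map == other.dp_map
            and self.annotation == other.annotation
            and self.regions == other.regions
            and self.class_a_domains == other.class_a_domains
            and self.class_b_processes == other.class_b_processes
            and self.pfam2go == other.pfam2go
            and self.class_d_proteins == other.class_d_proteins
        )


def load_inputs(
    edges: str | Path,
    domain_protein_map: str | Path,
    annotation: str | Path,
    regions: str | Path | None = None,
    class_a: str | Path | None = None,
    class_b_processes: str | Path | None = None,
    pfam2go: str | Path | None = None,
    class_d: str | Path | None = None,
) -> InputBundle:
    """Load and cross-validate the input files for a run.

    Unknown identifiers (e.g. a mapped protein missing from the annotation
    table) are logged in the validation report, not fatal: public mapping and
    catalog files routinely cover a larger universe than one run's candidates.
    """
    bundle = InputBundle(
        edges=load_edges(edges),
        dp_map=load_domain_protein_map(domain_protein_map),
        annotation=load_annotation(annotation),
        regions=load_regions(regions) if regions else [],
        class_a_domains=load_id_list(class_a) if class_a else set(),
        class_b_processes=load_id_list(class_b_processes)
        if class_b_processes
        else set(),
        pfam2go=dict(load_pfam2go(pfam2go)) if pfam2go else {},
        class_d_proteins=load_id_list(class_d) if class_d else set(),
    )

    edge_domains = {d for e in bundle.edges for d in (e.dom_a, e.dom_b)}
    mapped_proteins = bundle.dp_map.proteins
    annotated = set(bundle.annotation)
    report = {
        "n_edges": len(bundle.edges),
        "n_mapped_pairs": len(bundle.dp_map),
        "n_annotated_proteins": len(annotated),
        "n_regions": len(bundle.regions),
        "unannotated_mapped_proteins": sorted(mapped_proteins - annotated),
        "edge_domains_without_proteins": sorted(
            edge_domains - bundle.dp_map.domains
        ),
    }
    for key in ("unannotated_mapped_proteins", "edge_domains_without_proteins"):
        if report[key]:
            logger.info("%s: %d identifiers", key, len(report[key]))
    bundle.validation_report = report
    return bundle


def annotation_frame(proteins: Mapping[str, Protein]) -> pd.DataFrame:
    """Annotation table as a DataFrame (protein-indexed), for reporting."""
    rows = [
        {
            "protein": p.accession,
            "gene_symbol": p.gene_symbol,
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
        }
        for p in proteins.values()
    ]
    return pd.DataFrame(rows).set_index("protein").sort_index()
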