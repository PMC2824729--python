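"""Synthetic input worlds with planted disease-like candidates.

The generator emits, on disk and in memory, the complete six-part input a
prioritization run needs: a domain interaction edge list with confidence
scores, a domain→protein map, a coordinate-bearing annotation table,
marker regions, the four evidence-class catalogs, and benchmark label
lists.  Structure emulated:

* a heterogeneous-degree random background graph of Pfam-style domains
  (configuration-model flavor, target mean degree 6.5 as observed in
  curated domain interaction networks);
* confidence scores drawn uniformly on (0, 50] so roughly 20% fall below
  the standard cutoff of 10 and the confidence filter is exercised;
* ``n_planted`` candidate proteins whose (unique) parent domains are wired
  to an evidence pool of partner domains that are members of all four
  classes, while background partners carry no class membership — so a
  correct implementation must rank the planted candidates at the top;
* class totals defaulting to the published catalog sizes (60, 15, 64,
  1746) scaled down about five-fold for desk-scale runs, padded with
  catalog-only dummy identifiers where the world itself has fewer members.

Identical ``(config, seed)`` produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import (
    DomainInteraction,
    DomainProteinMap,
    InputBundle,
    MarkerRegion,
    Protein,
    region_overlap,
    write_annotation,
    write_domain_protein_map,
    write_edges,
    write_id_list,
    write_pfam2go,
    write_regions,
)

__all__ = ["WorldConfig", "World", "generate_world"]


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of a synthetic world; defaults are the desk-scale conditions."""

    n_domains: int = 300
    n_proteins: int = 500
    n_markers: int = 13
    mean_degree: float = 6.5
    confidence_max: float = 50.0  # uniform(0, max): ~20% below cutoff 10
    t_a: int = 12
    t_b: int = 3
    t_c: int = 13  # equals n_markers (one region per marker)
    t_d: int = 349
    n_planted: int = 10
    evidence_pool_size: int = 8
    partners_per_planted: int = 4
    n_negatives: int = 100
    chrom_length: int = 50_000_000
    n_chromosomes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_proteins:
            raise ValueError("more planted candidates than proteins")
        if self.n_planted and self.evidence_pool_size < self.partners_per_planted:
            raise ValueError("evidence pool smaller than partners per planted")
        if self.n_planted + self.evidence_pool_size >= self.n_domains:
            raise ValueError("too few domains for the planted structure")
        for name in ("n_domains", "n_proteins", "n_markers", "t_a", "t_b", "t_c", "t_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class World:
    """A generated world: file paths plus the in-memory ground truth."""

    config: WorldConfig
    bundle: InputBundle
    planted_proteins: list[str]
    positives: list[str]
    negatives: list[str]
    paths: dict[str, Path] = field(default_factory=dict)


def _domain_id(i: int) -> str:
    return f"PF{i + 1:05d}"


def _protein_id(i: int) -> str:
    return f"SP{i + 1:05d}"


def generate_world(
    config: WorldConfig, outdir: str | Path | None = None
) -> World:
    """Generate a world; write the input files when ``outdir`` is given."""
    rng = np.random.default_rng(config.seed)
    domains = [_domain_id(i) for i in range(config.n_domains)]
    proteins = [_protein_id(i) for i in range(config.n_proteins)]

    planted_parents = domains[: config.n_planted]
    pool = domains[config.n_planted : config.n_planted + config.evidence_pool_size]
    background = domains[config.n_planted + config.evidence_pool_size :]

    # --- background graph: heterogeneous expected degrees, mean 6.5 -------
    weights = rng.gamma(shape=2.0, scale=config.mean_degree / 2.0, size=len(background))
    p_scale = weights.sum()
    edge_set: set[tuple[str, str]] = set()
    for i in range(len(background)):
        for j in range(i + 1, len(background)):
            p = min(1.0, weights[i] * weights[j] / p_scale)
            if rng.random() < p:
                edge_set.add((background[i], background[j]))
    # planted parents also get a little background wiring (class-free)
    for parent in planted_parents:
        for other in rng.choice(len(background), size=2, replace=False):
            edge_set.add(tuple(sorted((parent, background[other]))))
    # evidence pool connects ONLY to planted parents
    for parent in planted_parents:
        picks = rng.choice(
            config.evidence_pool_size,
            size=config.partners_per_planted,
            replace=False,
        )
        for k in picks:
            edge_set.add(tuple(sorted((parent, pool[k]))))

    # confidence scores: uniform(0, confidence_max); planted-structure edges
    # are kept above the cutoff so the signal survives filtering
    edges = []
    structural = {
        tuple(sorted((p, q))) for p in planted_parents for q in pool
    }
    for a, b in sorted(edge_set):
        if (a, b) in structural:
            conf = 10.0 + rng.random() * (config.confidence_max - 10.0)
        else:
            conf = rng.random() * config.confidence_max
        edges.append(DomainInteraction(a, b, round(float(conf), 3)))

    # --- markers and regions ---------------------------------------------
    regions = []
    for m in range(config.n_markers):
        chrom = f"CHR{m % config.n_chromosomes + 1}"
        pos = int(rng.integers(6_000_000, config.chrom_length - 6_000_000))
        regions.append(
            MarkerRegion.around_marker(f"MRK{m + 1:03d}", chrom, pos)
        )

    # --- proteins: planted carry their parent domain; carriers harbor the
    # evidence pool and live inside regions; background proteins get 1-3
    # background domains and coordinates outside every region --------------
    dp = DomainProteinMap()
    annotation: dict[str, Protein] = {}
    planted_proteins = proteins[: config.n_planted]
    carrier_proteins = [
        f"CR{i + 1:05d}" for i in range(config.evidence_pool_size)
    ]

    def random_locus(inside_region: MarkerRegion | None) -> tuple[str, int, int]:
        if inside_region is not None:
            start = int(
                rng.integers(inside_region.start, inside_region.end - 10_000)
            )
            return inside_region.chrom, start, start + int(rng.integers(1_000, 10_000))
        # rejection-sample a locus overlapping no region
        while True:
            chrom = f"CHR{int(rng.integers(0, config.n_chromosomes)) + 1}"
            start = int(rng.integers(1, config.chrom_length))
            end = start + int(rng.integers(1_000, 10_000))
            probe = Protein("X", None, chrom, start, end)
            if not region_overlap(probe, regions):
                return chrom, start, end

    for i, acc in enumerate(planted_proteins):
        dp.add(planted_parents[i], acc)
        chrom, s, e = random_locus(None)
        annotation[acc] = Protein(acc, f"GENE{i + 1}", chrom, s, e)
    for i, acc in enumerate(carrier_proteins):
        dp.add(pool[i], acc)
        region = regions[int(rng.integers(0, len(regions)))]
        chrom, s, e = random_locus(region)
        annotation[acc] = Protein(acc, f"CARRIER{i + 1}", chrom, s, e)
    for i, acc in enumerate(proteins[config.n_planted :], start=config.n_planted):
        k = int(rng.integers(1, 4))
        for d in rng.choice(len(background), size=k, replace=False):
            dp.add(background[d], acc)
        # ~5% of background genes sit inside a linked region, giving the
        # evidence classes a realistic low-level background signal
        if rng.random() < 0.05:
            region = regions[int(rng.integers(0, len(regions)))]
            chrom, s, e = random_locus(region)
        else:
            chrom, s, e = random_locus(None)
        annotation[acc] = Protein(acc, f"GENE{i + 1}", chrom, s, e)

    # --- class catalogs: planted evidence pool plus a sprinkling of real
    # background members; dummy catalog-only IDs pad out the totals ---------
    def pad(members: list[str], total: int, prefix: str) -> list[str]:
        extra = [f"{prefix}{i + 1:05d}" for i in range(max(0, total - len(members)))]
        return (members + extra)[:total]

    n_bg_a = min(3, max(0, config.t_a - len(pool)), len(background))
    bg_a = [
        background[int(i)]
        for i in rng.choice(len(background), size=n_bg_a, replace=False)
    ]
    class_a = pad(list(pool) + bg_a, config.t_a, "PA")
    processes = [f"GO:{7000000 + i}" for i in range(config.t_b)]
    pfam2go = {
        d: frozenset({processes[i % config.t_b]}) for i, d in enumerate(pool)
    }
    bg_pool = proteins[config.n_planted + config.n_negatives :]
    n_bg_d = min(30, max(0, config.t_d - len(carrier_proteins)), len(bg_pool))
    bg_d = [
        bg_pool[int(i)]
        for i in rng.choice(len(bg_pool), size=n_bg_d, replace=False)
    ]
    class_d = pad(list(carrier_proteins) + bg_d, config.t_d, "OMIM")

    bundle = InputBundle(
        edges=edges,
        dp_map=dp,
        annotation=annotation,
        regions=regions,
        class_a_domains=set(class_a),
        class_b_processes=set(processes),
        pfam2go=pfam2go,
        class_d_proteins=set(class_d),
    )

    negatives = [
        p for p in proteins[config.n_planted :]
    ][: config.n_negatives]
    world = World(
        config=config,
        bundle=bundle,
        planted_proteins=list(planted_proteins),
        positives=list(planted_proteins),
        negatives=negatives,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "edges": outdir / "edges.tsv",
            "domain_protein_map": outdir / "dp_map.tsv",
            "annotation": outdir / "annotation.tsv",
            "regions": outdir / "regions.bed",
            "class_a": outdir / "class_a_domains.txt",
            "class_b_processes": outdir / "class_b_processes.txt",
            "pfam2go": outdir / "pfam2go.txt",
            "class_d": outdir / "class_d_proteins.txt",
            "positives": outdir / "benchmark_positives.txt",
            "negatives": outdir / "benchmark_negatives.txt",
        }
        write_edges(edges, paths["edges"])
        write_domain_protein_map(dp, paths["domain_protein_map"])
        write_annotation(annotation, paths["annotation"])
        write_regions(regions, paths["regions"])
        write_id_list(class_a, paths["class_a"])
        write_id_list(processes, paths["class_b_processes"])
        write_pfam2go(pfam2go, paths["pfam2go"])
        write_id_list(class_d, paths["class_d"])
        write_id_list(world.positives, paths["positives"])
        write_id_list(world.negatives, paths["negatives"])
        world.paths = paths
    return world
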