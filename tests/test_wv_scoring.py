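"""Partner scoring, weight-value aggregation, normalization, assignment."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domprior.core_model import DomainProteinMap, MarkerRegion, Protein
from domprior.wv_scoring import (
    ClassCatalog,
    WvScore,
    assign_protein_scores,
    normalize_scores,
    score_candidates,
    score_partner,
    weight_value,
)

PAPER_TOTALS = (60, 15, 64, 1746)


def make_catalog(
    class_a=(),
    class_b=(),
    pfam2go=None,
    regions=(),
    class_d=(),
    totals=PAPER_TOTALS,
):
    return ClassCatalog.from_members(
        class_a, class_b, pfam2go or {}, list(regions), class_d, totals=totals
    )


def test_partner_in_class_a_only():
    cat = make_catalog(class_a=["PF00001"])
    ps = score_partner("PF00001", cat, DomainProteinMap(), {})
    assert (ps.d_ja, ps.d_jb, ps.p_jc, ps.p_jd) == (1, 0, 0, 0)
    assert ps.a_j == pytest.approx(1 / 60)
    assert ps.b_j == ps.c_j == ps.d_j == 0.0


def test_partner_absent_everywhere_scores_zero():
    ps = score_partner("PF09999", make_catalog(), DomainProteinMap(), {})
    assert ps.total == 0.0


def test_class_b_via_pfam2go():
    cat = make_catalog(
        class_b=["GO:0008152"],
        pfam2go={"PF00002": frozenset({"GO:0008152", "GO:0001"})},
    )
    assert score_partner("PF00002", cat, DomainProteinMap(), {}).d_jb == 1
    assert score_partner("PF00003", cat, DomainProteinMap(), {}).d_jb == 0


def test_classes_c_and_d_fire_if_any_harboring_protein_qualifies():
    dp = DomainProteinMap([("PF1", "P1"), ("PF1", "P2")])
    ann = {
        "P1": Protein("P1", None, "chr1", 50_000, 60_000),  # outside region
        "P2": Protein("P2", None, "chr2", 100, 200),  # inside region
    }
    regions = [MarkerRegion("M1", "chr2", 1, 10_000)]
    cat = make_catalog(regions=regions, class_d=["P1"])
    ps = score_partner("PF1", cat, dp, ann)
    assert ps.p_jc == 1  # P2 overlaps
    assert ps.p_jd == 1  # P1 is a disease protein
    assert ps.c_j == pytest.approx(1 / 64)
    assert ps.d_j == pytest.approx(1 / 1746)


def test_partner_scores_match_set_membership_oracle():
    """50 random partners against random catalogs, component by component."""
    rng = np.random.default_rng(21)
    domains = [f"PF{i:05d}" for i in range(60)]
    proteins = [f"P{i}" for i in range(80)]
    dp = DomainProteinMap()
    for d in domains:
        for p in rng.choice(proteins, size=rng.integers(1, 4), replace=False):
            dp.add(d, str(p))
    ann = {
        p: Protein(p, None, f"chr{rng.integers(1, 4)}",
                   int(s := rng.integers(1, 9_000)), int(s + rng.integers(1, 500)))
        for p in proteins
    }
    regions = [MarkerRegion("M", "chr1", 1, 4_000)]
    class_a = set(rng.choice(domains, size=10, replace=False))
    class_d = {str(p) for p in rng.choice(proteins, size=15, replace=False)}
    procs = {"GO:1", "GO:2"}
    pfam2go = {
        d: frozenset({"GO:1"} if rng.random() < 0.5 else {"GO:9"})
        for d in rng.choice(domains, size=20, replace=False)
    }
    cat = make_catalog(class_a, procs, pfam2go, regions, class_d)
    for d in rng.choice(domains, size=50):
        ps = score_partner(str(d), cat, dp, ann)
        # independent set-membership re-derivation
        assert ps.d_ja == int(d in class_a)
        assert ps.d_jb == int(bool(pfam2go.get(d, frozenset()) & procs))
        harb = dp.proteins_of(str(d))
        expect_c = any(
            ann[p].chrom == "chr1" and ann[p].start <= 4000 and ann[p].end >= 1
            for p in harb
        )
        assert ps.p_jc == int(expect_c)
        assert ps.p_jd == int(bool(harb & class_d))


def test_count_mode_counts_qualifying_harboring_proteins():
    """cd_mode='count' replaces the binary OR by per-protein counts for
    classes c and d; classes a and b stay binary."""
    dp = DomainProteinMap([("PF1", "P1"), ("PF1", "P2"), ("PF1", "P3")])
    ann = {
        "P1": Protein("P1", None, "chr1", 10, 20),
        "P2": Protein("P2", None, "chr1", 30, 40),
        "P3": Protein("P3", None, "chr9", 10, 20),
    }
    cat = make_catalog(
        regions=[MarkerRegion("M", "chr1", 1, 100)], class_d=["P1", "P3"]
    )
    binary = score_partner("PF1", cat, dp, ann)
    counted = score_partner("PF1", cat, dp, ann, cd_mode="count")
    assert (binary.p_jc, binary.p_jd) == (1, 1)
    assert (counted.p_jc, counted.p_jd) == (2, 2)
    assert counted.c_j == pytest.approx(2 / 64)
    with pytest.raises(ValueError):
        score_partner("PF1", cat, dp, ann, cd_mode="bogus")


def test_weight_value_hand_summed_fractions():
    """One partner hitting all four classes: raw equals the exact fraction
    1/60 + 1/15 + 1/64 + 1/1746."""
    dp = DomainProteinMap([("PF2", "P1")])
    ann = {"P1": Protein("P1", None, "chr1", 10, 20)}
    cat = make_catalog(
        class_a=["PF2"],
        class_b=["GO:1"],
        pfam2go={"PF2": frozenset({"GO:1"})},
        regions=[MarkerRegion("M", "chr1", 1, 100)],
        class_d=["P1"],
    )
    g = nx.Graph([("PF1", "PF2")])
    expected = Fraction(1, 60) + Fraction(1, 15) + Fraction(1, 64) + Fraction(1, 1746)
    score = weight_value("PF1", g, cat, dp, ann)
    assert score.raw == pytest.approx(float(expected))
    assert float(expected) == pytest.approx(0.09956, abs=5e-5)
    assert score.n_partners == 1


def test_zero_partner_parent_and_zero_partners_sum():
    g = nx.Graph()
    g.add_node("PF1")
    cat = make_catalog()
    assert weight_value("PF1", g, cat, DomainProteinMap(), {}).raw == 0.0
    g2 = nx.Graph([("PF1", "PF2"), ("PF1", "PF3")])
    s = weight_value("PF1", g2, cat, DomainProteinMap(), {})
    assert s.raw == 0.0 and s.n_partners == 2


def test_mean_aggregation_divides_by_n():
    dp = DomainProteinMap([("PF2", "P1")])
    cat = make_catalog(class_a=["PF2"])
    g = nx.Graph([("PF1", "PF2"), ("PF1", "PF3")])
    s_sum = weight_value("PF1", g, cat, dp, {}, aggregation="sum")
    s_mean = weight_value("PF1", g, cat, dp, {}, aggregation="mean")
    assert s_mean.raw == pytest.approx(s_sum.raw / 2)


def test_adding_scoring_partner_is_monotone():
    """Adding a partner with a positive component never decreases raw Wv."""
    cat = make_catalog(class_a=["PF2", "PF3"])
    g = nx.Graph([("PF1", "PF2")])
    before = weight_value("PF1", g, cat, DomainProteinMap(), {}).raw
    g.add_edge("PF1", "PF3")
    after = weight_value("PF1", g, cat, DomainProteinMap(), {}).raw
    assert after >= before
    assert after == pytest.approx(before + 1 / 60)


@given(
    st.lists(
        st.floats(min_value=0, max_value=100, allow_nan=False), min_size=2, max_size=50
    )
)
@settings(max_examples=100, deadline=None)
def test_minmax_normalization_properties(raws):
    scores = normalize_scores([WvScore(f"D{i}", 1, r) for i, r in enumerate(raws)])
    values = [s.normalized for s in scores]
    assert all(0.0 <= v <= 1.0 for v in values)
    if max(raws) > min(raws):
        assert max(values) == pytest.approx(1.0)
        assert min(values) == pytest.approx(0.0)
        # order preserved
        order_raw = np.argsort(raws, kind="stable")
        order_norm = np.argsort(values, kind="stable")
        assert list(order_raw) == list(order_norm)
    else:
        assert values == [0.0] * len(values)


def test_minmax_simple_rescale_and_affine_invariance():
    scores = normalize_scores([WvScore("A", 1, 0), WvScore("B", 1, 5), WvScore("C", 1, 10)])
    assert [s.normalized for s in scores] == pytest.approx([0.0, 0.5, 1.0])
    rng = np.random.default_rng(5)
    raws = rng.random(30) * 10
    base = [s.normalized for s in normalize_scores([WvScore(f"D{i}", 1, r) for i, r in enumerate(raws)])]
    shifted = [
        s.normalized
        for s in normalize_scores(
            [WvScore(f"D{i}", 1, 3.0 * r + 7.0) for i, r in enumerate(raws)]
        )
    ]
    assert shifted == pytest.approx(base)


def test_all_equal_raw_normalizes_to_zero_with_warning(caplog):
    scores = normalize_scores([WvScore("A", 1, 2.0), WvScore("B", 1, 2.0)])
    assert [s.normalized for s in scores] == [0.0, 0.0]


def test_protein_gets_max_domain_wv_and_strict_hwe_threshold():
    dp = DomainProteinMap([("PF1", "P1"), ("PF2", "P1"), ("PF3", "P2"), ("PF4", "P3")])
    ann = {p: Protein(p, None) for p in ("P1", "P2", "P3")}
    g = nx.Graph()
    g.add_nodes_from(["PF1", "PF2", "PF3", "PF4"])
    wv = {
        "PF1": WvScore("PF1", 2, 1.0, normalized=0.3),
        "PF2": WvScore("PF2", 3, 2.0, normalized=0.7),
        "PF3": WvScore("PF3", 1, 0.5, normalized=0.51),
        "PF4": WvScore("PF4", 1, 0.4, normalized=0.5),
    }
    cands, excluded = assign_protein_scores(ann, dp, wv, g)
    by_protein = {c.protein: c for c in cands}
    assert by_protein["P1"].wv == 0.7
    assert by_protein["P1"].best_domain == "PF2"
    assert by_protein["P2"].is_hwe  # 0.51 > 0.5
    assert not by_protein["P3"].is_hwe  # exactly 0.5 is not an HWE
    assert excluded == []


def test_protein_without_domains_is_excluded():
    ann = {"P1": Protein("P1", None), "P2": Protein("P2", None)}
    dp = DomainProteinMap([("PF1", "P1")])
    g = nx.Graph()
    g.add_node("PF1")
    cands, excluded = assign_protein_scores(
        ann, dp, {"PF1": WvScore("PF1", 0, 0.0, normalized=0.0)}, g
    )
    assert [c.protein for c in cands] == ["P1"]
    assert excluded == ["P2"]


def test_tie_breaks_toward_lower_ci_then_lexicographic():
    dp = DomainProteinMap([("PFA", "P1"), ("PFB", "P1"), ("PFC", "P1")])
    ann = {"P1": Protein("P1", None)}
    # PFB sits in a triangle (ci=1), PFA and PFC are isolated (ci=0)
    g = nx.Graph([("PFB", "X"), ("PFB", "Y"), ("X", "Y")])
    g.add_nodes_from(["PFA", "PFC"])
    wv = {d: WvScore(d, 1, 1.0, normalized=0.9) for d in ("PFA", "PFB", "PFC")}
    cands, _ = assign_protein_scores(ann, dp, wv, g)
    assert cands[0].best_domain == "PFA"  # ci 0 beats ci 1; PFA < PFC


def test_planted_parents_outscore_background(small_world):
    """Every planted candidate's normalized Wv exceeds every background
    candidate's in a planted synthetic world."""
    b = small_world.bundle
    from domprior.domain_network import build_network

    g = build_network(b.edges, 10.0, extra_nodes=b.dp_map.domains)
    cat = make_catalog(
        b.class_a_domains, b.class_b_processes, b.pfam2go, b.regions,
        b.class_d_proteins, totals=None,
    )
    cands, _ = score_candidates(g, cat, b.dp_map, b.annotation)
    planted = {c.wv for c in cands if c.protein in set(small_world.planted_proteins)}
    background = {
        c.wv
        for c in cands
        if c.protein not in set(small_world.planted_proteins)
        and not c.protein.startswith("CR")
    }
    assert min(planted) > max(background)
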