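"""Shannon, Venn partitions, rank abundance, rarefaction, activity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brinepop.community_ecology import (
    call_active,
    fit_rarefaction_tail,
    presence_matrix,
    rank_abundance,
    rarefy,
    shannon,
    shared_unique,
)
from brinepop.io_formats import AlignmentRecord, Contig
from brinepop.synthetic_community import (
    CommunitySpec,
    generate_genomes,
    simulate_reads,
    simulate_transcriptome,
)


def test_shannon_closed_forms():
    assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))
    assert shannon([5.0]) == 0.0
    assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)
    assert shannon([1, 1], base=2) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        shannon([0.0, 0.0])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(0.01, 100), min_size=2, max_size=20))
def test_shannon_maximal_at_uniform_and_zero_padding_invariant(abunds):
    h = shannon(abunds)
    assert h <= np.log(len(abunds)) + 1e-9
    assert shannon(list(abunds) + [0.0]) == pytest.approx(h)


def _presence(d):
    return pd.DataFrame(d)


def test_shared_unique_toy_matrix():
    pres = _presence(
        {"A": [True, True, True, False, False],
         "B": [True, True, False, True, True]}
    )
    pres.index = [f"v{i+1}" for i in range(5)]
    df = shared_unique(pres, ["A", "B"]).set_index("region")
    assert df.loc["A&B", "n_votus"] == 2
    assert df.loc["A", "n_votus"] == 1
    assert df.loc["B", "n_votus"] == 2


def test_shared_unique_self_and_disjoint():
    pres = _presence({"A": [True, True], "B": [True, True]})
    df = shared_unique(pres, ["A", "B"]).set_index("region")
    assert df.loc["A&B", "n_votus"] == 2
    assert df.loc["A", "n_votus"] == 0
    disjoint = _presence({"A": [True, False], "B": [False, True]})
    df2 = shared_unique(disjoint, ["A", "B"]).set_index("region")
    assert df2.loc["A&B", "n_votus"] == 0
    with pytest.raises(ValueError):
        shared_unique(pres, ["A", "missing"])


def test_venn_regions_sum_to_union():
    rng = np.random.default_rng(3)
    pres = pd.DataFrame(
        rng.random((30, 3)) < 0.5, columns=["A", "B", "C"],
        index=[f"v{i}" for i in range(30)],
    )
    df = shared_unique(pres, ["A", "B", "C"])
    union = int(pres.any(axis=1).sum())
    assert df["n_votus"].sum() == union


def test_shared_unique_reports_region_abundance_share():
    pres = _presence({"A": [True, True, False], "B": [True, False, True]})
    pres.index = ["v1", "v2", "v3"]
    rel = pd.DataFrame(
        {"A": [0.6, 0.4, 0.0], "B": [0.9, 0.0, 0.1]}, index=pres.index
    )
    df = shared_unique(pres, ["A", "B"], rel).set_index("region")
    assert df.loc["A&B", "abundance_A"] == pytest.approx(0.6)
    assert df.loc["A&B", "abundance_B"] == pytest.approx(0.9)
    assert df.loc["B", "abundance_B"] == pytest.approx(0.1)


def test_rank_abundance_order_and_exclusives():
    rel = pd.DataFrame(
        {"SW": [3.0, 1.0, 2.0, 0.0], "SB": [0.1, 0.2, 0.3, 0.7]},
        index=["v1", "v2", "v3", "v4"],
    )
    out = rank_abundance(rel, "SW", "SB")
    assert list(out.index) == ["v1", "v3", "v2", "v4"]
    assert out.loc["v4", "exclusive"]
    # ties break lexicographically
    rel2 = pd.DataFrame({"SW": [1.0, 1.0], "SB": [0.0, 0.0]}, index=["vb", "va"])
    assert list(rank_abundance(rel2, "SW", "SB").index) == ["va", "vb"]


def test_rarefaction_tail_fits():
    linear = [(d, 5e-6 * d) for d in (10**5, 2 * 10**5, 5 * 10**5, 10**6)]
    slope, pred = fit_rarefaction_tail(linear)
    assert pred == pytest.approx(5.0)
    flat = [(10**5, 40), (2 * 10**5, 40), (5 * 10**5, 40), (10**6, 40)]
    assert fit_rarefaction_tail(flat)[1] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        fit_rarefaction_tail(linear[:3])


def test_rarefy_detects_more_with_depth_and_bounds():
    spec = CommunitySpec(
        n_genomes=4, genome_len_range=(8000, 9000), depth_mean=20, seed=9
    )
    contigs, _genes = generate_genomes(spec)
    rng = np.random.default_rng(10)
    recs = []
    for c in contigs:
        _fq, r = simulate_reads([c.seq], [1.0], c, 20, 100, 0.0, seed=int(rng.integers(2**31)))
        recs.extend(r)
    depths = [200, 1000, 3000, len(recs)]
    curve = rarefy(recs, contigs, depths, seed=1)
    counts = [v for _d, v in curve.points]
    assert counts[-1] == 4  # all genomes detected at full depth
    assert counts[0] <= counts[-1]
    assert curve.prediction >= 0 or counts[-1] == 4
    with pytest.raises(ValueError):
        rarefy(recs, contigs, [1, 2, 3], seed=1)


def _transcript_recs(contig, covered_frac):
    """Perfect tiled reads covering the first covered_frac of the contig."""
    L = len(contig)
    span = int(L * covered_frac)
    recs = []
    for i, start in enumerate(range(0, span - 99, 100)):
        recs.append(
            AlignmentRecord(
                f"t{i}", contig.id, start, [("M", 100)], 0, 100,
                seq=contig.seq[start : start + 100],
            )
        )
    return recs


def test_call_active_flips_at_half_breadth():
    contig = Contig("v1", "ACGT" * 2500)  # 10 kb
    at_half = call_active(_transcript_recs(contig, 0.5), [contig])
    assert bool(at_half.loc[0, "active"])
    below = call_active(_transcript_recs(contig, 0.49), [contig])
    assert not bool(below.loc[0, "active"])
    none = call_active([], [contig])
    assert not bool(none.loc[0, "active"])


def test_activity_recovered_from_simulated_transcriptome():
    spec = CommunitySpec(
        n_genomes=3, genome_len_range=(10_000, 12_000), gene_density=1.2, seed=12
    )
    contigs, genes = generate_genomes(spec)
    _fq, recs = simulate_transcriptome(
        ["g1", "g3"], contigs, genes, depth=15, read_len=100, seed=13
    )
    df = call_active(recs, contigs, genes).set_index("votu")
    assert set(df.index[df["active"]]) == {"g1", "g3"}
    active_row = df.loc["g1"]
    assert active_row["gene_depths"], "per-gene transcript depth reported"


def test_presence_matrix_threshold():
    pres = presence_matrix(
        {"s1": {"v1": 0.9, "v2": 0.5}, "s2": {"v1": 0.71}}, min_breadth=0.7
    )
    assert bool(pres.loc["v1", "s1"]) and bool(pres.loc["v1", "s2"])
    assert not bool(pres.loc["v2", "s1"])
    assert not bool(pres.loc["v2", "s2"])
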