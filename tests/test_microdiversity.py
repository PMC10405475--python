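"""SNP calling, π, Nei–Gojobori sites, pN/pS, group comparison."""

import numpy as np
import pytest
from Bio.Seq import Seq

from brinepop.codon import SENSE_CODONS
from brinepop.coverage_profiles import SiteCounts
from brinepop.io_formats import Contig, GeneRecord
from brinepop.microdiversity import (
    call_snps,
    compare_groups,
    contig_summary,
    eligible_sites,
    genes_with_snp_fraction,
    ng_sites,
    pi,
    pnps,
    snp_density,
    snps_to_vcf,
)


def _counts(rows, contig_seq=None):
    arr = np.array(rows, dtype=np.int64)
    return SiteCounts("c1", arr), Contig("c1", contig_seq or "A" * len(arr))


# ---------------------------------------------------------------------- SNPs


def test_snp_called_at_thresholds():
    sc, contig = _counts([[90, 10, 0, 0]])
    (call,) = call_snps(sc, contig)
    assert call.consensus == "A"
    assert call.alts == [("C", 10, pytest.approx(0.10))]


def test_shallow_site_is_ineligible():
    sc, contig = _counts([[4, 4, 0, 0]])
    assert call_snps(sc, contig) == []


def test_low_count_allele_not_called():
    sc, contig = _counts([[97, 3, 0, 0]])
    assert call_snps(sc, contig) == []


def test_multiallelic_site_one_call_many_alts():
    sc, contig = _counts([[60, 20, 20, 0]])
    (call,) = call_snps(sc, contig)
    assert [a for a, _, _ in call.alts] == ["C", "G"]


def test_consensus_tie_breaks_toward_reference():
    sc, contig = _counts([[50, 50, 0, 0]], contig_seq="C")
    (call,) = call_snps(sc, contig)
    assert call.consensus == "C"
    assert call.alts[0][0] == "A"


# ------------------------------------------------------------------------ π


def test_site_pi_enumeration_example():
    """n=4 with A:2 C:2 -> 12 ordered pairs, 8 discordant: π = 8/12."""
    sc, contig = _counts([[2, 2, 0, 0]])
    assert pi(sc, min_cov=4, min_count=1, min_freq=0.0, ref_seq=contig.seq) == (
        pytest.approx(2 * 2 * 2 / (4 * 3))
    )


def test_monomorphic_region_pi_zero():
    sc, contig = _counts([[50, 0, 0, 0]] * 100)
    assert pi(sc, ref_seq=contig.seq) == 0.0


def test_region_pi_is_mean_over_eligible_sites():
    rows = [[50, 0, 0, 0]] * 99 + [[25, 25, 0, 0]]
    sc, contig = _counts(rows)
    site = (50 * 50 - 2 * 25 * 25) / (50 * 49)
    assert pi(sc, min_count=1, ref_seq=contig.seq) == pytest.approx(site / 100)


def test_pi_invariant_to_allele_relabeling():
    sc_a, contig = _counts([[30, 20, 0, 0]] * 10)
    sc_b, _ = _counts([[0, 0, 20, 30]] * 10)
    a = pi(sc_a, min_count=1, ref_seq=contig.seq)
    b = pi(sc_b, min_count=1, ref_seq=contig.seq)
    assert a == pytest.approx(b) and a > 0


def test_pi_nan_when_no_eligible_sites():
    sc, contig = _counts([[2, 1, 0, 0]])
    assert np.isnan(pi(sc, ref_seq=contig.seq))


def test_pi_recovery_from_two_strain_pileup(diverse_pileup):
    """Pileup π at 60x from a 50/50 two-strain pool recovers the
    truth-strain pairwise oracle within 10%."""
    contig, _genes, sc, truth = diverse_pileup
    est = pi(sc, ref_seq=contig.seq)
    oracle = truth.pi_oracle(contig.id)
    assert est == pytest.approx(oracle, rel=0.10)


def test_error_free_snp_calls_equal_truth(diverse_pileup):
    contig, _genes, sc, truth = diverse_pileup
    called = {c.pos for c in call_snps(sc, contig)}
    true_pos = {s.pos for s in truth.true_snps}
    assert called == true_pos


# ------------------------------------------------------------------ density


def test_snp_density_arithmetic():
    assert snp_density(5, 10_000) == pytest.approx(0.5)
    assert snp_density(0, 10_000) == 0.0
    assert np.isnan(snp_density(3, 0))


def test_genes_with_snp_fraction_counts():
    rows = [[50, 0, 0, 0]] * 1200
    rows[100] = [40, 10, 0, 0]
    sc, contig = _counts(rows)
    calls = call_snps(sc, contig)
    genes = [
        GeneRecord(f"g{i}", "c1", i * 300, i * 300 + 300, "+") for i in range(4)
    ]
    frac = genes_with_snp_fraction(genes, calls, sc)
    assert frac == pytest.approx(1 / 4)


# ------------------------------------------------------------- Nei–Gojobori


def _ng_oracle(codon):
    """Independent 9-mutant enumeration via Biopython translation."""
    aa = str(Seq(codon).translate(table=11))
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            mut_aa = str(Seq(mut).translate(table=11))
            if mut_aa == aa and mut_aa != "*":
                syn += 1
        s += syn / 3.0
    return 3.0 - s, s


@pytest.mark.parametrize("codon,expected", [
    ("TTT", (3 - 1 / 3, 1 / 3)),  # only TTT->TTC synonymous
    ("GGG", (2.0, 1.0)),          # third position fully synonymous
    ("ATG", (3.0, 0.0)),          # Met is a singleton codon
])
def test_ng_sites_hand_enumerated_codons(codon, expected):
    n, s = ng_sites(codon)
    assert (n, s) == (pytest.approx(expected[0]), pytest.approx(expected[1]))


def test_ng_sites_matches_enumeration_oracle_for_all_sense_codons():
    for codon in SENSE_CODONS:
        n, s = ng_sites(codon)
        n_o, s_o = _ng_oracle(codon)
        assert n == pytest.approx(n_o) and s == pytest.approx(s_o)
        assert n + s == pytest.approx(3.0)


def test_ng_sites_rejects_stop_and_ambiguous():
    with pytest.raises(ValueError):
        ng_sites("TAA")
    with pytest.raises(ValueError):
        ng_sites("ANT")


# ------------------------------------------------------------------- pN/pS


def _gene_fixture():
    """A 12-codon plus gene with 60x coverage and two engineered variants."""
    # gene: ATG + 10 sense codons + TAA
    body = "ATG" + "GCT" * 10 + "TAA"  # Ala codons; GCx all synonymous at pos 3
    seq = "TT" + body + "TT"
    contig = Contig("c1", seq)
    gene = GeneRecord("g1", "c1", 2, 2 + len(body), "+")
    counts = np.zeros((len(seq), 4), dtype=np.int64)
    code = {b: i for i, b in enumerate("ACGT")}
    for i, b in enumerate(seq):
        counts[i, code[b]] = 60
    return contig, gene, counts, code


def test_pnps_ratio_and_classes():
    contig, gene, counts, code = _gene_fixture()
    # synonymous variant: third position of a GCT codon -> GCC (A->C at pos)
    syn_pos = gene.start + 3 + 2  # first GCT codon, 3rd base (T)
    counts[syn_pos, code["C"]] = 20
    # nonsynonymous variant: first position GCT -> CCT (Ala->Pro)
    non_pos = gene.start + 6
    counts[non_pos, code["C"]] = 20
    sc = SiteCounts("c1", counts)
    calls = call_snps(sc, contig)
    sel = pnps(gene, calls, sc, contig)
    assert (sel.n_obs, sel.s_obs) == (1, 1)
    # GCT: ng sites (2, 1); ATG (3, 0); of 11 non-stop codons all covered
    assert sel.ratio == pytest.approx((1 / sel.n_sites) / (1 / sel.s_sites))
    assert sel.selection == ("positive" if sel.ratio > 1 else "purifying")
    assert sel.flag == ""


def test_pnps_spec_arithmetic_identity():
    """pN/pS = (N/N_sites)/(S/S_sites); with N=2,S=1 at sites 200/100 the
    ratio is exactly 1 and the class is purifying (not > 1)."""
    ratio = (2 / 200) / (1 / 100)
    assert ratio == 1.0 and not ratio > 1


def test_pnps_no_variation_class():
    contig, gene, counts, _ = _gene_fixture()
    sc = SiteCounts("c1", counts)
    sel = pnps(gene, call_snps(sc, contig), sc, contig)
    assert sel.selection == "no-variation"
    assert np.isnan(sel.ratio)


def test_pnps_pseudocount_when_no_synonymous_changes():
    contig, gene, counts, code = _gene_fixture()
    for k in (1, 3, 5):
        counts[gene.start + 3 * k, code["C"]] = 20  # GCT->CCT nonsyn x3
    sc = SiteCounts("c1", counts)
    sel = pnps(gene, call_snps(sc, contig), sc, contig)
    assert sel.flag == "pseudocount"
    assert sel.n_obs == 3 and sel.s_obs == 0
    assert sel.ratio == pytest.approx((4 / sel.n_sites) / (1 / sel.s_sites))
    assert sel.selection == "positive"


def test_pnps_rejects_broken_frames():
    contig, gene, counts, _ = _gene_fixture()
    sc = SiteCounts("c1", counts)
    bad = GeneRecord("g2", "c1", 2, 6, "+")
    with pytest.raises(ValueError):
        pnps(bad, [], sc, contig)
    # internal reference stop
    stop_contig = Contig("c2", "ATGTAAGCTTAA")
    stop_gene = GeneRecord("g3", "c2", 0, 12, "+")
    sc2 = SiteCounts("c2", np.zeros((12, 4), dtype=np.int64))
    with pytest.raises(ValueError, match="internal stop"):
        pnps(stop_gene, [], sc2, stop_contig)


def test_directional_pnps_from_simulated_strains(small_genome):
    """frac_nonsyn 0.9 vs 0.1 at matched mutation load: median gene pN/pS
    lands above 1 in the first arm and below in the second."""
    from brinepop.coverage_profiles import allele_counts, filter_alignments
    from brinepop.synthetic_community import StrainSpec, inject_strains, simulate_reads

    contig, genes = small_genome
    medians = {}
    for fn in (0.9, 0.1):
        sspec = StrainSpec(n_strains=2, target_pi=0.004, frac_nonsyn=fn, coding_only=True)
        strains, _ = inject_strains(contig, genes, sspec, seed=31)
        _fq, recs = simulate_reads(strains, [0.5, 0.5], contig, 50, 100, 0.0, seed=32)
        sc = allele_counts(filter_alignments(recs), contig)
        calls = call_snps(sc, contig)
        ratios = [pnps(g, calls, sc, contig).ratio for g in genes]
        ratios = [r for r in ratios if not np.isnan(r)]
        medians[fn] = np.median(ratios)
    assert medians[0.9] > 1 > medians[0.1]


# ------------------------------------------------------------- comparisons


def test_compare_groups_identical_samples_tie():
    df = compare_groups({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
    assert df.loc[0, "p_value"] > 0.9


def test_compare_groups_fully_separated():
    rng = np.random.default_rng(0)
    a = 0.001 + rng.normal(0, 1e-5, 20)
    b = 0.01 + rng.normal(0, 1e-5, 20)
    df = compare_groups({"stable": a, "fluct": b})
    assert df.loc[0, "p_value"] < 1e-6
    assert df.loc[0, "median_a"] < df.loc[0, "median_b"]


def test_compare_groups_requires_two_nonempty_groups():
    with pytest.raises(ValueError):
        compare_groups({"a": [1.0]})
    with pytest.raises(ValueError):
        compare_groups({"a": [1.0], "b": [float("nan")]})


def test_contig_summary_and_vcf_output(diverse_pileup):
    contig, genes, sc, truth = diverse_pileup
    row, gene_df = contig_summary(sc, contig, genes)
    assert row["n_snps"] == len(truth.true_snps)
    assert row["eligible_sites"] > 0.95 * len(contig)
    assert len(gene_df) == len(genes)
    calls = call_snps(sc, contig)
    vcf = snps_to_vcf(calls)
    assert vcf.count("\n") == len(calls) + 2
    first = vcf.splitlines()[2].split("\t")
    assert int(first[1]) == calls[0].pos + 1  # 1-based POS
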