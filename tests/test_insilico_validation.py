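"""Harmonization, directionality, McNemar, structural support, replication,
and evidence profiles."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from v2gtier import (
    GeneModel,
    GenomicInterval,
    InteractionPair,
    Variant,
    directionality_consistency,
    epi_tad_support,
    eqtl_replication,
    evidence_profiles,
    harmonize_z,
    mcnemar_improvement,
)
from v2gtier.insilico_validation import HarmonizedZ, group_evidence

from conftest import make_record

CANON = Variant("chr1", 100, "A", "G")


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def test_alt_effect_allele_is_unchanged():
    rec = make_record(100, 0.17, 0.1, effect_allele="G")
    assert harmonize_z(rec, CANON).z == pytest.approx(1.7)


def test_ref_effect_allele_is_flipped():
    rec = make_record(100, 0.17, 0.1, effect_allele="A")
    assert harmonize_z(rec, CANON).z == pytest.approx(-1.7)


def test_harmonization_is_idempotent():
    rec = make_record(100, 0.17, 0.1, effect_allele="A")
    once = harmonize_z(rec, CANON)
    # re-expressing the harmonized record (now ALT-oriented) changes nothing
    rec2 = make_record(100, once.z * 0.1, 0.1, effect_allele="G")
    assert harmonize_z(rec2, CANON).z == pytest.approx(once.z)


def test_unknown_effect_allele_rejected():
    rec = make_record(100, 0.17, 0.1, ref="C", alt="T", effect_allele="T")
    with pytest.raises(ValueError):
        harmonize_z(rec, CANON)


def test_ambiguous_variant_is_flagged_not_silently_flipped():
    amb = Variant("chr1", 100, "A", "T")
    rec = make_record(100, 0.17, 0.1, ref="A", alt="T", effect_allele="T")
    hz = harmonize_z(rec, amb)
    assert hz.ambiguous and hz.z == pytest.approx(1.7)


# ---------------------------------------------------------------------------
# directionality
# ---------------------------------------------------------------------------

def test_all_groups_same_sign_is_consistent():
    gz = {("M", "Frontal Cortex"): 1.2, ("M", "Limbic System"): 0.4,
          ("E", "Basal Ganglia"): 2.0}
    v = directionality_consistency(("v", "g"), gz, reference_z=0.8)
    assert v.n_disagree == 0 and v.fraction_disagree == 0.0
    assert not v.inconsistent


def test_three_of_four_disagree_is_inconsistent():
    gz = {("M", "a"): -1.0, ("M", "b"): -0.5, ("E", "c"): -2.0, ("E", "d"): 1.0}
    v = directionality_consistency(("v", "g"), gz, reference_z=0.8)
    assert v.n_groups == 4 and v.n_disagree == 3
    assert v.fraction_disagree == pytest.approx(0.75)
    assert v.inconsistent


def test_half_disagreement_is_not_inconsistent():
    gz = {("M", "a"): -1.0, ("M", "b"): 1.0}
    v = directionality_consistency(("v", "g"), gz, reference_z=1.0)
    assert v.fraction_disagree == pytest.approx(0.5)
    assert not v.inconsistent   # strictly greater than the threshold


def test_zero_z_groups_leave_denominator():
    gz = {("M", "a"): 0.0, ("M", "b"): 1.0, ("M", "c"): -1.0}
    v = directionality_consistency(("v", "g"), gz, reference_z=1.0)
    assert v.n_groups == 2


def test_missing_reference_is_undetermined():
    assert directionality_consistency(("v", "g"), {("M", "a"): 1.0}, None) is None
    assert directionality_consistency(("v", "g"), {("M", "a"): 1.0}, 0.0) is None


def test_group_evidence_averages_and_drops_unmapped():
    ev = [HarmonizedZ("v", "g", "t1", "M", 1.0),
          HarmonizedZ("v", "g", "t2", "M", 3.0),
          HarmonizedZ("v", "g", "nowhere", "M", 9.0)]
    gz = group_evidence(ev, {"t1": "A", "t2": "A"})
    assert gz == {("M", "A"): pytest.approx(2.0)}


def test_sign_scramble_harmonization_monte_carlo():
    """Random effect-allele reporting scrambles raw signs; harmonization
    restores a single direction, so inconsistency never increases and
    typically collapses.  50 seeded cohorts."""
    group_map = {f"t{k}": f"G{k}" for k in range(6)}
    improvements = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        raw_flags, harm_flags = [], []
        for _ in range(10):   # pairs per cohort
            true_z = rng.uniform(1.0, 3.0)   # one true positive direction
            raws, harms = {}, {}
            for k in range(6):
                flip = rng.random() < 0.5
                rec = make_record(100, (-true_z if flip else true_z) * 0.1, 0.1,
                                  effect_allele="A" if flip else "G",
                                  gene_id="g", tissue=f"t{k}", source="M")
                hz = harmonize_z(rec, CANON)
                harms[("M", f"G{k}")] = hz.z
                raws[("M", f"G{k}")] = rec.z
            ref = true_z
            raw_v = directionality_consistency(("v", "g"), raws, ref)
            harm_v = directionality_consistency(("v", "g"), harms, ref)
            raw_flags.append(raw_v.inconsistent)
            harm_flags.append(harm_v.inconsistent)
        assert sum(harm_flags) == 0          # harmonization fully restores direction
        mc = mcnemar_improvement(raw_flags, harm_flags)
        assert mc.percent_reduction >= 0
        improvements.append(sum(raw_flags))
    assert sum(improvements) > 0             # the scramble does break raw signs


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

def test_printed_improvement_arithmetic():
    before = [True] * 35 + [False] * 6
    after = [True] * 6 + [False] * 35        # nested improvement 35 -> 6
    mc = mcnemar_improvement(before, after)
    assert mc.percent_reduction == 83
    assert mc.pvalue < 0.0001


def test_no_change_is_degenerate():
    flags = [True, False, True]
    mc = mcnemar_improvement(flags, flags)
    assert mc.percent_reduction == 0
    assert mc.statistic is None and mc.pvalue == 1.0
    assert mc.method == "degenerate"


def test_one_sided_discordance_exact_binomial():
    before = [True] * 29 + [False] * 12
    after = [False] * 41
    mc = mcnemar_improvement(before, after, method="chi2")
    assert mc.statistic == pytest.approx(29.0)
    exact = mcnemar_improvement(before, after, method="exact")
    assert exact.pvalue == pytest.approx(2 * 0.5 ** 29)
    assert exact.pvalue < 0.0001


def test_chi2_and_exact_agree_in_significance_for_large_discordance():
    rng = np.random.default_rng(11)
    for _ in range(30):
        n = 120
        before = rng.random(n) < 0.5
        flip_to_0 = before & (rng.random(n) < rng.uniform(0.1, 0.8))
        flip_to_1 = ~before & (rng.random(n) < rng.uniform(0.0, 0.4))
        after = (before & ~flip_to_0) | flip_to_1
        b = int((before & ~after).sum())
        c = int((~before & after).sum())
        if b + c < 25:
            continue
        chi2 = mcnemar_improvement(before, after, method="chi2")
        exact = mcnemar_improvement(before, after, method="exact")
        assert (chi2.pvalue < 0.05) == (exact.pvalue < 0.05)
        # cross-check both against the statsmodels implementation
        table = [[int((before & after).sum()), b], [c, int((~before & ~after).sum())]]
        sm_exact = sm_mcnemar(table, exact=True)
        assert exact.pvalue == pytest.approx(sm_exact.pvalue, rel=1e-6)
        sm_chi2 = sm_mcnemar(table, exact=False, correction=False)
        assert chi2.statistic == pytest.approx(sm_chi2.statistic)
        assert chi2.pvalue == pytest.approx(sm_chi2.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# EPI / TAD support
# ---------------------------------------------------------------------------

GENE = GeneModel(gene_id="G1", chrom="chr1", strand="+",
                 exons=((10_000, 10_500), (11_000, 12_000)),
                 cds_start=10_100, cds_end=11_800)
MODELS = {"G1": GENE}
VAR = Variant("chr1", 150, "A", "G")


def _epi(a1, a2, source="3DGenome"):
    return InteractionPair(anchor1=GenomicInterval("chr1", *a1),
                           anchor2=GenomicInterval("chr1", *a2),
                           assay="HiC", source=source, celltype="mg")


def test_variant_and_promoter_in_opposite_anchors_supported():
    # promoter = [9000, 10000); variant pos 150 -> anchor [100, 200)
    sup = epi_tad_support(VAR, "G1", [_epi((100, 200), (9500, 9900))], [], MODELS)
    assert sup.epi_supported and sup.epi_sources == ("3DGenome",)


def test_orientation_swap_still_supported():
    sup = epi_tad_support(VAR, "G1", [_epi((9500, 9900), (100, 200))], [], MODELS)
    assert sup.epi_supported


def test_promoter_outside_far_anchor_unsupported():
    sup = epi_tad_support(VAR, "G1", [_epi((100, 200), (50_000, 51_000))], [], MODELS)
    assert not sup.epi_supported


def test_tad_requires_variant_and_tss_in_same_interval():
    covering = GenomicInterval("chr1", 0, 20_000, name="3DGenome")
    split = GenomicInterval("chr1", 0, 5_000, name="3DGenome")
    assert epi_tad_support(VAR, "G1", [], [covering], MODELS).tad_supported
    assert not epi_tad_support(VAR, "G1", [], [split], MODELS).tad_supported


def test_unknown_gene_yields_no_support():
    sup = epi_tad_support(VAR, "NOPE", [_epi((100, 200), (9500, 9900))],
                          [GenomicInterval("chr1", 0, 20_000)], MODELS)
    assert not sup.epi_supported and not sup.tad_supported


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def test_same_pair_same_sign_replicates():
    ext = make_record(100, 0.2, 0.1, gene_id="G1", source="MetaBrain")
    assert eqtl_replication(CANON, "G1", 1.0, [ext]) == {"MetaBrain"}


def test_opposite_sign_does_not_replicate():
    ext = make_record(100, -0.2, 0.1, gene_id="G1", source="MetaBrain")
    assert eqtl_replication(CANON, "G1", 1.0, [ext]) == set()


def test_ref_oriented_record_replicates_after_flip():
    # reported against REF with negative beta == positive ALT effect
    ext = make_record(100, -0.2, 0.1, effect_allele="A", gene_id="G1",
                      source="eQTLCatalogue")
    assert eqtl_replication(CANON, "G1", 1.0, [ext]) == {"eQTLCatalogue"}


def test_wrong_gene_or_variant_does_not_replicate():
    other_gene = make_record(100, 0.2, 0.1, gene_id="G2", source="M")
    other_var = make_record(500, 0.2, 0.1, gene_id="G1", source="M")
    assert eqtl_replication(CANON, "G1", 1.0, [other_gene, other_var]) == set()


# ---------------------------------------------------------------------------
# evidence profiles
# ---------------------------------------------------------------------------

EMPTY_V = pd.DataFrame(columns=["vid", "cadd", "regdb", "histone_q", "atac",
                                "other_gwas"])
EMPTY_G = pd.DataFrame(columns=["gene_id", "nominated", "brain_expressed"])


def _vtable(**kw):
    row = dict(vid=CANON.vid, cadd=None, regdb=None, histone_q=None,
               atac=0, other_gwas=0)
    row.update(kw)
    return pd.DataFrame([row])


def test_empty_tables_give_all_false():
    profile, gene = evidence_profiles(CANON, "G1", EMPTY_V, EMPTY_G)
    assert profile.count == 0 and not profile.validated
    assert gene.count == 0 and not gene.validated


def test_cadd_threshold_is_strict():
    profile, _ = evidence_profiles(CANON, "G1", _vtable(cadd=10.0), EMPTY_G)
    assert not profile.effect_pred
    profile, _ = evidence_profiles(CANON, "G1", _vtable(cadd=10.01), EMPTY_G)
    assert profile.effect_pred


def test_regdb_rank_disjunction():
    profile, _ = evidence_profiles(CANON, "G1", _vtable(cadd=3.0, regdb="1d"),
                                   EMPTY_G)
    assert profile.effect_pred
    profile, _ = evidence_profiles(CANON, "G1", _vtable(cadd=3.0, regdb="2b"),
                                   EMPTY_G)
    assert not profile.effect_pred


def test_malformed_regdb_treated_as_absent():
    profile, _ = evidence_profiles(CANON, "G1", _vtable(regdb="banana"), EMPTY_G)
    assert not profile.effect_pred and profile.regdb is None


def test_histone_q_threshold_strict():
    profile, _ = evidence_profiles(CANON, "G1", _vtable(histone_q=0.05), EMPTY_G)
    assert not profile.histone
    profile, _ = evidence_profiles(CANON, "G1", _vtable(histone_q=0.049), EMPTY_G)
    assert profile.histone


def test_gene_evidence_counts():
    gt = pd.DataFrame([dict(gene_id="G1", nominated=1, brain_expressed=1)])
    _, gene = evidence_profiles(CANON, "G1", EMPTY_V, gt)
    assert gene.count == 2 and gene.validated
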