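"""Approximate Bayes factors, configuration-enumeration posteriors, V2G calls."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

from v2gtier import (
    ColocPriors,
    ColocResult,
    Variant,
    call_v2g,
    coloc_fdr,
    coloc_posteriors,
    log_abf,
)
from v2gtier.colocalization import filter_nominal_eqtl_genes

from conftest import enumerate_coloc_oracle, make_record


# ---------------------------------------------------------------------------
# log ABF
# ---------------------------------------------------------------------------

def test_null_z_gives_negative_log_abf():
    rec = make_record(100, 0.0, 0.1)
    W = 0.0225
    assert log_abf(rec, W) == pytest.approx(0.5 * math.log(0.01 / (0.01 + W)))
    assert log_abf(rec, W) < 0


def test_no_information_limit():
    rec = make_record(100, 2e6, 1e6)   # z = 2 but enormous variance
    assert log_abf(rec, 0.0225) == pytest.approx(0.0, abs=1e-10)


def test_log_abf_against_arbitrary_precision_oracle():
    beta, se, W = sympy.Rational(2, 5), sympy.Rational(1, 10), sympy.Rational(9, 400)
    V = se ** 2
    z = beta / se
    expected = sympy.log(V / (V + W)) / 2 + z ** 2 * W / (V + W) / 2
    rec = make_record(100, 0.4, 0.1)
    assert log_abf(rec, 0.0225) == pytest.approx(float(expected.evalf(30)), rel=1e-12)


def test_log_abf_monotone_in_abs_z():
    W = 0.0225
    vals = [log_abf(make_record(1, b, 0.1), W) for b in (0.0, 0.1, 0.2, 0.5, 1.0)]
    assert vals == sorted(vals)
    assert log_abf(make_record(1, -0.5, 0.1), W) == pytest.approx(
        log_abf(make_record(1, 0.5, 0.1), W))


# ---------------------------------------------------------------------------
# posteriors vs brute-force enumeration
# ---------------------------------------------------------------------------

def _random_locus(rng, n):
    pos = sorted(rng.choice(np.arange(1000, 100_000), size=n, replace=False))
    r1 = [make_record(int(p), float(rng.normal(0, 0.3)), 0.05) for p in pos]
    r2 = [make_record(int(p), float(rng.normal(0, 0.3)), 0.05) for p in pos]
    return r1, r2


@pytest.mark.parametrize("n", [1, 2, 3, 5, 8])
def test_posteriors_match_enumeration_oracle(n):
    rng = np.random.default_rng(100 + n)
    priors = ColocPriors()
    for _ in range(20):
        r1, r2 = _random_locus(rng, n)
        result = coloc_posteriors(r1, r2, priors)
        oracle = enumerate_coloc_oracle(r1, r2, priors)
        for h in "H0 H1 H2 H3 H4".split():
            assert result.pp[h] == pytest.approx(oracle["pp"][h], rel=1e-8, abs=1e-300)
        for vid, p in oracle["snp_pp_h4"].items():
            assert result.snp_pp_h4[vid] == pytest.approx(p, rel=1e-8)


def test_three_snp_worked_example_fixed_betas():
    """3-SNP locus with fixed (beta, se): frozen against the enumeration oracle."""
    priors = ColocPriors()
    r1 = [make_record(100, 0.45, 0.05), make_record(200, 0.30, 0.05),
          make_record(300, 0.02, 0.05)]
    r2 = [make_record(100, 0.50, 0.05), make_record(200, 0.28, 0.05),
          make_record(300, -0.01, 0.05)]
    result = coloc_posteriors(r1, r2, priors)
    oracle = enumerate_coloc_oracle(r1, r2, priors)
    assert result.pp["H4"] == pytest.approx(oracle["pp"]["H4"], rel=1e-10)
    assert result.pp["H4"] > 0.9                       # strongly shared at SNP1
    assert max(result.snp_pp_h4, key=result.snp_pp_h4.get) == "chr1:100:A:G"


def test_one_sided_signal_puts_mass_on_h1():
    r1 = [make_record(100, 0.6, 0.05), make_record(200, 0.0, 0.05),
          make_record(300, 0.01, 0.05)]
    r2 = [make_record(100, 0.0, 0.01), make_record(200, 0.0, 0.01),
          make_record(300, 0.0, 0.01)]
    result = coloc_posteriors(r1, r2, ColocPriors())
    assert result.pp["H1"] == max(result.pp.values())
    oracle = enumerate_coloc_oracle(r1, r2, ColocPriors())
    assert max(oracle["pp"], key=oracle["pp"].get) == "H1"


@given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=10_000))
@settings(max_examples=60, deadline=None)
def test_posteriors_and_snp_posteriors_normalize(n, seed):
    rng = np.random.default_rng(seed)
    r1, r2 = _random_locus(rng, n)
    result = coloc_posteriors(r1, r2, ColocPriors())
    assert sum(result.pp.values()) == pytest.approx(1.0, abs=1e-9)
    assert sum(result.snp_pp_h4.values()) == pytest.approx(1.0, abs=1e-9)
    assert 0.0 <= result.fdr <= 1.0


def test_monotone_in_shared_signal():
    """Raising the shared SNP's |z| in both traits never lowers PP(H4)."""
    priors = ColocPriors()
    prev = -1.0
    for z in np.linspace(0.0, 12.0, 25):
        beta = z * 0.05
        r1 = [make_record(100, beta, 0.05), make_record(200, 0.05, 0.05)]
        r2 = [make_record(100, beta, 0.05), make_record(200, -0.03, 0.05)]
        h4 = coloc_posteriors(r1, r2, priors).pp["H4"]
        assert h4 >= prev - 1e-12
        prev = h4


def test_snp_order_invariance():
    rng = np.random.default_rng(3)
    r1, r2 = _random_locus(rng, 6)
    base = coloc_posteriors(r1, r2, ColocPriors())
    perm = coloc_posteriors(list(reversed(r1)), list(np.random.default_rng(1).permutation(r2)),
                            ColocPriors())
    for h in base.pp:
        assert base.pp[h] == pytest.approx(perm.pp[h], rel=1e-12)
    assert base.snp_pp_h4 == pytest.approx(perm.snp_pp_h4)


def test_empty_intersection_raises():
    r1 = [make_record(100, 0.1, 0.05)]
    r2 = [make_record(999, 0.1, 0.05)]
    with pytest.raises(ValueError):
        coloc_posteriors(r1, r2, ColocPriors())


def test_priors_validation():
    with pytest.raises(ValueError):
        ColocPriors(p1=1e-4, p2=1e-4, p12=1e-3)   # p12 > min(p1, p2)
    with pytest.raises(ValueError):
        ColocPriors(W=0.0)


# ---------------------------------------------------------------------------
# V2G calling and FDR
# ---------------------------------------------------------------------------

def _result(pp_h4, snp_pps, n_snps=None):
    rest = (1.0 - pp_h4) / 4
    pp = {"H0": rest, "H1": rest, "H2": rest, "H3": rest, "H4": pp_h4}
    return ColocResult(locus_id="L", n_snps=n_snps or len(snp_pps),
                       pp=pp, snp_pp_h4=snp_pps, priors=ColocPriors())


def _eqtl_records(pps):
    return [make_record(int(vid.split(":")[1]), 0.2, 0.1, gene_id="G1",
                        tissue="cortex", source="GTEx") for vid in pps]


def test_single_snp_locus_never_called():
    res = _result(0.99, {"chr1:100:A:G": 1.0})
    assert call_v2g(res, _eqtl_records(res.snp_pp_h4)) is None


def test_call_thresholds_are_strict():
    pps = {"chr1:100:A:G": 0.51, "chr1:200:A:G": 0.29,
           "chr1:300:A:G": 0.1, "chr1:400:A:G": 0.06, "chr1:500:A:G": 0.04}
    res = _result(0.71, pps)
    pair = call_v2g(res, _eqtl_records(pps))
    assert pair is not None and pair.variant.vid == "chr1:100:A:G"
    # at the threshold exactly: no call
    assert call_v2g(_result(0.70, pps), _eqtl_records(pps)) is None
    at_snp = dict(pps, **{"chr1:100:A:G": 0.50, "chr1:200:A:G": 0.30})
    assert call_v2g(_result(0.71, at_snp), _eqtl_records(at_snp)) is None


@pytest.mark.parametrize("pp_h4,expected", [(0.95, 0.05), (1.0, 0.0), (0.0, 1.0)])
def test_fdr_is_one_minus_h4(pp_h4, expected):
    res = _result(pp_h4, {"chr1:100:A:G": 0.6, "chr1:200:A:G": 0.4})
    assert coloc_fdr(res) == pytest.approx(expected)
    assert res.fdr == pytest.approx(sum(res.pp[h] for h in ("H0", "H1", "H2", "H3")),
                                    abs=1e-12)


def test_nominal_gene_filter():
    strong = [make_record(100, 0.5, 0.1, gene_id="G1", tissue="t", source="s"),
              make_record(200, 0.0, 0.1, gene_id="G1", tissue="t", source="s")]
    weak = [make_record(100, 0.05, 0.1, gene_id="G2", tissue="t", source="s")]
    kept = filter_nominal_eqtl_genes(strong + weak, alpha=0.05)
    assert ("G1", "t", "s") in kept and ("G2", "t", "s") not in kept
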