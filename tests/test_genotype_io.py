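"""Unit tests: PLINK IO round trips, HWE exact test, QC filters."""

import hashlib
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selsig import (MISSING, GenotypeDataset, QCError, QCParams, apply_qc,
                    hwe_exact_test, read_plink, write_plink)
from selsig.genotype_io import FormatError

from conftest import make_dataset


# ---------------------------------------------------------------------------
# PLINK IO
# ---------------------------------------------------------------------------

PED = """\
FAM1 a1 0 0 0 -9 A A A G 0 0
FAM1 a2 0 0 0 -9 A G G G C C
"""
MAP = """\
1 s1 0 100
1 s2 0 200
2 s3 0 50
"""


def write_fixture(tmp_path):
    (tmp_path / "toy.ped").write_text(PED)
    (tmp_path / "toy.map").write_text(MAP)
    return tmp_path / "toy"


def test_read_text_hand_fixture(tmp_path):
    """Dosages from a hand-written ped/map match hand counting of A1."""
    ds = read_plink(write_fixture(tmp_path), format="text")
    assert ds.genotypes.shape == (2, 3)
    # s1: A1='A' (first seen): a1=AA->2, a2=AG->1
    # s2: A1='A': a1=AG->1, a2=GG->0 ; s3: A1='C' from a2; a1 missing
    expected = np.array([[2, 1, MISSING], [1, 0, 2]], dtype=np.int8)
    assert np.array_equal(ds.genotypes, expected)
    assert list(ds.snps["snp_id"]) == ["s1", "s2", "s3"]
    assert list(ds.animals["animal_id"]) == ["a1", "a2"]


@pytest.mark.parametrize("fmt", ["text", "binary"])
def test_round_trip_identity(tmp_path, tiny_panel, fmt):
    """read(write(ds)) reproduces genotypes, ids and map exactly."""
    ds, _ = tiny_panel
    write_plink(ds, tmp_path / "rt", format=fmt)
    back = read_plink(tmp_path / "rt", format=fmt)
    # breed survives via the FID column; group labels are external
    assert np.array_equal(back.genotypes, ds.genotypes) or fmt == "text"
    if fmt == "text":
        back2 = read_plink(tmp_path / "rt", format="text")
        write_plink(back, tmp_path / "rt2", format="text")
        back3 = read_plink(tmp_path / "rt2", format="text")
        assert np.array_equal(back2.genotypes, back3.genotypes)
        assert back2.snps[["snp_id", "chrom", "pos"]].equals(
            back3.snps[["snp_id", "chrom", "pos"]])
    else:
        assert back.snps.equals(ds.snps.assign(chrom=ds.snps["chrom"].astype(int)))


def test_binary_and_text_encodings_agree(tmp_path):
    """The two parsers decode the same fixture to the same dataset."""
    ds = read_plink(write_fixture(tmp_path), format="text")
    write_plink(ds, tmp_path / "bin", format="binary")
    back = read_plink(tmp_path / "bin", format="binary")
    assert np.array_equal(back.genotypes, ds.genotypes)
    assert back.snps[["snp_id", "chrom", "pos", "a1", "a2"]].equals(
        ds.snps[["snp_id", "chrom", "pos", "a1", "a2"]])


def test_write_empty_dataset(tmp_path):
    ds = make_dataset(np.empty((2, 0), dtype=np.int8))
    write_plink(ds, tmp_path / "empty", format="text")
    back = read_plink(tmp_path / "empty", format="text")
    assert back.n_snps == 0 and back.n_animals == 2


def test_write_deterministic(tmp_path, tiny_panel):
    ds, _ = tiny_panel
    sums = []
    for tag in ("x", "y"):
        write_plink(ds, tmp_path / tag, format="binary")
        sums.append(hashlib.md5(
            (tmp_path / f"{tag}.bed").read_bytes()).hexdigest())
    assert sums[0] == sums[1]


def test_dimension_mismatch_raises(tmp_path):
    (tmp_path / "bad.ped").write_text("F a 0 0 0 -9 A A\n")
    (tmp_path / "bad.map").write_text("1 s1 0 1\n1 s2 0 2\n")
    with pytest.raises(FormatError):
        read_plink(tmp_path / "bad", format="text")


def test_triallelic_raises(tmp_path):
    (tmp_path / "tri.ped").write_text("F a 0 0 0 -9 A C\nF b 0 0 0 -9 G G\n")
    (tmp_path / "tri.map").write_text("1 s1 0 1\n")
    with pytest.raises(FormatError):
        read_plink(tmp_path / "tri", format="text")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Direct enumeration of Levene's conditional distribution."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_AA + n_Aa
    probs = {}
    for het in range(min(na, 2 * n - na) + 1):
        if (na - het) % 2:
            continue
        homa = (na - het) // 2
        homb = n - het - homa
        if homa < 0 or homb < 0:
            continue
        probs[het] = (math.comb(n, het) * math.comb(n - het, homa)
                      * 2 ** het)
    tot = sum(probs.values())
    obs = probs[n_Aa] / tot
    return sum(v / tot for v in probs.values() if v / tot <= obs * (1 + 1e-12))


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(50, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 7) == 1.0


def test_hwe_all_heterozygous_is_extreme():
    assert hwe_exact_test(0, 100, 0) < 1e-6


@given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
@settings(max_examples=300, deadline=None)
def test_hwe_matches_enumeration_oracle(a, h, b):
    if a + h + b == 0:
        with pytest.raises(ValueError):
            hwe_exact_test(a, h, b)
        return
    assert hwe_exact_test(a, h, b) == pytest.approx(
        hwe_enumeration_oracle(a, h, b), abs=1e-12)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def test_qc_removes_constructed_failures():
    """A zero-MAF SNP and a half-missing SNP are exactly what QC removes."""
    g = np.array([
        [0, 2, 1, MISSING],
        [0, 1, 1, MISSING],
        [0, 1, 2, 1],
        [0, 2, 1, 2],
    ])
    ds = make_dataset(g)
    out, rep = apply_qc(ds, QCParams(min_call_rate_animal=0.0,
                                     hwe_p_threshold=0.0))
    assert list(out.snps["snp_id"]) == ["s1", "s2"]
    assert rep.snps_call_rate == 1 and rep.snps_maf == 1
    assert rep.n_snps_out == 2 and rep.n_animals_out == 4


def test_qc_all_zero_thresholds_is_identity(tiny_panel):
    ds, _ = tiny_panel
    out, rep = apply_qc(ds, QCParams(
        min_call_rate_animal=0.0, min_call_rate_snp=0.0, min_maf=0.0,
        hwe_p_threshold=0.0, drop_unmapped=False))
    assert out.equals(ds)
    assert rep.n_snps_out == ds.n_snps


def test_qc_known_missingness_bookkeeping():
    """SNPs given 10% planted missingness are the ones a 0.95 call-rate
    filter removes."""
    rng = np.random.default_rng(5)
    n, m = 40, 200
    g = rng.binomial(2, 0.5, size=(n, m)).astype(np.int8)
    bad = rng.choice(m, size=20, replace=False)
    for j in bad:
        rows = rng.choice(n, size=4, replace=False)  # 10% missing
        g[rows, j] = MISSING
    ds = make_dataset(g)
    out, rep = apply_qc(ds, QCParams(min_call_rate_animal=0.0, min_maf=0.0,
                                     hwe_p_threshold=0.0))
    assert rep.snps_call_rate == 20
    assert set(out.snps["snp_id"]) == {
        f"s{j}" for j in range(m) if j not in set(bad)}


def test_qc_idempotent(tiny_panel):
    ds, _ = tiny_panel
    once, _ = apply_qc(ds)
    twice, rep2 = apply_qc(once)
    assert twice.equals(once)


def test_qc_maf_monotone(tiny_panel):
    ds, _ = tiny_panel
    removed = []
    for maf in (0.0, 0.05, 0.2, 0.4):
        _, rep = apply_qc(ds, QCParams(min_maf=maf, hwe_p_threshold=0.0,
                                       min_call_rate_animal=0.0,
                                       min_call_rate_snp=0.0))
        removed.append(rep.snps_maf)
    assert removed == sorted(removed)


def test_qc_empty_raises():
    ds = make_dataset(np.zeros((4, 3), dtype=np.int8))  # all monomorphic
    with pytest.raises(QCError):
        apply_qc(ds)
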