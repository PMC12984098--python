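import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from codonbias import (CodingSequence, CodonCountTable, ReferenceWeights,
                       cai, composition, count_codons, enc, get_reference,
                       profile_gene, rscu)
from conftest import counts_from, random_cds
from oracles import cai_oracle, composition_oracle, enc_oracle, rscu_oracle


def make_counts(code, **kw):
    counts = dict.fromkeys(code.sense_codons, 0)
    counts.update(kw)
    return CodonCountTable(counts=counts, total_codons=sum(counts.values()))


# --------------------------------------------------------------------- counts

def test_count_codons(code):
    cds = CodingSequence("sp", "g", "ATGATGTGG")
    table = count_codons(cds)
    assert table.total_codons == 3
    assert table.counts["ATG"] == 2 and table.counts["TGG"] == 1
    empty = count_codons(CodingSequence("sp", "g", ""))
    assert empty.total_codons == 0 and sum(empty.counts.values()) == 0


# ----------------------------------------------------------------------- RSCU

def test_rscu_closed_forms(code):
    # uniform Leu usage -> all 1
    uniform = make_counts(code, **dict.fromkeys(code.families["L"], 5))
    prof = rscu(uniform)
    assert all(prof.rscu[c] == pytest.approx(1.0) for c in code.families["L"])
    # twofold {10, 0} -> {2, 0}
    two = make_counts(code, TTT=10)
    assert rscu(two).rscu["TTT"] == pytest.approx(2.0)
    assert rscu(two).rscu["TTC"] == 0.0
    # Leu counts {CTG: 2, CTA: 1} -> 4, 2, 0
    leu = make_counts(code, CTG=2, CTA=1)
    prof = rscu(leu)
    assert prof.rscu["CTG"] == pytest.approx(4.0)
    assert prof.rscu["CTA"] == pytest.approx(2.0)
    assert prof.rscu["CTT"] == 0.0


def test_rscu_unobserved_amino_acid_flagged(code):
    prof = rscu(make_counts(code, TTT=3))
    assert "L" in prof.undefined_aas
    assert math.isnan(prof.rscu["CTG"])


def test_rscu_normalization_random_genes(code, random_genes):
    """Family RSCU values sum to the family size for observed amino acids."""
    for cds in random_genes:
        prof = rscu(counts_from(cds))
        for aa, fam in code.multi_codon_families.items():
            if aa in prof.undefined_aas:
                continue
            assert sum(prof.rscu[c] for c in fam) == pytest.approx(
                len(fam), abs=1e-9)
            for c in fam:
                assert -1e-12 <= prof.rscu[c] <= len(fam) + 1e-12


@given(st.lists(st.integers(0, 50), min_size=6, max_size=6))
def test_rscu_sixfold_family_property(counts6):
    """Hypothesis: any Leu count vector normalizes to mean RSCU 1."""
    from codonbias import standard_table
    code = standard_table()
    table = make_counts(code, **dict(zip(code.families["L"], counts6)))
    prof = rscu(table)
    total = sum(counts6)
    vals = [prof.rscu[c] for c in code.families["L"]]
    if total == 0:
        assert all(math.isnan(v) for v in vals)
    else:
        assert sum(vals) == pytest.approx(6.0, abs=1e-9)


# ---------------------------------------------------------------- composition

def test_composition_single_codon_sequence():
    comp = composition(CodingSequence("sp", "g", "GGC" * 10))
    assert comp.gc == 1.0 and comp.gc3 == 1.0
    assert comp.c3s == 1.0
    assert comp.a3s == 0.0 and comp.t3s == 0.0 and comp.g3s == 0.0


def test_composition_met_trp_only_flagged():
    comp = composition(CodingSequence("sp", "g", "ATGTGG" * 5))
    assert math.isnan(comp.gc3s)
    assert {"GC3s", "A3s", "T3s", "C3s", "G3s"} <= comp.flags


def test_composition_hand_built_vs_oracle(code):
    seq = "ATGGCTTTAAGACGGTTTCTGGGGATCATAACCTGG"  # 12 codons, mixed families
    comp = composition(CodingSequence("sp", "g", seq))
    expect = composition_oracle(seq, code.families, code.codon_to_aa)
    for key, val in comp.as_dict().items():
        assert val == pytest.approx(expect[key], abs=1e-12), key


def test_silent_site_frequencies_can_exceed_one(code):
    """The 3s convention is not a partition: A3s+T3s+C3s+G3s may top 1."""
    rng = np.random.default_rng(11)
    cds = random_cds(rng, 500)
    comp = composition(cds)
    total = comp.a3s + comp.t3s + comp.c3s + comp.g3s
    assert total > 1.0
    assert comp.gc12 == pytest.approx((comp.gc1 + comp.gc2) / 2, abs=1e-12)


# ------------------------------------------------------------------------ ENC

def test_enc_uniform_limit(code):
    """Equal use of every sense codon gives the unbiased limit 61."""
    counts = make_counts(code, **dict.fromkeys(code.sense_codons, 50))
    assert enc(counts).value == pytest.approx(61.0, abs=0.5)


def test_enc_single_codon_limit(code):
    """One codon per family at ~1000 codons gives maximal bias, ENC 20."""
    chosen = {fam[0]: 50 for fam in code.families.values()}
    counts = make_counts(code, **chosen)
    res = enc(counts)
    assert res.value == pytest.approx(20.0, abs=0.5)
    assert not res.partial


def test_enc_oracle_equivalence(code, random_genes):
    for cds in random_genes:
        table = counts_from(cds)
        expect = enc_oracle(dict(table.counts), code.families)
        assert enc(table).value == pytest.approx(expect, abs=1e-9)


def test_enc_monotone_under_concentration(code):
    """Concentrating synonymous usage (fixed amino-acid totals) never
    raises ENC."""
    rng = np.random.default_rng(3)
    base = counts_from(random_cds(rng, 600, concentration=5.0))
    prev = enc(base).value
    counts = dict(base.counts)
    for _ in range(10):
        # move one count toward each family's first codon
        for aa, fam in code.multi_codon_families.items():
            donors = [c for c in fam[1:] if counts[c] > 0]
            if donors:
                counts[donors[0]] -= 1
                counts[fam[0]] += 1
        cur = enc(CodonCountTable(counts=dict(counts),
                                  total_codons=sum(counts.values()))).value
        assert cur <= prev + 1e-9
        prev = cur


def test_enc_degenerate_inputs(code):
    none = make_counts(code)
    assert math.isnan(enc(none).value)
    # only Ile absent: threefold class imputed from classes 2 and 4
    chosen = {fam[0]: 20 for aa, fam in code.families.items() if aa != "I"}
    res = enc(make_counts(code, **chosen))
    assert not res.partial and 3 in res.f_bar


# ------------------------------------------------------------------------ CAI

def test_cai_closed_forms(code):
    ref = ReferenceWeights("t", dict.fromkeys(code.sense_codons, 1.0))
    gene = make_counts(code, TTT=5, GGC=5)
    assert cai(gene, ref) == pytest.approx(1.0)
    w = dict.fromkeys(code.sense_codons, 1.0)
    w["TTT"], w["GGC"] = 1.0, 0.25
    two = make_counts(code, TTT=1, GGC=1)
    assert cai(two, ReferenceWeights("t", w)) == pytest.approx(0.5)


def test_cai_excludes_met_trp(code):
    ref_w = dict.fromkeys(code.sense_codons, 0.3)
    ref_w["ATG"] = ref_w["TGG"] = 1.0
    counts = make_counts(code, ATG=50, TGG=50, TTT=2)
    assert cai(counts, ReferenceWeights("t", ref_w)) == pytest.approx(0.3)


def test_cai_oracle_equivalence(code, random_genes):
    ref = get_reference("ecoli")
    for cds in random_genes:
        table = counts_from(cds)
        expect = cai_oracle(dict(table.counts), dict(ref.w),
                            code.synonymous_codons)
        assert cai(table, ref) == pytest.approx(expect, abs=1e-10)


def test_cai_invariant_to_codon_order(code):
    rng = np.random.default_rng(5)
    cds = random_cds(rng, 150)
    ref = get_reference("human")
    shuffled_codons = list(cds.codons)
    rng.shuffle(shuffled_codons)
    shuffled = CodingSequence("sp", "g", "".join(shuffled_codons))
    assert cai(count_codons(cds), ref) == pytest.approx(
        cai(count_codons(shuffled), ref), abs=1e-12)


# ----------------------------------------------------------- reference tables

@pytest.mark.parametrize("name", ["ecoli", "human"])
def test_reference_family_max_is_one(code, name):
    ref = get_reference(name)
    for aa, fam in code.families.items():
        assert max(ref.w[c] for c in fam) == pytest.approx(1.0)
        assert all(ref.w[c] > 0 for c in fam)


def test_reference_from_counts_small_value_convention(code):
    counts = dict.fromkeys(code.sense_codons, 1.0)
    counts["TTT"], counts["TTC"] = 10.0, 0.0
    ref = ReferenceWeights.from_counts("x", counts)
    assert ref.w["TTT"] == 1.0
    assert ref.w["TTC"] == pytest.approx(0.5 / 10.0)


def test_reference_tsv_round_trip(tmp_path, code):
    ref = get_reference("ecoli")
    path = tmp_path / "ref.tsv"
    ref.to_tsv(path)
    back = ReferenceWeights.from_tsv(path, name="ecoli")
    for codon in code.sense_codons:
        assert back.w[codon] == pytest.approx(ref.w[codon], rel=1e-5)
    assert "Sharp" in back.provenance


# -------------------------------------------------------------------- bundles

def test_profile_gene_bundle(code):
    rng = np.random.default_rng(9)
    cds = random_cds(rng, 300)
    prof = profile_gene(cds, get_reference("ecoli"))
    assert prof.counts.total_codons == 300
    assert 20.0 <= prof.enc.value <= 61.0
    assert 0.0 < prof.cai <= 1.0


def test_profile_gene_degenerate_flags():
    cds = CodingSequence("sp", "g", "ATGTGG" * 4)
    prof = profile_gene(cds, get_reference("ecoli"))
    assert math.isnan(prof.enc.value) and math.isnan(prof.cai)
    assert "enc-undefined" in prof.flags and "cai-undefined" in prof.flags
    assert any(f.startswith("rscu-undefined") for f in prof.flags)
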