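import numpy as np
import pandas as pd
import pytest

from codonbias import (DefectRates, GeneSpec, SyntheticCollectionSpec,
                       count_codons, composition, enc, generate_collection,
                       generate_gene, inject_defects, neutrality_cloud,
                       neutrality_regression, read_cds_fasta, validate_cds,
                       vertebrate_demo_spec)
from codonbias.synthetic import DEFECT_TO_REASON, family_codon_probs


def _one_gene_spec(gc3=0.5, kappa=1.0, length=800, n_species=4, seed=0,
                   jitter=0.0):
    return SyntheticCollectionSpec(
        n_species=n_species, seed=seed,
        genes=(GeneSpec(gene_id="g", gc3_target=gc3, bias_concentration=kappa,
                        length_codons_mean=length, length_codons_sd=0.0,
                        interspecies_sd=jitter),))


def test_generated_sequences_pass_qc():
    coll = generate_collection(vertebrate_demo_spec(n_species=5, seed=1,
                                                    length_codons_mean=200))
    for gene, records in coll.raw_records.items():
        for _, raw in records:
            clean, reason, had_stop, has_atg = validate_cds(raw)
            assert reason is None and had_stop and has_atg


def test_collection_is_byte_reproducible(tmp_path):
    spec = vertebrate_demo_spec(n_species=3, seed=9, length_codons_mean=120)
    p1 = generate_collection(spec).write(tmp_path / "a")
    p2 = generate_collection(spec).write(tmp_path / "b")
    for gene in ("geneAT", "geneGC"):
        assert p1[gene].read_bytes() == p2[gene].read_bytes()
    assert (p1["ground_truth"].read_text() == p2["ground_truth"].read_text())


def test_written_collection_round_trips_through_qc(tmp_path):
    spec = vertebrate_demo_spec(n_species=6, seed=2, length_codons_mean=150)
    paths = generate_collection(spec).write(tmp_path)
    for gene in ("geneAT", "geneGC"):
        records, report = read_cds_fasta(paths[gene], gene)
        assert report.n_input == 6 and report.n_passed == 6


def test_family_codon_probs_shape(code):
    for aa, fam in code.multi_codon_families.items():
        p = family_codon_probs(fam, gc3=0.7, kappa=1.0)
        assert p.shape == (len(fam),)
        assert p.sum() == pytest.approx(1.0)
    # kappa=0 -> uniform
    p0 = family_codon_probs(code.families["L"], gc3=0.9, kappa=0.0)
    assert np.allclose(p0, 1 / 6)


def _mean_enc(gc3, kappa, length=2000, n=3, seed=0):
    coll = generate_collection(_one_gene_spec(gc3, kappa, length, n, seed))
    return float(np.mean([enc(count_codons(c)).value
                          for c in coll.coding_sequences("g")]))


def test_enc_uniform_limit_at_kappa_zero():
    assert _mean_enc(0.5, 0.0) == pytest.approx(61.0, abs=1.0)


def test_enc_maximal_bias_limit_at_large_kappa():
    # kappa large enough that the per-codon tiebreak also saturates,
    # leaving a unique winner in every family
    assert _mean_enc(0.9, 5000.0) == pytest.approx(20.0, abs=0.5)


def test_enc_monotone_in_bias_concentration():
    values = [_mean_enc(0.7, k, length=1500, n=2) for k in (0.0, 1.0, 3.0, 10.0)]
    assert all(a >= b - 0.5 for a, b in zip(values, values[1:]))
    assert values[0] - values[-1] > 20


def test_gc3s_monotone_in_target():
    targets = [0.1, 0.3, 0.5, 0.7, 0.9]
    measured = []
    for t in targets:
        coll = generate_collection(_one_gene_spec(t, 1.0, length=2000,
                                                  n_species=2, seed=5))
        measured.append(np.mean([composition(c).gc3s
                                 for c in coll.coding_sequences("g")]))
    assert all(a < b for a, b in zip(measured, measured[1:]))


def test_ground_truth_records_realized_draws():
    spec = vertebrate_demo_spec(n_species=4, seed=3, length_codons_mean=120)
    coll = generate_collection(spec)
    gt = coll.ground_truth
    assert len(gt) == 8 and set(gt["gene"]) == {"geneAT", "geneGC"}
    jit = gt.loc[gt["gene"] == "geneAT", "gc3_used"]
    assert (jit - 0.31).abs().max() < 0.1  # jittered around the target


def test_generate_gene_single():
    rng = np.random.default_rng(12)
    cds = generate_gene(GeneSpec(gene_id="x", length_codons_mean=100,
                                 length_codons_sd=0.0), "spZ", rng)
    assert cds.species_id == "spZ" and cds.n_codons == 100
    assert cds.sequence.startswith("ATG")


# ------------------------------------------------------------------- defects

def _records(n=40, seed=6):
    coll = generate_collection(vertebrate_demo_spec(n_species=n, seed=seed,
                                                    length_codons_mean=100))
    return coll.raw_records["geneAT"]


def test_inject_defects_rate_zero_is_identity():
    records = _records(5)
    out, manifest = inject_defects(records, DefectRates(), seed=1)
    assert out == records and manifest.empty


def test_inject_single_internal_stop_detected(tmp_path):
    records = _records(1)
    out, manifest = inject_defects(records, DefectRates(internal_stop=1.0),
                                   seed=2)
    assert len(manifest) == 1
    _, reason, _, _ = validate_cds(out[0][1])
    assert reason == "internal-stop"


def test_defect_manifest_matches_qc_one_to_one(tmp_path):
    """Every injected defect appears as exactly the predicted QC
    rejection, and undamaged records all pass."""
    records = _records(60)
    rates = DefectRates(ambiguous_base=0.15, internal_stop=0.15, frameshift=0.15)
    out, manifest = inject_defects(records, rates, seed=7)
    path = tmp_path / "defects.fasta"
    with open(path, "w") as fh:
        for rec_id, seq in out:
            fh.write(f">{rec_id}\n{seq}\n")
    _, report = read_cds_fasta(path, "geneAT")
    got = {r.record_id: r.reason for r in report.rejections}
    expected = dict(zip(manifest["record_id"], manifest["expected_reason"]))
    assert got == expected
    assert report.n_passed == len(records) - len(manifest)
    assert len(manifest) > 0


def test_defect_rates_validated():
    with pytest.raises(ValueError):
        inject_defects(_records(2), DefectRates(0.5, 0.5, 0.5), seed=1)


# ------------------------------------------------- numeric diagnostic clouds

def test_neutrality_cloud_plants_requested_slope():
    for slope in (0.0, 1.0):
        gc3, gc12 = neutrality_cloud(slope, n=49, noise_sd=0.01, seed=13)
        fit = neutrality_regression(gc3, gc12)
        assert fit.slope == pytest.approx(slope, abs=0.05)


def test_sequence_generator_gc12_independent_of_gc3():
    """With a fixed amino-acid profile the generator varies GC3 without
    moving GC12: the fitted neutrality slope is near zero."""
    spec = SyntheticCollectionSpec(
        n_species=30, seed=17,
        genes=(GeneSpec(gene_id="g", gc3_target=0.5, interspecies_sd=0.12,
                        length_codons_mean=600, length_codons_sd=0.0),))
    coll = generate_collection(spec)
    comps = [composition(c) for c in coll.coding_sequences("g")]
    fit = neutrality_regression([c.gc3 for c in comps],
                                [c.gc12 for c in comps])
    assert abs(fit.slope) < 0.1
    assert np.ptp([c.gc3 for c in comps]) > 0.2  # GC3 really varied
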