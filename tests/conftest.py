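import numpy as np
import pytest
from hypothesis import settings

from codonbias import CodingSequence, CodonCountTable, standard_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code():
    return standard_table()


def random_cds(rng: np.random.Generator, n_codons: int = 200,
               concentration: float = 1.0, species: str = "sp",
               gene: str = "g") -> CodingSequence:
    """A random CDS with Dirichlet-distributed synonymous preferences,
    giving a different bias pattern per draw."""
    code = standard_table()
    aas = [aa for aa in code.families]
    weights = {aa: rng.dirichlet(np.full(len(code.families[aa]), concentration))
               for aa in aas}
    picks = rng.choice(len(aas), size=n_codons)
    codons = []
    for k in picks:
        aa = aas[k]
        fam = code.families[aa]
        codons.append(fam[rng.choice(len(fam), p=weights[aa])])
    return CodingSequence(species_id=species, gene_id=gene,
                          sequence="".join(codons), record_id=f"{species}|{gene}")


def counts_from(cds: CodingSequence) -> CodonCountTable:
    code = standard_table()
    counts = dict.fromkeys(code.sense_codons, 0)
    for c in cds.codons:
        counts[c] += 1
    return CodonCountTable(counts=counts, total_codons=cds.n_codons)


@pytest.fixture(scope="session")
def random_genes():
    """100 random genes reused by the oracle-equivalence tests."""
    rng = np.random.default_rng(20260927)
    return [random_cds(rng, n_codons=int(rng.integers(120, 400)),
                       concentration=float(rng.uniform(0.2, 3.0)))
            for _ in range(100)]
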