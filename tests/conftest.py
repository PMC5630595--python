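import numpy as np
import pytest

from famvar.containers import (
    DomainInstance,
    FamilyAlignment,
    Proteome,
    VariantRecord,
    VariantTable,
)
from famvar.synth import (
    SyntheticConfig,
    generate_cohort,
    generate_proteome,
    generate_variants,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_individuals=120, n_families=4, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    cohort = generate_cohort(small_config)
    proteome = generate_proteome(small_config)
    variants = generate_variants(proteome, cohort, small_config)
    return cohort, proteome, variants


@pytest.fixture
def toy_proteome():
    """Two tiny families over four hand-built proteins, identity mappings."""
    seqs = {
        "pA": "MKTAYRLWQD",   # domain of famX at 3..7
        "pB": "GKTVYRLWHH",   # famX at 3..7
        "pC": "AACDEFGHIK",   # famY at 2..6
        "pD": "TTCDEFGHIW",   # famY at 2..6
    }
    famX = FamilyAlignment("famX", 5, [
        DomainInstance("famX", "pA", 3, 7, {i: i - 2 for i in range(3, 8)}),
        DomainInstance("famX", "pB", 3, 7, {i: i - 2 for i in range(3, 8)}),
    ])
    famY = FamilyAlignment("famY", 5, [
        DomainInstance("famY", "pC", 2, 6, {i: i - 1 for i in range(2, 7)}),
        DomainInstance("famY", "pD", 2, 6, {i: i - 1 for i in range(2, 7)}),
    ])
    return Proteome(sequences=seqs, families=[famX, famY])


@pytest.fixture
def toy_variants(toy_proteome):
    """Hand-placed variants over three individuals."""
    seqs = toy_proteome.sequences

    def v(protein, pos, alt, counts, consequence="missense"):
        return VariantRecord(protein, pos, seqs[protein][pos - 1], alt,
                             consequence, np.array(counts, dtype=np.int8))

    records = [
        v("pA", 5, "H", [1, 0, 2]),   # famX column 3
        v("pA", 6, "K", [0, 1, 0]),   # famX column 4
        v("pB", 5, "Q", [2, 0, 0]),   # famX column 3
        v("pC", 4, "W", [0, 1, 1]),   # famY column 3
        v("pA", 1, "T", [1, 1, 0]),   # outside any domain
        v("pB", 9, "*", [0, 0, 1], "stop_gain"),
    ]
    return VariantTable(records, ["i1", "i2", "i3"])
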