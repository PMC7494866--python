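import numpy as np
import pytest

import porpopgen as pp


@pytest.fixture
def tiny_aln():
    """Three sequences, two segregating columns (both singletons)."""
    return pp.GenomeAlignment(["s1", "s2", "s3"], ["AAAA", "AAAT", "AATT"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_alignment(rng, n=None, L=None, alphabet="ACGT"):
    """Small random alignment for oracle comparisons."""
    n = n if n is not None else int(rng.integers(2, 7))
    L = L if L is not None else int(rng.integers(4, 61))
    mat = rng.choice(list(alphabet), size=(n, L))
    return pp.GenomeAlignment(
        [f"s{i}" for i in range(n)], ["".join(row) for row in mat]
    )


@pytest.fixture(scope="session")
def synth_bundle(tmp_path_factory):
    """A written synthetic study: expansion lineage (n=12), small lineage,
    and a diverged outgroup lineage, on an 8 kb mitogenome-like template."""
    out = tmp_path_factory.mktemp("synth")
    cfg = pp.SynthConfig(
        genome_length=8000,
        groups=[
            pp.GroupConfig(
                "species_a", "L1", 12,
                pp.DemographyModel("sudden_expansion", theta1=30.0, theta0=1.0, tau=4.0),
                stem_mutations=30,
            ),
            pp.GroupConfig(
                "species_a", "L2", 4,
                pp.DemographyModel("constant", theta1=5.0), stem_mutations=30,
            ),
            pp.GroupConfig(
                "species_b", "OUT", 3,
                pp.DemographyModel("constant", theta1=3.0), stem_mutations=120,
            ),
        ],
        cds_nonsyn_fraction=0.25,
        seed=11,
    )
    aln, ann, lin = pp.synth_mitogenome_set(cfg, out_dir=out)
    return {"dir": out, "config": cfg, "aln": aln, "ann": ann, "lineages": lin}
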