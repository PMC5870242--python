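import numpy as np
import pytest

from cpnmodes import PopulationSpec, RatioSample, generate_mosaic


@pytest.fixture(scope="session")
def unimodal_values():
    """Sharply unimodal cleaned-scale sample: N(0.8, 0.05^2), n=3000."""
    rng = np.random.default_rng(42)
    return rng.normal(0.8, 0.05, 3000)


@pytest.fixture(scope="session")
def bimodal_values():
    """Well-separated 50/50 mixture of N(0.45, 0.07^2) and N(0.95, 0.07^2)."""
    rng = np.random.default_rng(7)
    return np.concatenate(
        [rng.normal(0.45, 0.07, 2000), rng.normal(0.95, 0.07, 2000)]
    )


@pytest.fixture(scope="session")
def skewed_mixture_values():
    """92/8 mixture: a minor mode carrying ~8% of the mass."""
    rng = np.random.default_rng(11)
    return np.concatenate(
        [rng.normal(0.5, 0.06, 3680), rng.normal(1.1, 0.06, 320)]
    )


@pytest.fixture(scope="session")
def mosaic_records():
    """Two equally sized populations, CpG-depleted (d=0.5) and intact."""
    specs = [
        PopulationSpec(600, 1500, gc_content=0.5, depletion=0.5, label="meth"),
        PopulationSpec(600, 1500, gc_content=0.5, depletion=0.0, label="unmeth"),
    ]
    return generate_mosaic(specs, seed=20)


@pytest.fixture()
def tiny_fasta(tmp_path):
    """Three records; the second has only 199 unambiguous nucleotides."""
    block = "CGCGCGCGCG" * 20  # 200 nt, periodic
    short = "N" + "ACGT" * 49 + "ACG"  # 199 unambiguous + one N
    path = tmp_path / "tiny.fa"
    with open(path, "w") as fh:
        fh.write(f">a first record\n{block}\n")
        fh.write(f">b short one\n{short}\n")
        fh.write(">c wrapped\n")
        for i in range(0, len(block), 60):
            fh.write(block[i : i + 60] + "\n")
    return path


def make_sample(values, **kw):
    return RatioSample(values=np.asarray(values, dtype=float), **kw)
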