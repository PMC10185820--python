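import numpy as np
import pytest

from gutmr.harmonize import HarmonizedInstrument, HarmonizedSet
from gutmr.summary_io import GwasSummaryRecord, SummaryDataset


def make_record(rsid="rs1", chrom="1", pos=1000, a1="A", a2="G",
                beta=0.1, se=0.02, pval=1e-6, eaf=0.3, n=18340):
    return GwasSummaryRecord(rsid, chrom, pos, a1, a2, beta, se, pval, eaf, n)


def make_dataset(records, label="taxon", role="exposure"):
    ds = SummaryDataset(label, role)
    for rec in records:
        ds.add(rec)
    return ds


def make_harmonized(gammas, Gammas, se_gamma=0.01, se_Gamma=0.02,
                    exposure="taxon", outcome="disease"):
    """Harmonized set from parallel effect arrays (scalar SEs broadcast)."""
    gammas = np.atleast_1d(np.asarray(gammas, dtype=float))
    Gammas = np.atleast_1d(np.asarray(Gammas, dtype=float))
    sg = np.broadcast_to(np.asarray(se_gamma, dtype=float), gammas.shape)
    sG = np.broadcast_to(np.asarray(se_Gamma, dtype=float), gammas.shape)
    hset = HarmonizedSet(exposure, outcome)
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    for i, (g, G) in enumerate(zip(gammas, Gammas)):
        a1, a2 = pairs[i % 4]
        hset.instruments.append(HarmonizedInstrument(
            rsid=f"rs{i:04d}", gamma=float(g), se_gamma=float(sg[i]),
            Gamma_out=float(G), se_Gamma=float(sG[i]),
            effect_allele=a1, other_allele=a2,
        ))
    return hset


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def harmonized_factory():
    return make_harmonized
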