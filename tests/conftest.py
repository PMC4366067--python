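import numpy as np
import pytest
from hypothesis import settings

from ploidosage.core import AnalysisConfig, ExpressionTable
from ploidosage.qpcr import QpcrSample, QpcrWell

settings.register_profile("ci", derandomize=True, database=None, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def small_tables():
    """Two four-gene tables with hand-chosen abundances (powers of two)."""
    num = ExpressionTable.from_abundances(
        "num", "PAA", {"g1": 4.0, "g2": 1.0, "g3": 3.0, "g4": 0.0}
    )
    den = ExpressionTable.from_abundances(
        "den", "PA", {"g1": 2.0, "g2": 2.0, "g3": 1.0, "g4": 5.0}
    )
    return num, den


def make_plate(
    delta_cq_by_genomotype,
    targets=("rpl35",),
    reference_targets=("rpl8", "eef1a", "actb2"),
    n_biological=5,
    n_technical=3,
    baseline=22.0,
    rng=None,
    cq_noise_sd=0.0,
):
    """Build a qPCR plate where each genomotype's samples have the given
    target dCq exactly (plus optional per-well noise)."""
    samples = []
    for geno, dcq in delta_cq_by_genomotype.items():
        for b in range(1, n_biological + 1):
            wells = []
            for i, ref in enumerate(reference_targets):
                for rep in range(1, n_technical + 1):
                    cq = baseline + 0.5 * i
                    if rng is not None and cq_noise_sd:
                        cq += rng.normal(0, cq_noise_sd)
                    wells.append(QpcrWell(target=ref, template="gdna", cq=cq, replicate=rep))
            ref_mean = baseline + 0.5 * float(np.mean(range(len(reference_targets))))
            for target in targets:
                d = dcq[target] if isinstance(dcq, dict) else dcq
                for rep in range(1, n_technical + 1):
                    cq = ref_mean + d
                    if rng is not None and cq_noise_sd:
                        cq += rng.normal(0, cq_noise_sd)
                    wells.append(QpcrWell(target=target, template="cdna", cq=cq, replicate=rep))
            samples.append(QpcrSample(sample_id=f"{geno}_{b}", genomotype=geno, wells=wells))
    return samples


@pytest.fixture
def plate_factory():
    return make_plate
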