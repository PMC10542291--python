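import datetime as dt
import math

import pytest

from gcknipt.ddpcr import FetalFractionEstimate, GenotypePosterior
from gcknipt.qc import SampleRecord


def make_posterior(p_het: float, converged: bool = True) -> GenotypePosterior:
    """A posterior object with the given probability (marginals implied)."""
    p = min(max(p_het, 1e-12), 1 - 1e-12)
    return GenotypePosterior(
        p_het=p_het,
        log_marginal_nm=math.log(p),
        log_marginal_nn=math.log1p(-p),
        method="quadrature",
        converged=converged,
    )


def make_sample(
    pregnancy_id="P1",
    sample_id="S1",
    date_received=dt.date(2024, 1, 1),
    ga=16.0,
    f=0.08,
    paternal_droplets=200,
    p_het=None,
    assay_available=True,
    assay_specific=True,
    assay_preexisting=False,
    date_reported=None,
) -> SampleRecord:
    ff = FetalFractionEstimate(
        f=f, sd=0.005, method="SNP", paternal_allele_droplets=paternal_droplets
    )
    return SampleRecord(
        pregnancy_id=pregnancy_id,
        sample_id=sample_id,
        date_received=date_received,
        ga_at_receipt=ga,
        assay_available=assay_available,
        assay_specific=assay_specific,
        assay_preexisting=assay_preexisting,
        ff=ff,
        posterior=None if p_het is None else make_posterior(p_het),
        date_reported=date_reported,
    )


@pytest.fixture(scope="session")
def small_cohort():
    from gcknipt.synthetic import CohortParams, generate_cohort

    return generate_cohort(CohortParams(n_pregnancies=30, seed=20240101))
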