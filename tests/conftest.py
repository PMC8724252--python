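import numpy as np
import pytest

from adlongevity import synthetic_data as synth


@pytest.fixture(scope="session")
def panel():
    return synth.default_panel()


@pytest.fixture(scope="session")
def common_panel(panel):
    """The 38 variants surviving the MAF > 1% filter."""
    return [v for v in panel if min(v.maf_control, 1 - v.maf_control) > 0.01]


def single_variant_cohort(beta_lgv, maf=0.2, seed=0, n_cases=343, n_controls=2905):
    """One-variant cohort at the study's case/control sizes."""
    v = synth.VariantSpec(
        id="v1", chrom="1", pos=1000, effect_allele="A", other_allele="G",
        maf_control=maf, beta_ad=0.1, se_ad=0.02, beta_lgv=beta_lgv,
    )
    cfg = synth.SimulationConfig(
        variants=(v,), seed=seed, n_cases=n_cases, n_controls=n_controls
    )
    return synth.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate cohort reused by fit/bootstrap tests."""
    return single_variant_cohort(beta_lgv=-0.3, maf=0.3, seed=11)


@pytest.fixture(scope="session")
def annotation_resources():
    return synth.simulate_annotation_resources(
        synth.AnnotationResourceSpec(
            variant_ids=tuple(f"v{i:02d}" for i in range(38)), seed=5
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
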