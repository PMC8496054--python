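import warnings

import pytest

from ccapipe import synthetic


@pytest.fixture
def noiseless_field():
    """A 12-cell field with exact piecewise-constant intensities."""
    spec = synthetic.IFFieldSpec(noise_sd=0.0, seed=7)
    return synthetic.generate_if_field(spec, field_id="clean")


@pytest.fixture
def small_expression_cohort():
    """A reduced cohort (fast) with a strongly planted CIN cluster."""
    spec = synthetic.ExpressionCohortSpec(
        n_tumors=40,
        n_normals=4,
        genes=tuple(synthetic.CIN25_SIGNATURE) + tuple(f"BG_{i:03d}" for i in range(40)),
        signature=synthetic.CIN25_SIGNATURE,
        effect_log2fc=3.0,
        seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix, annotations, survival = synthetic.generate_expression_cohort(spec)
    return spec, matrix, annotations, survival
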