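import pytest

from hepachrom import experiments


@pytest.fixture(scope="session")
def trained_bundle():
    """One reduced-scale trained regressor shared by the end-to-end tests.

    Total bilirubin, 6 levels x 50 originals x (1 + 2 augmented) = 900
    images at 32x32 on the reference device, 80:20 level-stratified split,
    up to 40 epochs with best-validation checkpointing. Deterministic for
    the fixed seed.
    """
    return experiments.run_training("total-bilirubin", seed=20260921, image_size=32)


@pytest.fixture(scope="session")
def regressor(trained_bundle):
    return trained_bundle.regressor
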