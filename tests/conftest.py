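import pytest

from sisaflux.isotopes import na_correct_image
from sisaflux.msi_io import IonImageStack
from sisaflux.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """24x16 two-region phantom at 1% multiplicative noise, with unlabeled twin."""
    spec = PhantomSpec(width=24, height=16, fractional_noise_sd=0.01, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(width=20, height=14, fractional_noise_sd=0.0, seed=5)
    return generate_phantom(spec)


def na_corrected_stack(stack: IonImageStack, p13: float = 0.0107,
                       masks: dict = None) -> IonImageStack:
    """NA-correct every target of a stack (optionally with per-target channel masks)."""
    corrected = stack.tensor.copy()
    for t in stack.targets:
        sl = stack.channel_slice(t.name)
        mask = (masks or {}).get(t.name)
        corrected[sl] = na_correct_image(stack.tensor[sl], p13=p13, mask=mask)
    return IonImageStack(targets=stack.targets, tensor=corrected, grid=stack.grid,
                         labeled_flag=stack.labeled_flag)


@pytest.fixture(scope="session")
def small_corrected(small_phantom):
    return na_corrected_stack(small_phantom.labeled)
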