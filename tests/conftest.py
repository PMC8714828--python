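import numpy as np
import pytest

from topoivim.ivim import AcquisitionScheme, IVIMParams, VoxelSignal, ivim_signal
from topoivim.phantom import ivim_bvalues


@pytest.fixture(scope="session")
def scheme54() -> AcquisitionScheme:
    return AcquisitionScheme(ivim_bvalues(54))


@pytest.fixture(scope="session")
def scheme27() -> AcquisitionScheme:
    return AcquisitionScheme(ivim_bvalues(27))


@pytest.fixture()
def noiseless_voxel(scheme54):
    """A well-posed voxel: moderate perfusion, well-separated rates."""
    params = IVIMParams(f=0.349, D=0.001, Dstar=0.04)
    return params, VoxelSignal(ivim_signal(params, scheme54), scheme54)


def random_params(rng, f_range=(0.0, 1.0), D_range=(1e-5, 0.02),
                  Dstar_range=(1e-5, 0.2)) -> IVIMParams:
    return IVIMParams(
        f=float(rng.uniform(*f_range)),
        D=float(rng.uniform(*D_range)),
        Dstar=float(rng.uniform(*Dstar_range)),
    )
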