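import numpy as np
import pytest

from mhnet.network import NetworkConfig
from mhnet.synthetic import PhantomSpec, make_pair
from mhnet.volumes import DisplacementField, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    return Volume(rng.random((8, 8, 8), dtype=np.float32))


@pytest.fixture
def zero_field():
    return DisplacementField(np.zeros((3, 8, 8, 8), dtype=np.float32))


@pytest.fixture
def tiny_net_config():
    """A narrow network for fast structural tests."""
    return NetworkConfig(enc_channels=(4, 8, 8, 8), dec_channels=(8, 8, 8, 4))


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic synthetic registration case at 32^3."""
    return make_pair(PhantomSpec(seed=7))


def trilinear_oracle(img, u, mode="clamp"):
    """Explicit-loop trilinear warp: for each voxel, sum over the 8 integer
    neighbours of i + u(i) with weights prod_d (1 - |j_d - i'_d|)."""
    X, Y, Z = img.shape
    dims = (X, Y, Z)
    out = np.zeros_like(img, dtype=np.float64)
    for x in range(X):
        for y in range(Y):
            for z in range(Z):
                p = [x + u[0, x, y, z], y + u[1, x, y, z], z + u[2, x, y, z]]
                if mode == "clamp":
                    p = [min(max(p[d], 0.0), dims[d] - 1.0) for d in range(3)]
                base = [int(np.floor(p[d])) for d in range(3)]
                acc = 0.0
                for dx in (0, 1):
                    for dy in (0, 1):
                        for dz in (0, 1):
                            j = (base[0] + dx, base[1] + dy, base[2] + dz)
                            w = 1.0
                            for d in range(3):
                                w *= max(0.0, 1.0 - abs(j[d] - p[d]))
                            if w == 0.0:
                                continue
                            if mode == "zeros" and any(
                                j[d] < 0 or j[d] >= dims[d] for d in range(3)
                            ):
                                continue
                            jj = tuple(
                                min(max(j[d], 0), dims[d] - 1) for d in range(3)
                            )
                            acc += w * img[jj]
                out[x, y, z] = acc
    return out


def numeric_grad(fn, x, eps=1e-5):
    """Central finite-difference gradient of scalar fn at array x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return g
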