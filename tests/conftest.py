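import numpy as np
import pytest

from notchcis.kinetics import KineticParams
from notchcis.synthetic import GeneratorConfig, render_synthetic_field


@pytest.fixture
def gen_config() -> GeneratorConfig:
    """Small, fast generator configuration for round-trip tests."""
    return GeneratorConfig(n_cells_per_level=200, seed=11)


@pytest.fixture
def qss_params() -> KineticParams:
    """Generic parameters with QSS comfortably valid."""
    return KineticParams(beta_N=1.0, beta_D=0.8, gamma_N=0.1, gamma_D=0.15,
                         kC_plus=2.0, kC_minus=3.0, kI=5.0,
                         kD_plus=1.5, kD_minus=4.0, kS=1.0)


def make_disjoint_cells(n, rng, shape=(512, 512), r_range=(8, 14),
                        margin=12, channels=("cyto", "ligand", "avail")):
    """Random non-overlapping disks with known intensities."""
    cells = []
    while len(cells) < n:
        c = (rng.uniform(20, shape[0] - 20), rng.uniform(20, shape[1] - 20))
        r = rng.uniform(*r_range)
        if all(np.hypot(c[0] - o["center"][0], c[1] - o["center"][1])
               > r + o["radius"] + margin for o in cells):
            intensity = {ch: (300.0 if ch == "cyto" else float(rng.uniform(50, 500)))
                         for ch in channels}
            cells.append({"center": c, "radius": r, "intensity": intensity})
    return cells


@pytest.fixture
def synthetic_field():
    """50-cell field with gradient background and read noise, plus truth."""
    rng = np.random.default_rng(1)
    cells = make_disjoint_cells(50, rng)
    img, labels, truth = render_synthetic_field(
        cells, (512, 512), channels=("cyto", "ligand", "avail"),
        background_model={"kind": "gradient", "low": 20, "high": 120, "axis": 0},
        noise_sd=5.0, seed=2)
    return img, labels, truth
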