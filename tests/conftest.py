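import numpy as np
import pytest

from glucnmr import synthetic
from glucnmr.sequences import GLUC_DISULFIDES
from glucnmr.structure_io import Atom, Model, ResidueRecord


@pytest.fixture(scope="session")
def gluc_spec():
    return synthetic.gluc_like_ensemble_spec(seed=1)


@pytest.fixture(scope="session")
def gluc_ensemble(gluc_spec):
    """A study-condition synthetic ensemble: 19 models, 168 residues, 5 bonds."""
    return synthetic.make_ensemble(gluc_spec)


@pytest.fixture(scope="session")
def planted_pairs():
    return set(GLUC_DISULFIDES)


@pytest.fixture
def tiny_ensemble():
    """3 identical 4-residue models, poly-Ala plus one Cys pair, CA+SG only."""
    spec = synthetic.EnsembleSpec(
        n_models=3,
        n_residues=10,
        rigid_ranges=((1, 10),),
        flexible_ranges=(),
        planted_bonds=((2, 8, 1.0),),
        sigma_core=0.0,
        seed=0,
    )
    return synthetic.make_ensemble(spec)


def make_shell_model(r_shell=9.1, spacing=1.2, bore=None):
    """Hollow sphere of carbon pseudo-atoms enclosing an empty ball.

    With Bondi C radius 1.70 and probe 1.4 the accessible interior is a
    sphere of radius r_shell - 3.1.  `bore` drills a hole of that radius
    around the +z pole.
    """
    npts = int(4 * np.pi * r_shell**2 / spacing**2)
    idx = np.arange(npts) + 0.5
    phi = np.arccos(1 - 2 * idx / npts)
    theta = np.pi * (1 + 5**0.5) * idx
    pts = r_shell * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    if bore is not None:
        keep = ~((pts[:, 2] > 0) & (np.linalg.norm(pts[:, :2], axis=1) < bore))
        pts = pts[keep]
    residues = [
        ResidueRecord(seq_id=i + 1, aa="G", atoms=[Atom("CA", "C", p)])
        for i, p in enumerate(pts)
    ]
    return Model(model_id=1, residues=residues)


@pytest.fixture(scope="session")
def shell_model():
    return make_shell_model()
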