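import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def tiny_complex_pdb(tmp_path):
    """Minimal protonated complex: one VAL, one GLY, one 3-proton ligand."""
    from nmr2dock.structures import Atom, write_pdb

    receptor = [
        Atom(1, "VAL", "CA", "C", np.array([5.0, 0.0, 0.0])),
        Atom(1, "VAL", "CB", "C", np.array([4.5, 1.0, 0.0])),
        Atom(1, "VAL", "CG1", "C", np.array([4.0, 2.0, 1.0])),
        Atom(1, "VAL", "CG2", "C", np.array([5.5, 2.0, -1.0])),
        Atom(2, "GLY", "CA", "C", np.array([-5.0, 0.0, 0.0])),
    ]
    ligand = [
        Atom(10, "LIG", "C1", "C", np.array([0.0, 0.0, 0.0]), hetero=True),
        Atom(10, "LIG", "C2", "C", np.array([1.4, 0.0, 0.0]), hetero=True),
        Atom(10, "LIG", "H1", "H", np.array([-0.6, 0.9, 0.0]), hetero=True),
        Atom(10, "LIG", "H2", "H", np.array([1.0, 1.0, 0.3]), hetero=True),
        Atom(10, "LIG", "H3", "H", np.array([2.4, 0.0, 0.0]), hetero=True),
    ]
    path = tmp_path / "tiny.pdb"
    write_pdb(path, receptor, [ligand])
    return path


@pytest.fixture(scope="session")
def fast_config():
    """Light engine configuration for unit-level cases."""
    from nmr2dock.engine import EngineConfig

    def factory(seed=1, **kw):
        defaults = dict(n_restarts=3, sa_steps=80)
        defaults.update(kw)
        return EngineConfig(seed=seed, **defaults)

    return factory
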