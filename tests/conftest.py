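import numpy as np
import pytest

import nucbreathe as nb


@pytest.fixture(scope="session")
def spec():
    return nb.SyntheticSpec()


@pytest.fixture(scope="session")
def ideal(spec):
    """Closed, jitter-free idealized nucleosome + ground truth."""
    return nb.make_ideal_nucleosome(spec)


@pytest.fixture(scope="session")
def nuc(ideal, spec):
    return nb.annotate_synthetic(ideal[0], spec)


@pytest.fixture(scope="session")
def step_traj(spec):
    """60 frames: out-of-plane step 0 -> 30 deg on the 3' arm at frame 30."""
    n = 60
    ang = np.zeros((n, 2))
    ang[30:, 0] = 30.0
    return nb.make_breathing_trajectory(
        spec, {"3p": ang, "5p": np.zeros((n, 2))}, seed=3)


@pytest.fixture(scope="session")
def scenario():
    """Coupled tail-release / arm-opening trajectory (tail leads by 10)."""
    traj, truth = nb.coupled_opening_scenario(
        n_frames=200, switch_frame=100, lag=10, seed=2,
        spec=nb.SyntheticSpec(seed=2))
    nuc = nb.annotate_synthetic(traj.topology, nb.SyntheticSpec(seed=2))
    return traj, truth, nuc


def make_bead_nucleosome(n_bp, histones=None, seed=0):
    """Minimal random-coordinate structure: 1 bead per DNA nucleotide plus
    optional single-bead histone chains, for annotation-level tests."""
    rng = np.random.default_rng(seed)
    names, resnames, resids, chains, elements = [], [], [], [], []
    for chain in ("I", "J"):
        for r in range(1, n_bp + 1):
            names.append("C1'")
            resnames.append("DA")
            resids.append(r)
            chains.append(chain)
            elements.append("C")
    for chain, (htype, n_res) in (histones or {}).items():
        for r in range(1, n_res + 1):
            names.append("CA")
            resnames.append("GLY")
            resids.append(r)
            chains.append(chain)
            elements.append("C")
    n = len(names)
    return nb.StructureModel(
        atom_names=np.array(names),
        residue_names=np.array(resnames),
        residue_indices=np.array(resids),
        chain_ids=np.array(chains),
        elements=np.array(elements),
        masses=np.full(n, 12.011),
        coords=rng.uniform(0, 50, (1, n, 3)),
    )
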