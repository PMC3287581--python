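import numpy as np
import pytest

from csmkit import ChainCoordinates, CentroidScheme, CutoffGrid


def atom_line(
    serial,
    name,
    resname,
    chain,
    resseq,
    x,
    y,
    z,
    altloc=" ",
    occ=1.00,
    icode=" ",
    element=None,
    record="ATOM",
):
    """One fixed-width PDB coordinate record."""
    element = element or name[0]
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{altloc:1s}{resname:>3s} {chain:1s}"
        f"{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def pdb_text(lines):
    return "\n".join(list(lines) + ["END"]) + "\n"


@pytest.fixture
def default_grid():
    return CutoffGrid()


@pytest.fixture
def chain_factory():
    """Build a ChainCoordinates directly from a point array."""

    def _make(points, structure_id="chain", chain_id="A"):
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        rids = [(chain_id, i + 1, "") for i in range(len(points))]
        return ChainCoordinates(structure_id, chain_id, CentroidScheme.CA, points, rids)

    return _make


@pytest.fixture
def random_chain_factory(chain_factory):
    """Seeded random point clouds in a 17 Å box (diagonal ≈ 29.4 Å < 30 Å)."""

    def _make(n, seed, structure_id="chain", box=17.0):
        rng = np.random.default_rng(seed)
        return chain_factory(rng.uniform(0, box, size=(n, 3)), structure_id)

    return _make


def naive_contact_counts(points, thresholds, tol=1e-9):
    """Independent oracle: explicit double loop over residue pairs."""
    points = np.asarray(points, dtype=float)
    dists = []
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            dists.append(float(np.linalg.norm(points[i] - points[j])))
    dists = np.asarray(dists)
    if len(dists) == 0:
        return np.zeros(len(thresholds), dtype=int)
    return (dists[None, :] <= np.asarray(thresholds)[:, None] + tol).sum(axis=1)
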