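"""Read PDB coordinate files into ordered residue-centroid chains.

Preprocessing rules follow standard structural-bioinformatics practice for
distance-signature work: only the first model of multi-model (NMR) entries is
used, each chain becomes a separate coordinate set, and every residue is
represented by a single centroid point — its alpha carbon by default, or
optionally the beta carbon or the last heavy atom (LHA) of the side chain.

Parsing is delegated to :mod:`gemmi`; this module owns the centroid schemes,
alternate-location resolution and the filtering contracts built on top.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import gemmi
import numpy as np

from .errors import EmptyStructureError, PDBFormatError

logger = logging.getLogger(__name__)

#: Backbone atom names; everything else that is heavy counts as side chain.
_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})


class CentroidScheme(str, Enum):
    """Which atom stands in for a residue in distance calculations."""

    CA = "CA"
    CB = "CB"
    LHA = "LHA"


@dataclass(frozen=True)
class ResidueAtoms:
    """All ATOM records of one residue, in file order.

    ``residue_id`` is (chain id, sequence number, insertion code); insertion
    codes participate in identity.  Each atom tuple is
    (name, x, y, z, altloc, occupancy, is_hydrogen).
    """

    residue_name: str
    residue_id: tuple[str, int, str]
    atoms: tuple[tuple[str, float, float, float, str, float, bool], ...]


@dataclass
class ChainCoordinates:
    """Ordered residue centroids of one protein chain or domain."""

    structure_id: str
    chain_id: str
    centroid_scheme: CentroidScheme
    points: np.ndarray  # (n, 3) float array, Å
    residue_ids: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.residue_ids) != len(self.points):
            raise ValueError("points and residue_ids must be parallel")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_residues(self) -> int:
        return len(self.points)


def _select_altloc(atoms: Sequence[tuple]) -> tuple | None:
    """Pick one atom among alternate locations of the same name.

    Highest occupancy wins; ties go to the first in file order.
    """
    if not atoms:
        return None
    best = atoms[0]
    for atom in atoms[1:]:
        if atom[5] > best[5]:
            best = atom
    return best


def _named_atom(residue: ResidueAtoms, name: str) -> tuple | None:
    return _select_altloc([a for a in residue.atoms if a[0] == name])


def extract_centroid(
    residue: ResidueAtoms, scheme: CentroidScheme | str
) -> np.ndarray | None:
    """Return the centroid point of ``residue`` under ``scheme``, or None.

    CA: the alpha carbon.  CB: the beta carbon, falling back to CA for
    glycine (which has no side chain).  LHA: the last heavy side-chain atom
    in file order, falling back to CA when there is no side chain.
    Returns None when the required atom (after fallback) is absent.
    """
    scheme = CentroidScheme(scheme)
    if scheme is CentroidScheme.CA:
        atom = _named_atom(residue, "CA")
    elif scheme is CentroidScheme.CB:
        atom = _named_atom(residue, "CB")
        if atom is None and residue.residue_name == "GLY":
            atom = _named_atom(residue, "CA")
    else:  # LHA
        side = [a for a in residue.atoms if a[0] not in _BACKBONE and not a[6]]
        # altloc duplicates: keep the last *name* in file order, then resolve
        atom = None
        if side:
            last_name = side[-1][0]
            atom = _select_altloc([a for a in side if a[0] == last_name])
        if atom is None:
            atom = _named_atom(residue, "CA")
    if atom is None:
        return None
    return np.array(atom[1:4], dtype=float)


def _as_pdb_text(source: Union[str, os.PathLike, TextIO]) -> tuple[str, str | None]:
    """Return (pdb text, inferred structure id or None)."""
    if hasattr(source, "read"):
        return source.read(), None
    if isinstance(source, os.PathLike):
        p = Path(source)
        return p.read_text(), p.stem
    if isinstance(source, str):
        if "\n" in source or source.lstrip().startswith(("ATOM", "HETATM", "MODEL", "HEADER")):
            return source, None
        p = Path(source)
        if p.exists():
            return p.read_text(), p.stem
        raise PDBFormatError(f"no such file and not PDB text: {source!r}")
    raise TypeError(f"unsupported source type: {type(source)!r}")


def _residues_from_gemmi(chain: gemmi.Chain) -> list[ResidueAtoms]:
    out = []
    for res in chain:
        if res.het_flag != "A":  # HETATM-only entities (waters, ligands) excluded
            continue
        atoms = tuple(
            (
                a.name,
                a.pos.x,
                a.pos.y,
                a.pos.z,
                a.altloc if a.altloc != "\0" else "",
                a.occ,
                a.element.is_hydrogen,
            )
            for a in res
        )
        rid = (chain.name, res.seqid.num, res.seqid.icode.strip())
        out.append(ResidueAtoms(res.name, rid, atoms))
    return out


def read_pdb_coordinates(
    source: Union[str, os.PathLike, TextIO],
    scheme: CentroidScheme | str = CentroidScheme.CA,
    first_model_only: bool = True,
    structure_id: str | None = None,
) -> list[ChainCoordinates]:
    """Parse PDB-format text into one ChainCoordinates per chain.

    ``source`` may be a path, an open text stream, or PDB text itself.
    Only MODEL 1 is used when ``first_model_only`` (the default) and the
    file holds several models.  Residues lacking the centroid atom under
    ``scheme`` are skipped with a logged warning; non-standard residues
    deposited as ATOM records (e.g. MSE) are accepted.

    Raises :class:`PDBFormatError` for unparseable input and
    :class:`EmptyStructureError` when no residue yields a centroid.
    """
    scheme = CentroidScheme(scheme)
    text, inferred_id = _as_pdb_text(source)
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"could not parse PDB text: {exc}") from exc
    if len(structure) == 0:
        raise EmptyStructureError("no models in PDB input")

    sid = structure_id or inferred_id or structure.name.strip().lower() or "structure"
    models = [structure[0]] if first_model_only else list(structure)

    chains: list[ChainCoordinates] = []
    for model in models:
        for chain in model:
            points, rids = [], []
            for residue in _residues_from_gemmi(chain):
                centroid = extract_centroid(residue, scheme)
                if centroid is None:
                    logger.warning(
                        "%s chain %s: residue %s %s lacks %s centroid; skipped",
                        sid, chain.name, residue.residue_name,
                        residue.residue_id[1], scheme.value,
                    )
                    continue
                points.append(centroid)
                rids.append(residue.residue_id)
            if points:
                chains.append(
                    ChainCoordinates(
                        structure_id=sid,
                        chain_id=chain.name,
                        centroid_scheme=scheme,
                        points=np.array(points),
                        residue_ids=rids,
                    )
                )
        if first_model_only:
            break
    if not chains:
        raise EmptyStructureError(f"{sid}: no extractable residues")
    return chains


def filter_chain_length(
    chains: Iterable[ChainCoordinates], min_residues: int
) -> list[ChainCoordinates]:
    """Keep chains with at least ``min_residues`` centroids, order preserved."""
    if min_residues < 1:
        raise ValueError("min_residues must be >= 1")
    return [c for c in chains if len(c) >= min_residues]


def chain_to_pdb(chain: ChainCoordinates, residue_name: str = "ALA") -> str:
    """Render a centroid chain as minimal PDB text (one CA record per residue)."""
    atom_name = "CA"
    lines = []
    for i, (pt, rid) in enumerate(zip(chain.points, chain.residue_ids), start=1):
        cid, seq, icode = rid
        lines.append(
            f"ATOM  {i:5d}  {atom_name:<3s}{residue_name:>4s} {cid[:1] or 'A'}"
            f"{seq:4d}{(icode or ' '):1s}   "
            f"{pt[0]:8.3f}{pt[1]:8.3f}{pt[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {'C':>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(chain: ChainCoordinates, path: Union[str, os.PathLike]) -> None:
    Path(path).write_text(chain_to_pdb(chain))


def write_centroid_tsv(
    chains: Iterable[ChainCoordinates], stream: Union[TextIO, str, os.PathLike]
) -> None:
    """Dump centroids as TSV (structure_id, chain_id, residue_id, x, y, z)."""
    close = False
    if not hasattr(stream, "write"):
        stream = open(stream, "w")
        close = True
    try:
        stream.write("structure_id\tchain_id\tresidue_id\tx\ty\tz\n")
        for c in chains:
            for pt, rid in zip(c.points, c.residue_ids):
                rid_txt = f"{rid[0]}{rid[1]}{rid[2]}"
                stream.write(
                    f"{c.structure_id}\t{c.chain_id}\t{rid_txt}"
                    f"\t{pt[0]:.3f}\t{pt[1]:.3f}\t{pt[2]:.3f}\n"
                )
    finally:
        if close:
            stream.close()
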