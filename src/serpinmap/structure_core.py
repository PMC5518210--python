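"""Structure I/O, numbering conventions, accessibility and superposition.

These are the primitives shared by the structural stages: a residue-indexed
``Structure`` container (backed by a :class:`biotite.structure.AtomArray`),
the mature/precursor residue-numbering conversion used for AAT, relative
side-chain solvent accessibility by Shrake--Rupley point sampling, and
closed-form Kabsch rigid-body superposition.

Numbering conventions
---------------------
Mature ("conventional AAT") numbering counts from the first residue of the
secreted protein; precursor (HGVS p.) numbering additionally counts the
24-residue signal peptide.  The canonical worked example is the helix-C
variant E75V, which is p.Glu99Val in precursor numbering; all analyses in
this package operate in mature numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as _cif_get_structure

#: Length of the AAT signal peptide separating precursor from mature numbering.
SIGNAL_PEPTIDE_OFFSET = 24

#: Backbone heavy-atom names (side chain = everything else except hydrogens).
BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

# Van der Waals radii by element (Å), Bondi set; used for SASA sampling.
_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


class StructureParseError(ValueError):
    """Raised when a structure file violates the container invariants."""


@dataclass
class Structure:
    """A single protein chain with author residue numbering preserved.

    Parameters
    ----------
    atoms
        Biotite atom array; ``res_id`` carries the author numbering.
    numbering
        Either ``"mature"`` or ``"precursor"`` (see module docstring).
    coord
        Optional double-precision coordinates overriding ``atoms.coord``.
        Biotite stores single precision, which is fine for I/O and surface
        sampling but would contaminate superposition identities at the
        1e-8 Å level; all geometry in this package therefore reads from
        this float64 array.
    """

    atoms: struc.AtomArray
    numbering: str = "mature"
    coord: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.numbering not in ("mature", "precursor"):
            raise ValueError(f"unknown numbering convention {self.numbering!r}")
        n = self.atoms.array_length()
        if self.coord is None:
            self.coord = np.asarray(self.atoms.coord, dtype=float)
        else:
            self.coord = np.asarray(self.coord, dtype=float)
            if self.coord.shape != (n, 3):
                raise ValueError(
                    f"coord shape {self.coord.shape} does not match "
                    f"{n} atoms"
                )
            self.atoms = self.atoms.copy()
            self.atoms.coord = self.coord  # downcast copy for biotite ops
        if not np.all(np.isfinite(self.coord)):
            raise StructureParseError("non-finite coordinates in structure")
        _validate_residue_uniqueness(self.atoms)

    # -- residue-level views -------------------------------------------------

    @property
    def residue_ids(self) -> np.ndarray:
        """Author residue indices, one per residue, in file order."""
        return np.unique(self.atoms.res_id)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def ca_mask(self) -> np.ndarray:
        return self.atoms.atom_name == "CA"

    def ca_coordinates(self, residues: np.ndarray | None = None) -> np.ndarray:
        """Cα coordinates for ``residues`` (default: all, sorted by index)."""
        mask = self.ca_mask()
        ids = self.atoms.res_id[mask]
        coords = self.coord[mask]
        order = np.argsort(ids, kind="stable")
        ids = ids[order]
        coords = coords[order]
        if residues is None:
            return coords
        index = {r: i for i, r in enumerate(ids)}
        missing = [r for r in residues if r not in index]
        if missing:
            raise KeyError(f"residues without Cα atom: {missing}")
        return coords[[index[r] for r in residues]]

    def residue_name(self, res_id: int) -> str:
        names = self.atoms.res_name[self.atoms.res_id == res_id]
        if len(names) == 0:
            raise KeyError(f"residue {res_id} not in structure")
        return str(names[0])

    def residue_atoms(self, res_id: int) -> struc.AtomArray:
        return self.atoms[self.atoms.res_id == res_id]


def _validate_residue_uniqueness(atoms: struc.AtomArray) -> None:
    """Each (chain, residue index) maps to one residue with at most one Cα."""
    for chain in np.unique(atoms.chain_id):
        sub = atoms[atoms.chain_id == chain]
        for rid in np.unique(sub.res_id):
            res = sub[sub.res_id == rid]
            names = set(res.res_name)
            if len(names) > 1:
                raise StructureParseError(
                    f"residue index {rid} in chain {chain!r} maps to multiple "
                    f"residue types {sorted(names)} (insertion codes are not "
                    f"supported)"
                )
            n_ca = int(np.count_nonzero(res.atom_name == "CA"))
            if n_ca > 1:
                raise StructureParseError(
                    f"residue {rid} in chain {chain!r} has {n_ca} Cα atoms"
                )


def _infer_missing_elements(atoms: struc.AtomArray) -> struc.AtomArray:
    """Fill empty element fields from the atom-name prefix, with a warning."""
    elements = np.asarray(atoms.element, dtype="U2")
    missing = elements == ""
    if np.any(missing):
        inferred = []
        for name in atoms.atom_name[missing]:
            stripped = name.lstrip("0123456789")
            inferred.append(stripped[:1].upper() if stripped else "C")
        elements[missing] = inferred
        warnings.warn(
            f"inferred element for {int(missing.sum())} atoms from atom names",
            stacklevel=3,
        )
        atoms = atoms.copy()
        atoms.element = elements
    return atoms


def read_structure(
    path: str | Path,
    format: str | None = None,
    chain: str | None = None,
    numbering: str = "mature",
) -> Structure:
    """Read a protein chain from a PDB or mmCIF file.

    Only the first model of a multi-model file is read (trajectory ensembles
    are handled by :mod:`serpinmap.trajectory_analysis`).  By default the
    first protein chain is returned; pass ``chain`` to select another.

    Raises
    ------
    StructureParseError
        On malformed files, empty chains, or duplicated residue indices.
    """
    path = Path(path)
    if format is None:
        format = "mmCIF" if path.suffix.lower() in (".cif", ".mmcif") else "PDB"
    try:
        if format == "PDB":
            atoms = PDBFile.read(str(path)).get_structure(model=1)
        elif format == "mmCIF":
            atoms = _cif_get_structure(CIFFile.read(str(path)), model=1)
        else:
            raise ValueError(f"unknown format {format!r}")
    except ValueError:
        raise
    except Exception as exc:  # biotite raises format-specific errors
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise StructureParseError(f"{path}: no protein atoms found")
    if chain is None:
        chain = str(atoms.chain_id[0])
    atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise StructureParseError(f"{path}: chain {chain!r} is empty")
    atoms = _infer_missing_elements(atoms)
    return Structure(atoms=atoms, numbering=numbering)


def convert_numbering(index: int, direction: str) -> int:
    """Convert a residue index between mature and precursor numbering.

    ``mature_to_precursor`` adds the signal-peptide offset (24), so mature
    75 (the Trento site E75V) becomes precursor 99 (p.Glu99Val); the inverse
    subtracts it.  Raises ``ValueError`` if the input or result leaves the
    valid range (≥ 1).
    """
    if index < 1:
        raise ValueError(f"residue index must be ≥ 1, got {index}")
    if direction == "mature_to_precursor":
        return index + SIGNAL_PEPTIDE_OFFSET
    if direction == "precursor_to_mature":
        result = index - SIGNAL_PEPTIDE_OFFSET
        if result < 1:
            raise ValueError(
                f"precursor index {index} lies within the signal peptide"
            )
        return result
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class SasaProfile:
    """Per-residue relative side-chain solvent accessibility.

    ``relative[i]`` is the side-chain SASA of residue ``residue_ids[i]`` in
    the full structure divided by the side-chain SASA of the same residue
    extracted in isolation (its maximal exposure), clipped to [0, 1].  For
    glycine the Cα atom stands in for the side chain.
    """

    residue_ids: np.ndarray
    relative: np.ndarray
    probe_radius: float
    sidechain_sasa: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if np.any(self.relative < 0) or np.any(self.relative > 1):
            raise ValueError("relative accessibilities must lie in [0, 1]")

    def as_dict(self) -> dict[int, float]:
        return {int(r): float(v) for r, v in zip(self.residue_ids, self.relative)}


def _check_elements(atoms: struc.AtomArray) -> None:
    unknown = [
        f"{n} (element {e!r})"
        for n, e in zip(atoms.atom_name, atoms.element)
        if e.upper() not in _VDW_RADII
    ]
    if unknown:
        raise ValueError(f"no van der Waals radius for atoms: {unknown[:5]}")


def atom_sasa(
    atoms: struc.AtomArray, probe_radius: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom SASA (Å²) by Shrake--Rupley sampling over heavy atoms.

    Hydrogens are excluded from both the surface and the occlusion set;
    their entries are 0.
    """
    heavy = atoms.element != "H"
    _check_elements(atoms[heavy])
    # NaN radius removes hydrogens from the occlusion set as well
    radii = np.array(
        [_VDW_RADII.get(e.upper(), np.nan) for e in atoms.element]
    )
    values = struc.sasa(
        atoms,
        probe_radius=probe_radius,
        atom_filter=heavy,
        ignore_ions=False,
        point_number=n_points,
        vdw_radii=radii,
    )
    return np.nan_to_num(values, nan=0.0)


def _sidechain_mask(atoms: struc.AtomArray) -> np.ndarray:
    """Side-chain heavy atoms; Cα is the glycine placeholder."""
    heavy = atoms.element != "H"
    side = heavy & ~np.isin(atoms.atom_name, BACKBONE_ATOMS)
    # residues with no side-chain heavy atom (GLY or backbone-only models):
    # fall back to Cα so every residue has a defined accessibility
    for rid in np.unique(atoms.res_id):
        res = atoms.res_id == rid
        if not np.any(side & res):
            side |= res & (atoms.atom_name == "CA")
    return side


def compute_sasa(
    structure: Structure, probe_radius: float = 1.4, n_points: int = 960
) -> SasaProfile:
    """Relative side-chain accessibility for every residue.

    The reference (maximal) exposure of each residue is computed by
    evaluating the same side-chain SASA on the residue extracted alone,
    so an isolated residue scores exactly 1 and a fully occluded one 0.
    """
    atoms = structure.atoms
    per_atom = atom_sasa(atoms, probe_radius, n_points)
    side = _sidechain_mask(atoms)

    residue_ids = structure.residue_ids
    context = np.empty(len(residue_ids))
    reference = np.empty(len(residue_ids))
    for i, rid in enumerate(residue_ids):
        res_mask = atoms.res_id == rid
        context[i] = per_atom[res_mask & side].sum()
        isolated = atoms[res_mask]
        iso_sasa = atom_sasa(isolated, probe_radius, n_points)
        reference[i] = iso_sasa[side[res_mask]].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        relative = np.where(reference > 0, context / reference, 0.0)
    return SasaProfile(
        residue_ids=residue_ids,
        relative=np.clip(relative, 0.0, 1.0),
        probe_radius=probe_radius,
        sidechain_sasa=context,
    )


def surface_residues(profile: SasaProfile, threshold: float = 0.10) -> set[int]:
    """Residues whose relative side-chain accessibility is ≥ ``threshold``.

    The 10% default is a conventional exposure cutoff for calling a residue
    surface-accessible.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    keep = profile.relative >= threshold
    return {int(r) for r in profile.residue_ids[keep]}


@dataclass
class SuperpositionResult:
    """Optimal rigid-body superposition of one coordinate set onto another.

    ``rotation`` @ (coords_b − centroid_b) + centroid_a approximates
    coords_a with the minimum possible RMSD over all proper rigid
    transforms of the given pairing; reflections are excluded
    (det(rotation) = +1).
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Closed-form Kabsch solution via SVD of the cross-covariance matrix,
    with the sign of the smallest singular vector corrected so that the
    rotation is proper (no reflection).  Requires ≥ 3 non-collinear paired
    points.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(
            f"paired (n, 3) arrays required, got {a.shape} and {b.shape}"
        )
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"at least 3 atom pairs required, got {n}")
    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    da = a - cen_a
    db = b - cen_b
    cov = db.T @ da
    u, s, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rotation = vt.T @ d @ u.T
    fitted = db @ rotation.T + cen_a
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - a) ** 2, axis=1))))
    translation = cen_a - rotation @ cen_b
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=rmsd, n_atoms=n
    )
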