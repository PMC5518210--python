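"""Surface-patch structural divergence mapping between two conformers.

For each surface-accessible residue of a reference structure, an
epitope-sized patch is defined as all residues whose Cα lies within a fixed
radius (default 8 Å) of the central residue's Cα.  The patch is optimally
superposed (Kabsch, Cα-only by default) onto the identical residues of an
alternate structure, and the resulting Cα RMSD is mapped back onto the
central residue.  The per-residue map localises where two conformers — e.g.
wild-type AAT and a polymer-unreactive stabilised mutant — diverge at the
length scale of an antibody footprint.

Residues whose patch overlaps a glycan attachment site are masked: a
glycan-binding-competent antibody's epitope cannot overlap those positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from serpinmap.structure_core import (
    Structure,
    SuperpositionResult,
    compute_sasa,
    kabsch_superpose,
    surface_residues,
)

#: Curated default glycan attachment sites of AAT (mature numbering).
#: N-linked sequons at Asn46, Asn83 and Asn247.
AAT_GLYCAN_SITES = frozenset({46, 83, 247})

#: Epitope-sized patch radius in Å.
DEFAULT_PATCH_RADIUS = 8.0

SCORED = "scored"
NOT_SURFACE = "not_surface"
GLYCAN_MASKED = "glycan_masked"
UNALIGNABLE = "unalignable"

_FLAGS = (SCORED, NOT_SURFACE, GLYCAN_MASKED, UNALIGNABLE)


@dataclass(frozen=True)
class ResiduePatch:
    """All residues with a Cα within ``radius`` of the center's Cα."""

    center: int
    members: frozenset[int]
    radius: float

    def __post_init__(self) -> None:
        if self.center not in self.members:
            raise ValueError("patch center must be a member of the patch")


@dataclass
class DivergenceMap:
    """Per-residue patch RMSD with status flags.

    Every residue of the reference structure appears exactly once with
    status ``scored`` (value in Å), ``not_surface``, ``glycan_masked`` or
    ``unalignable``.
    """

    residue_ids: np.ndarray
    values: np.ndarray  # NaN where not scored
    status: np.ndarray  # one of _FLAGS per residue

    def __post_init__(self) -> None:
        bad = set(self.status) - set(_FLAGS)
        if bad:
            raise ValueError(f"unknown status flags {bad}")
        scored = self.status == SCORED
        if np.any(self.values[scored] < 0):
            raise ValueError("scored patch RMSD must be ≥ 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residue_ids,
                "status": self.status,
                "patch_rmsd": self.values,
            }
        ).sort_values("residue", ignore_index=True)

    def scored_series(self) -> pd.Series:
        frame = self.to_frame()
        frame = frame[frame.status == SCORED]
        return pd.Series(
            frame.patch_rmsd.values, index=frame.residue.values, name="patch_rmsd"
        )


def define_patch(
    reference: Structure, center: int, radius: float = DEFAULT_PATCH_RADIUS
) -> ResiduePatch:
    """Epitope-sized patch around ``center`` by Euclidean Cα–Cα distance."""
    if radius <= 0:
        raise ValueError("patch radius must be positive")
    mask = reference.ca_mask()
    ca_ids = reference.atoms.res_id[mask]
    ca_coord = reference.coord[mask]
    center_coord = ca_coord[ca_ids == center]
    if len(center_coord) == 0:
        raise ValueError(f"residue {center} has no Cα atom")
    dist = np.linalg.norm(ca_coord - center_coord[0], axis=1)
    members = frozenset(int(r) for r in ca_ids[dist <= radius])
    return ResiduePatch(center=center, members=members, radius=radius)


def _paired_coords(
    patch: ResiduePatch, reference: Structure, alternate: Structure
) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinates of patch members present in both structures with the
    same residue type ("identical residues"); mismatches are dropped."""
    alt_residues = set(int(r) for r in alternate.residue_ids)
    paired = []
    for rid in sorted(patch.members):
        if rid not in alt_residues:
            continue
        if reference.residue_name(rid) != alternate.residue_name(rid):
            continue
        paired.append(rid)
    paired = np.array(paired, dtype=int)
    if len(paired) == 0:
        return np.empty((0, 3)), np.empty((0, 3))
    try:
        ref_ca = reference.ca_coordinates(paired)
        alt_ca = alternate.ca_coordinates(paired)
    except KeyError:
        # members lacking a Cα in either structure cannot be paired
        ok = []
        ref_ids = {int(r) for r in reference.atoms.res_id[reference.ca_mask()]}
        alt_ids = {int(r) for r in alternate.atoms.res_id[alternate.ca_mask()]}
        ok = [r for r in paired if r in ref_ids and r in alt_ids]
        paired = np.array(ok, dtype=int)
        if len(paired) == 0:
            return np.empty((0, 3)), np.empty((0, 3))
        ref_ca = reference.ca_coordinates(paired)
        alt_ca = alternate.ca_coordinates(paired)
    return ref_ca, alt_ca


def patch_rmsd(
    patch: ResiduePatch, reference: Structure, alternate: Structure
) -> float | None:
    """Cα RMSD of the patch after optimal superposition, or ``None``.

    The pairing is restricted to patch members present in both structures
    with identical residue type; the Kabsch superposition and the RMSD use
    the same Cα atoms.  Returns ``None`` (unalignable) when fewer than
    three residues can be paired.
    """
    if reference.numbering != alternate.numbering:
        raise ValueError("structures must share the numbering convention")
    ref_ca, alt_ca = _paired_coords(patch, reference, alternate)
    if len(ref_ca) < 3:
        return None
    fit: SuperpositionResult = kabsch_superpose(ref_ca, alt_ca)
    return fit.rmsd


def divergence_map(
    reference: Structure,
    alternate: Structure,
    glycan_sites: frozenset[int] | set[int] = frozenset(),
    radius: float = DEFAULT_PATCH_RADIUS,
    surface_threshold: float = 0.10,
    probe_radius: float = 1.4,
    sasa_points: int = 960,
) -> DivergenceMap:
    """Per-surface-residue patch RMSD map between two conformers.

    Non-surface residues (relative side-chain accessibility below
    ``surface_threshold``) are flagged ``not_surface``; residues whose patch
    contains any glycan attachment site are flagged ``glycan_masked``;
    patches with fewer than three identical paired residues are
    ``unalignable``; the rest carry their patch RMSD.
    """
    ref_ids = set(int(r) for r in reference.residue_ids)
    alt_ids = set(int(r) for r in alternate.residue_ids)
    if not (ref_ids & alt_ids):
        raise ValueError("structures share no residue indices")

    profile = compute_sasa(reference, probe_radius, sasa_points)
    surface = surface_residues(profile, surface_threshold)
    glycans = set(glycan_sites)

    residue_ids = np.array(sorted(ref_ids), dtype=int)
    values = np.full(len(residue_ids), np.nan)
    status = np.empty(len(residue_ids), dtype=object)
    for i, rid in enumerate(residue_ids):
        if rid not in surface:
            status[i] = NOT_SURFACE
            continue
        patch = define_patch(reference, int(rid), radius)
        if patch.members & glycans:
            status[i] = GLYCAN_MASKED
            continue
        value = patch_rmsd(patch, reference, alternate)
        if value is None:
            status[i] = UNALIGNABLE
        else:
            status[i] = SCORED
            values[i] = value
    return DivergenceMap(residue_ids=residue_ids, values=values, status=status)


def write_divergence(
    dmap: DivergenceMap, structure: Structure, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write the map as a TSV and as a PDB with values in the B-factor column.

    Flagged (non-scored) residues are encoded as B-factor −1 so surface
    renderers can grey them out.  Returns the two written paths.
    """
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".tsv")
    pdb_path = out_prefix.with_suffix(".pdb")

    frame = dmap.to_frame()
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.4f")

    value_by_res = dict(zip(frame.residue, frame.patch_rmsd))
    atoms = structure.atoms.copy()
    b = np.array(
        [
            v if np.isfinite(v := value_by_res.get(int(rid), np.nan)) else -1.0
            for rid in atoms.res_id
        ]
    )
    atoms.set_annotation("b_factor", b)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(pdb_path))
    return tsv_path, pdb_path
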