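"""Replicate-MD post-analysis: RMSF profiles and hydrogen-bond occupancy.

Consumes ensembles of replicate trajectories over a shared topology (the
production engine itself is out of scope — trajectories are read from
multi-model PDB, XTC or DCD files, or generated synthetically) and
produces the two observables used to characterise a destabilising variant:

- a per-residue backbone RMSF profile averaged over replicates, and
- an occupancy table of hydrogen-bond counts for selected donor/acceptor
  residue pairs, with a difference ledger between two variants.

A hydrogen bond is counted geometrically: donor--acceptor heavy-atom
distance ≤ 3.5 Å and hydrogen-donor-acceptor angle ≤ 30°, evaluated for
every hydrogen attached to the donor.  Counts are sampled every 2 ps by
default, averaged within each replicate, and replicate means are averaged
(replicates are independent simulations, so the mean of means — not a
pooled-frame mean — is reported, with its SEM across replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from serpinmap.structure_core import Structure, kabsch_superpose

#: Maximum covalent H–heavy-atom bond length used to attach hydrogens (Å).
_H_BOND_LENGTH = 1.25

_BACKBONE = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition.

    ``max_distance`` is the donor--acceptor heavy-atom distance limit (Å);
    ``max_angle`` the hydrogen-donor-acceptor angle limit (degrees).
    """

    max_distance: float = 3.5
    max_angle: float = 30.0

    def __post_init__(self) -> None:
        if self.max_distance <= 0 or self.max_angle <= 0:
            raise ValueError("hydrogen-bond criteria must be positive")


@dataclass
class TrajectoryEnsemble:
    """Replicate frame sets over a shared topology.

    ``replicates`` holds one ``(n_frames, n_atoms, 3)`` coordinate array
    (Å) per independent simulation; all share the topology atom order.
    ``frame_interval`` is the time between stored frames in ps.
    """

    replicates: list[np.ndarray]
    topology: Structure
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        n_atoms = self.topology.atoms.array_length()
        for i, rep in enumerate(self.replicates):
            rep = np.asarray(rep, dtype=float)
            if rep.ndim != 3 or rep.shape[1:] != (n_atoms, 3):
                raise ValueError(
                    f"replicate {i}: expected (n_frames, {n_atoms}, 3) "
                    f"coordinates, got {rep.shape}"
                )
            if not np.all(np.isfinite(rep)):
                raise ValueError(f"replicate {i}: non-finite coordinates")
            self.replicates[i] = rep
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def load_ensemble(
    trajectory_paths: list[str | Path],
    topology_path: str | Path,
    frame_interval: float = 2.0,
) -> TrajectoryEnsemble:
    """Load replicate trajectories (multi-model PDB, XTC or DCD).

    XTC/DCD files are read through mdtraj (optional dependency) against the
    topology; multi-model PDB files are read directly.  Atom counts are
    validated against the topology for every replicate.
    """
    if not trajectory_paths:
        raise ValueError("at least one replicate trajectory is required")
    topology = _read_topology(topology_path)
    n_atoms = topology.atoms.array_length()
    replicates = []
    for path in trajectory_paths:
        path = Path(path)
        suffix = path.suffix.lower()
        if suffix == ".pdb":
            stack = PDBFile.read(str(path)).get_structure()
            coords = np.atleast_3d(stack.coord)
            if coords.ndim == 2:
                coords = coords[None]
        elif suffix in (".xtc", ".dcd"):
            import mdtraj

            traj = mdtraj.load(str(path), top=str(topology_path))
            coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm → Å
        else:
            raise ValueError(f"unsupported trajectory format {suffix!r}")
        if coords.shape[1] != n_atoms:
            raise ValueError(
                f"replicate {path.name}: {coords.shape[1]} atoms, "
                f"topology has {n_atoms}"
            )
        replicates.append(coords)
    return TrajectoryEnsemble(
        replicates=replicates, topology=topology, frame_interval=frame_interval
    )


def _read_topology(path: str | Path) -> Structure:
    """Topology with hydrogens retained (first model only)."""
    atoms = PDBFile.read(str(path)).get_structure(model=1)
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no protein atoms in topology")
    return Structure(atoms=atoms, numbering="mature")


def write_ensemble_pdb(
    ensemble: TrajectoryEnsemble, out_prefix: str | Path
) -> list[Path]:
    """Write each replicate as a multi-model PDB; returns the paths."""
    out_prefix = Path(out_prefix)
    paths = []
    for i, coords in enumerate(ensemble.replicates):
        stack = struc.from_template(ensemble.topology.atoms, coords)
        pdb = PDBFile()
        pdb.set_structure(stack)
        path = out_prefix.parent / f"{out_prefix.name}_rep{i}.pdb"
        pdb.write(str(path))
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------


@dataclass
class RMSFProfile:
    """Per-residue RMSF (Å) averaged over replicates."""

    residue_ids: np.ndarray
    rmsf: np.ndarray
    selection: str = "backbone"
    per_replicate: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residue_ids, "rmsf": self.rmsf})


def _selection_mask(topology: Structure, selection: str) -> np.ndarray:
    atoms = topology.atoms
    heavy = atoms.element != "H"
    if selection == "backbone":
        return heavy & np.isin(atoms.atom_name, _BACKBONE)
    if selection == "heavy":
        return heavy
    if selection == "CA":
        return atoms.atom_name == "CA"
    raise ValueError(f"unknown selection {selection!r}")


def _superpose_frames(
    coords: np.ndarray, fit_mask: np.ndarray, n_iterations: int = 2
) -> np.ndarray:
    """Superpose every frame onto the ensemble-mean structure.

    The reference is the mean structure after iterative refinement: frames
    are fitted (Kabsch on ``fit_mask`` atoms) to the running mean, the mean
    is recomputed, and the fit repeated.
    """
    frames = np.array(coords, dtype=float, copy=True)
    reference = frames[0]
    for _ in range(n_iterations):
        for f in range(frames.shape[0]):
            fit = kabsch_superpose(reference[fit_mask], frames[f][fit_mask])
            frames[f] = fit.apply(frames[f])
        reference = frames.mean(axis=0)
    return frames


def compute_rmsf(
    ensemble: TrajectoryEnsemble, selection: str = "backbone"
) -> RMSFProfile:
    """Per-residue RMSF averaged over replicates.

    Within each replicate, frames are least-squares superposed onto the
    replicate mean structure (backbone heavy atoms, two refinement
    iterations); the RMSF of each selected atom is its root-mean-square
    deviation from its time-average position, residues average over their
    selected atoms, and the final profile is the mean over replicates.
    """
    topology = ensemble.topology
    sel_mask = _selection_mask(topology, selection)
    fit_mask = _selection_mask(topology, "backbone")
    if not np.any(sel_mask):
        raise ValueError(f"selection {selection!r} matches no atoms")
    res_ids = topology.atoms.res_id[sel_mask]
    unique_res = np.unique(res_ids)

    profiles = []
    for i, coords in enumerate(ensemble.replicates):
        if coords.shape[0] < 2:
            raise ValueError(f"replicate {i}: RMSF needs at least 2 frames")
        fitted = _superpose_frames(coords, fit_mask)
        sel = fitted[:, sel_mask, :]
        mean_pos = sel.mean(axis=0)
        atom_rmsf = np.sqrt(
            np.mean(np.sum((sel - mean_pos) ** 2, axis=2), axis=0)
        )
        per_res = np.array(
            [atom_rmsf[res_ids == r].mean() for r in unique_res]
        )
        profiles.append(per_res)
    per_replicate = np.array(profiles)
    return RMSFProfile(
        residue_ids=unique_res,
        rmsf=per_replicate.mean(axis=0),
        selection=selection,
        per_replicate=per_replicate,
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def _polar_topology(topology: Structure):
    """Map donors (N/O with attached hydrogens) and acceptors (N/O).

    Hydrogens are attached to the nearest N/O heavy atom within the
    covalent bond length in the topology geometry.  Returns
    ``(donors, acceptors)`` where donors maps residue id →
    list of (heavy index, tuple of hydrogen indices) and acceptors maps
    residue id → list of heavy indices.
    """
    atoms = topology.atoms
    coord = atoms.coord
    polar = np.isin(atoms.element, ("N", "O"))
    polar_idx = np.flatnonzero(polar)
    h_idx = np.flatnonzero(atoms.element == "H")

    attached: dict[int, list[int]] = {int(i): [] for i in polar_idx}
    for h in h_idx:
        if len(polar_idx) == 0:
            break
        dists = np.linalg.norm(coord[polar_idx] - coord[h], axis=1)
        j = int(np.argmin(dists))
        if dists[j] <= _H_BOND_LENGTH:
            attached[int(polar_idx[j])].append(int(h))

    donors: dict[int, list[tuple[int, tuple[int, ...]]]] = {}
    acceptors: dict[int, list[int]] = {}
    for i in polar_idx:
        rid = int(atoms.res_id[i])
        acceptors.setdefault(rid, []).append(int(i))
        if attached[int(i)]:
            donors.setdefault(rid, []).append((int(i), tuple(attached[int(i)])))
    return donors, acceptors


def count_hbonds_frame(
    frame: np.ndarray,
    donor_atoms: list[tuple[int, tuple[int, ...]]],
    acceptor_atoms: list[int],
    criteria: HBondCriteria = HBondCriteria(),
) -> int:
    """Hydrogen bonds between donor and acceptor atom sets in one frame.

    A donor/acceptor atom combination counts one bond when the heavy-atom
    distance is within the limit and *any* hydrogen on the donor satisfies
    the hydrogen-donor-acceptor angle limit; counts are summed over the
    combinations.
    """
    count = 0
    cos_limit = np.cos(np.deg2rad(criteria.max_angle))
    for d_idx, h_indices in donor_atoms:
        d = frame[d_idx]
        for a_idx in acceptor_atoms:
            if a_idx == d_idx:
                continue
            da = frame[a_idx] - d
            dist = np.linalg.norm(da)
            if dist > criteria.max_distance or dist == 0:
                continue
            for h_idx in h_indices:
                dh = frame[h_idx] - d
                norm = np.linalg.norm(dh)
                if norm == 0:
                    continue
                cos_angle = np.dot(dh, da) / (norm * dist)
                if cos_angle >= cos_limit:  # angle ≤ limit
                    count += 1
                    break
    return count


@dataclass
class OccupancyTable:
    """Average hydrogen-bond counts for selected residue pairs.

    One row per (donor residue, acceptor residue): the mean over replicate
    means, the per-replicate means, and the SEM across replicates (0 for a
    single replicate).
    """

    frame: pd.DataFrame  # columns: donor, acceptor, mean, sem
    replicate_means: np.ndarray  # (n_pairs, n_replicates)

    def __post_init__(self) -> None:
        if self.frame.duplicated(["donor", "acceptor"]).any():
            raise ValueError("duplicate (donor, acceptor) rows")
        if (self.frame["mean"] < 0).any() or (self.frame["sem"] < 0).any():
            raise ValueError("means and SEMs must be ≥ 0")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.frame.donor, self.frame.acceptor))


def hbond_occupancy(
    ensemble: TrajectoryEnsemble,
    pairs: list[tuple[int, int]],
    criteria: HBondCriteria = HBondCriteria(),
    stride: float = 2.0,
) -> OccupancyTable:
    """Average hydrogen-bond count per frame for each residue pair.

    Frames are sampled every ``stride`` ps (must be a multiple of the
    ensemble frame interval).  For each pair the per-frame counts are
    averaged within each replicate, and the table reports the mean of the
    replicate means with its SEM.

    Raises if a donor residue carries no hydrogen-bearing polar atom — the
    topology then cannot support the angle criterion.
    """
    if not pairs:
        raise ValueError("empty pair list")
    step_f = stride / ensemble.frame_interval
    step = int(round(step_f))
    if step < 1 or abs(step_f - step) > 1e-9:
        raise ValueError(
            f"stride {stride} ps is not a multiple of the frame interval "
            f"{ensemble.frame_interval} ps"
        )
    donors, acceptors = _polar_topology(ensemble.topology)
    for donor_res, _ in pairs:
        if donor_res not in donors:
            raise ValueError(
                f"donor residue {donor_res} has no polar atom with an "
                f"attached hydrogen in the topology"
            )

    n_pairs = len(pairs)
    replicate_means = np.zeros((n_pairs, ensemble.n_replicates))
    for r, coords in enumerate(ensemble.replicates):
        sampled = coords[::step]
        counts = np.zeros((n_pairs, sampled.shape[0]))
        for f, frame in enumerate(sampled):
            for p, (donor_res, acceptor_res) in enumerate(pairs):
                counts[p, f] = count_hbonds_frame(
                    frame,
                    donors[donor_res],
                    acceptors.get(acceptor_res, []),
                    criteria,
                )
        replicate_means[:, r] = counts.mean(axis=1)

    mean = replicate_means.mean(axis=1)
    if ensemble.n_replicates > 1:
        sem = replicate_means.std(axis=1, ddof=1) / np.sqrt(
            ensemble.n_replicates
        )
    else:
        sem = np.zeros(n_pairs)
    frame = pd.DataFrame(
        {
            "donor": [p[0] for p in pairs],
            "acceptor": [p[1] for p in pairs],
            "mean": mean,
            "sem": sem,
        }
    )
    return OccupancyTable(frame=frame, replicate_means=replicate_means)


def occupancy_difference(
    table_a: OccupancyTable, table_b: OccupancyTable
) -> pd.DataFrame:
    """Difference ledger between two variants' occupancy tables.

    Rows (donor, acceptor, mean_a, mean_b, difference = mean_a − mean_b),
    ordered by descending difference — the layout used to summarise which
    hydrogen bonds a mutation abolishes or creates.
    """
    if set(table_a.pairs) != set(table_b.pairs):
        raise ValueError("occupancy tables cover different pair sets")
    a = table_a.frame.rename(columns={"mean": "mean_a"})[
        ["donor", "acceptor", "mean_a"]
    ]
    b = table_b.frame.rename(columns={"mean": "mean_b"})[
        ["donor", "acceptor", "mean_b"]
    ]
    merged = a.merge(b, on=["donor", "acceptor"], validate="one_to_one")
    merged["difference"] = merged.mean_a - merged.mean_b
    return merged.sort_values(
        "difference", ascending=False, ignore_index=True
    )
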