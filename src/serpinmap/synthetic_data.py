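"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its arguments (seed included):
repeated calls produce identical objects, so tests and the acceptance
script need no downloaded structures, trajectories, plate-reader exports
or alignments.  The generators emulate:

- idealised helical / extended backbones with localised Gaussian
  conformational perturbations (standing in for conformer crystal pairs);
- replicate trajectory ensembles with prescribed per-residue fluctuation
  amplitudes, and minimal donor/hydrogen/acceptor systems toggled between
  hydrogen-bond-satisfying and -violating geometries at a prescribed
  occupancy;
- saturating conjugation-kinetics curve pairs with configurable
  intensity/time scaling truth and noise;
- alignments drawn per column from prescribed amino-acid compositions
  with a gapless reference row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from serpinmap.structure_core import Structure
from serpinmap.trajectory_analysis import TrajectoryEnsemble
from serpinmap.protection_assay import (
    CurvePair,
    KineticsCurve,
    WITH_ANTIBODY,
    WITHOUT_ANTIBODY,
)

# Ideal alpha-helix parameters: 1.5 Å rise and 100° twist per residue on a
# 2.3 Å radius give consecutive Cα spacing ≈ 3.8 Å.
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)
_HELIX_RADIUS = 2.3
_CA_SPACING = 3.8


@dataclass
class GeneratorConfig:
    """Bundle of generator settings with the defaults used throughout.

    Only ``seed`` is required; the section dictionaries override the
    keyword defaults of the individual generators.
    """

    seed: int = 0
    geometry: dict = field(default_factory=dict)
    trajectory: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    alignment: dict = field(default_factory=dict)


def _backbone_atoms(ca: np.ndarray, start_res: int, chain: str) -> struc.AtomArray:
    """Full backbone (N, CA, C, O) threaded through given Cα positions.

    N and C are placed along the chain direction at covalent-bond
    distances; O is offset perpendicular to the local chain axis.  The
    geometry is idealised, not force-field-refined.
    """
    n_res = len(ca)
    atoms = struc.AtomArray(4 * n_res)
    coords = np.empty((4 * n_res, 3))
    names, elements, res_ids = [], [], []
    for i in range(n_res):
        if n_res == 1:
            prev_dir = np.array([-1.0, 0.0, 0.0])
            nxt_dir = np.array([1.0, 0.0, 0.0])
        else:
            prev_dir = ca[i] - ca[i - 1] if i > 0 else ca[i] - ca[i + 1]
            nxt_dir = ca[i + 1] - ca[i] if i < n_res - 1 else ca[i] - ca[i - 1]
        prev_u = prev_dir / np.linalg.norm(prev_dir)
        nxt_u = nxt_dir / np.linalg.norm(nxt_dir)
        perp = np.cross(prev_u, nxt_u)
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(nxt_u, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.array([0.0, 1.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        n_pos = ca[i] - 1.46 * prev_u
        c_pos = ca[i] + 1.52 * nxt_u
        o_pos = c_pos + 1.23 * perp
        base = 4 * i
        coords[base] = n_pos
        coords[base + 1] = ca[i]
        coords[base + 2] = c_pos
        coords[base + 3] = o_pos
        names += ["N", "CA", "C", "O"]
        elements += ["N", "C", "C", "O"]
        res_ids += [start_res + i] * 4
    atoms.coord = coords
    atoms.atom_name = np.array(names)
    atoms.element = np.array(elements)
    atoms.res_id = np.array(res_ids)
    atoms.res_name = np.full(4 * n_res, "GLY")
    atoms.chain_id = np.full(4 * n_res, chain)
    return atoms


def helix_ca_coordinates(
    n_residues: int, origin: np.ndarray | None = None, axis_z: bool = True
) -> np.ndarray:
    """Cα positions of an ideal α-helix along z."""
    i = np.arange(n_residues)
    coords = np.column_stack(
        [
            _HELIX_RADIUS * np.cos(_HELIX_TWIST * i),
            _HELIX_RADIUS * np.sin(_HELIX_TWIST * i),
            _HELIX_RISE * i,
        ]
    )
    if origin is not None:
        coords = coords + np.asarray(origin, dtype=float)
    return coords


def make_helix(n_residues: int = 20, start_res: int = 1, chain: str = "A") -> Structure:
    """Ideal α-helical glycine backbone (deterministic)."""
    ca = helix_ca_coordinates(n_residues)
    return Structure(atoms=_backbone_atoms(ca, start_res, chain))


def make_extended(
    n_residues: int = 10, start_res: int = 1, chain: str = "A"
) -> Structure:
    """Extended glycine chain with exact 3.8 Å Cα spacing along x."""
    i = np.arange(n_residues)
    ca = np.column_stack(
        [_CA_SPACING * i, 0.4 * (i % 2), np.zeros(n_residues)]
    )
    return Structure(atoms=_backbone_atoms(ca, start_res, chain))


def make_two_helix_bundle(
    n_per_helix: int = 30, separation: float = 10.0, chain: str = "A"
) -> Structure:
    """Two antiparallel ideal helices with axes ``separation`` Å apart.

    Residues 1..n form the first helix, n+1..2n the second (reversed
    direction), producing inter-helix Cα contacts within 8 Å for the
    default geometry — a minimal globular stand-in with a buried face and
    an exposed face on each helix.
    """
    ca_a = helix_ca_coordinates(n_per_helix)
    ca_b = helix_ca_coordinates(n_per_helix, origin=[separation, 0.0, 0.0])
    ca_b = ca_b[::-1]  # antiparallel
    atoms_a = _backbone_atoms(ca_a, 1, chain)
    atoms_b = _backbone_atoms(ca_b, n_per_helix + 1, chain)
    return Structure(atoms=atoms_a + atoms_b)


def perturb_region(
    structure: Structure,
    residues: set[int] | list[int],
    amplitude: float,
    seed: int = 0,
) -> Structure:
    """Gaussian displacement (per-coordinate sd = ``amplitude`` Å) applied
    only to the named residues; all other atoms are bit-identical."""
    if amplitude < 0:
        raise ValueError("amplitude must be ≥ 0")
    rng = np.random.default_rng(seed)
    coord = structure.coord.copy()
    mask = np.isin(structure.atoms.res_id, list(residues))
    if amplitude:
        coord[mask] += rng.normal(scale=amplitude, size=(int(mask.sum()), 3))
    return Structure(
        atoms=structure.atoms.copy(),
        numbering=structure.numbering,
        coord=coord,
    )


def write_structure_pdb(structure: Structure, path: str | Path) -> Path:
    """Write a generated structure to PDB."""
    pdb = PDBFile()
    pdb.set_structure(structure.atoms)
    pdb.write(str(path))
    return Path(path)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def make_trajectory(
    structure: Structure,
    sigma_profile: float | dict[int, float],
    n_frames: int = 100,
    n_replicates: int = 1,
    seed: int = 0,
    frame_interval: float = 2.0,
) -> TrajectoryEnsemble:
    """Ensemble of frames = structure + isotropic Gaussian jitter.

    ``sigma_profile`` is the per-coordinate standard deviation in Å,
    either a scalar or a mapping residue index → σ (unlisted residues get
    0).  Replicates use independent draws from a single seeded stream.
    """
    atoms = structure.atoms
    n_atoms = atoms.array_length()
    if isinstance(sigma_profile, dict):
        sigma = np.array(
            [sigma_profile.get(int(r), 0.0) for r in atoms.res_id]
        )
    else:
        sigma = np.full(n_atoms, float(sigma_profile))
    if np.any(sigma < 0):
        raise ValueError("fluctuation amplitudes must be ≥ 0")
    rng = np.random.default_rng(seed)
    base = structure.coord
    replicates = []
    for _ in range(n_replicates):
        jitter = rng.normal(size=(n_frames, n_atoms, 3)) * sigma[None, :, None]
        replicates.append(base[None] + jitter)
    return TrajectoryEnsemble(
        replicates=replicates, topology=structure, frame_interval=frame_interval
    )


def hbond_triad(distance: float, angle_deg: float) -> tuple[np.ndarray, list, list]:
    """Single donor/hydrogen/acceptor geometry with exact parameters.

    The donor N sits at the origin, the acceptor O at ``distance`` Å along
    x, and the hydrogen at 1.0 Å from the donor making exactly
    ``angle_deg`` with the donor→acceptor axis.  Returns
    ``(frame, donor_atoms, acceptor_atoms)`` ready for
    :func:`serpinmap.trajectory_analysis.count_hbonds_frame`.
    """
    theta = np.deg2rad(angle_deg)
    frame = np.array(
        [
            [0.0, 0.0, 0.0],                       # donor N
            [np.cos(theta), np.sin(theta), 0.0],   # H at 1.0 Å
            [distance, 0.0, 0.0],                  # acceptor O
        ]
    )
    return frame, [(0, (1,))], [2]


def _hbond_topology() -> Structure:
    """Two-residue donor/acceptor system (glycine-like placeholders).

    Residue 1 carries the donor N with its hydrogen; residue 2 the
    acceptor O.  Cα atoms anchor each residue away from the bond axis.
    """
    atoms = struc.AtomArray(5)
    atoms.coord = np.array(
        [
            [0.0, 0.0, 0.0],    # N  (donor, res 1)
            [1.0, 0.0, 0.0],    # H  on donor, pointing at the acceptor
            [-1.5, 0.0, 0.0],   # CA res 1
            [3.2, 0.0, 0.0],    # O  (acceptor, res 2)
            [4.7, 0.0, 0.0],    # CA res 2
        ]
    )
    atoms.atom_name = np.array(["N", "H", "CA", "O", "CA"])
    atoms.element = np.array(["N", "H", "C", "O", "C"])
    atoms.res_id = np.array([1, 1, 1, 2, 2])
    atoms.res_name = np.full(5, "GLY")
    atoms.chain_id = np.full(5, "A")
    return Structure(atoms=atoms)


def make_hbond_ensemble(
    occupancy: float,
    n_frames: int = 1000,
    n_replicates: int = 1,
    seed: int = 0,
    frame_interval: float = 2.0,
    on_distance: float = 3.2,
    off_distance: float = 4.5,
) -> TrajectoryEnsemble:
    """Minimal ensemble whose (1 → 2) hydrogen bond has occupancy ``p``.

    Each frame independently places the acceptor at 3.2 Å (bond present:
    distance and angle criteria both satisfied) with probability ``p`` or
    at 4.5 Å (absent) otherwise — explicit geometry toggling, so the
    target occupancy is exact in expectation rather than emergent from
    thermal sampling.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    topology = _hbond_topology()
    base = topology.coord
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(n_replicates):
        frames = np.repeat(base[None], n_frames, axis=0)
        on = rng.random(n_frames) < occupancy
        distances = np.where(on, on_distance, off_distance)
        frames[:, 3, 0] = distances          # acceptor O
        frames[:, 4, 0] = distances + 1.5    # its CA follows
        replicates.append(frames)
    return TrajectoryEnsemble(
        replicates=replicates, topology=topology, frame_interval=frame_interval
    )


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


def make_kinetics_pair(
    a_true: float = 1.0,
    b_true: float = 1.0,
    amplitude: float = 1000.0,
    rate: float = 0.15,
    baseline: float = 100.0,
    noise_sd: float = 0.0,
    duration: float = 30.0,
    n_points: int = 61,
    position: int = 232,
    antibody: str = "mAb",
    replicate: int = 1,
    seed: int = 0,
) -> CurvePair:
    """Saturating conjugation curve pair with known scaling truth.

    The −antibody curve is ``baseline + A(1 − e^{−kt}) + noise`` on a
    0–``duration`` minute grid; the +antibody curve is
    ``baseline + a·A(1 − e^{−b·k·t}) + noise``, so the configured
    ``(a_true, b_true)`` are exactly the intensity/time superposition
    scales a fitter should recover.  ``noise_sd`` is in the same arbitrary
    fluorescence units as ``amplitude``.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    minus = baseline + amplitude * (1.0 - np.exp(-rate * t))
    plus = baseline + a_true * amplitude * (1.0 - np.exp(-b_true * rate * t))
    if noise_sd > 0:
        minus = minus + rng.normal(scale=noise_sd, size=n_points)
        plus = plus + rng.normal(scale=noise_sd, size=n_points)
    common = dict(position=position, antibody=antibody, replicate=replicate)
    return CurvePair(
        plus=KineticsCurve(t, plus, WITH_ANTIBODY, **common),
        minus=KineticsCurve(t, minus, WITHOUT_ANTIBODY, **common),
    )


def make_protection_panel(
    positions: tuple[int, ...] = (29, 68, 74, 81, 89, 139, 155, 178, 203, 260, 306),
    protected: dict[int, float] | None = None,
    n_replicates: int = 4,
    noise_fraction: float = 0.02,
    amplitude: float = 1000.0,
    antibody: str = "2C1",
    seed: int = 0,
) -> tuple[list[CurvePair], dict[int, float]]:
    """Single-cysteine survey panel with protection at chosen positions.

    Emulates an 11-position epitope-mapping survey in which only two
    positions respond to the antibody.  ``protected`` maps position →
    true fractional intensity (default: 139 → 0.60, 155 → 0.55); all
    other positions have truth 1.0.  Noise is ``noise_fraction`` of the
    amplitude.  Returns the curve pairs and the truth map.
    """
    if protected is None:
        protected = {139: 0.60, 155: 0.55}
    truth = {p: protected.get(p, 1.0) for p in positions}
    pairs = []
    counter = 0
    for position in positions:
        for replicate in range(1, n_replicates + 1):
            counter += 1
            pairs.append(
                make_kinetics_pair(
                    a_true=truth[position],
                    b_true=1.0,
                    amplitude=amplitude,
                    noise_sd=noise_fraction * amplitude,
                    position=position,
                    antibody=antibody,
                    replicate=replicate,
                    seed=seed * 100003 + counter,
                )
            )
    return pairs, truth


def kinetics_to_csv(pairs: list[CurvePair], path: str | Path) -> Path:
    """Write curve pairs in the long CSV layout ``read_curves`` expects."""
    rows = []
    for pair in pairs:
        for curve in (pair.plus, pair.minus):
            for t, i in zip(curve.time, curve.intensity):
                rows.append(
                    {
                        "time": t,
                        "intensity": i,
                        "condition": curve.condition,
                        "position": curve.position,
                        "antibody": curve.antibody,
                        "replicate": curve.replicate,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


def make_msa(
    column_compositions: list[dict[str, float]],
    n_sequences: int = 50,
    seed: int = 0,
    reference_id: str = "AAT_REFERENCE",
) -> MultipleSeqAlignment:
    """Alignment drawn per column from prescribed compositions.

    Each composition maps states (amino-acid letters or ``'-'``) to
    probabilities summing to 1.  The first row is a gapless reference
    carrying each column's most probable non-gap state, so structure
    mapping through it is trivial; the remaining ``n_sequences − 1`` rows
    are sampled independently per column.
    """
    rng = np.random.default_rng(seed)
    n_cols = len(column_compositions)
    rows = np.empty((n_sequences, n_cols), dtype="U1")
    for c, composition in enumerate(column_compositions):
        states = sorted(composition)
        probs = np.array([composition[s] for s in states], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"column {c}: composition must sum to 1")
        non_gap = [s for s in states if s != "-"]
        if not non_gap:
            raise ValueError(f"column {c}: needs a non-gap state for the reference")
        best = max(non_gap, key=lambda s: composition[s])
        rows[0, c] = best
        rows[1:, c] = rng.choice(states, size=n_sequences - 1, p=probs)
    records = [
        SeqRecord(
            Seq("".join(rows[i])),
            id=reference_id if i == 0 else f"seq{i:04d}",
            description="",
        )
        for i in range(n_sequences)
    ]
    return MultipleSeqAlignment(records)
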