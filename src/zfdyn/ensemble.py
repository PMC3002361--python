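"""Conformational-ensemble I/O and geometry for protein-DNA complexes.

An ensemble is represented at one site per residue: the Cα atom of each amino
acid and the C1′ deoxyribose atom of each nucleotide.  Coordinates are stored
in nanometres; PDB files (Ångström) are converted on read and write.

The module covers reading multi-model PDB files, a plain per-frame coordinate
table, least-squares (Kabsch) superposition, concatenation of independent
simulation runs with leading-equilibration trimming, and RMSD monitoring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ANGSTROM_PER_NM = 10.0

#: Three-letter codes treated as amino acids.
PROTEIN_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE HID HIE HIP CYX""".split()
)
#: Residue names treated as nucleotides (DNA and RNA conventions).
NUCLEIC_RESIDUES = frozenset(
    "DA DT DG DC DU DI A T G C U I ADE THY GUA CYT URA".split()
)


class MoleculeClass(str, Enum):
    PROTEIN = "protein"
    NUCLEIC = "nucleic"


@dataclass(frozen=True)
class SiteTopology:
    """One representative site per residue or nucleotide.

    ``site_index`` is 0-based and contiguous over the complex; physical
    parameters (mass, charge, Lennard-Jones) are optional and only needed by
    the energy model.  Units: mass amu, charge e, lj_epsilon kcal/mol,
    lj_rmin_half nm.
    """

    site_index: int
    chain_id: str
    residue_number: int
    residue_name: str
    molecule_class: MoleculeClass
    representative_atom: str = "CA"
    mass: float | None = None
    partial_charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_name}{self.residue_number}"


def validate_topology(topology: Sequence[SiteTopology]) -> None:
    """Check contiguity and uniqueness of site indices."""
    indices = [s.site_index for s in topology]
    if sorted(indices) != list(range(len(topology))):
        raise ValueError("site_index values must be unique and cover 0..N-1")


def protein_sites(topology: Sequence[SiteTopology]) -> np.ndarray:
    return np.array(
        [s.site_index for s in topology if s.molecule_class == MoleculeClass.PROTEIN],
        dtype=int,
    )


def nucleic_sites(topology: Sequence[SiteTopology]) -> np.ndarray:
    return np.array(
        [s.site_index for s in topology if s.molecule_class == MoleculeClass.NUCLEIC],
        dtype=int,
    )


@dataclass
class CoordinateEnsemble:
    """Frames × sites × 3 coordinates in nm.

    ``superposed`` records whether rigid-body motion has been removed; the
    covariance/RMSF stages require it, the inter-site distance stages do not.
    """

    coordinates: np.ndarray
    frame_times: np.ndarray | None = None
    superposed: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_sites, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.n_frames < 1 or self.n_sites < 2:
            raise ValueError("need n_frames >= 1 and n_sites >= 2")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.n_frames,):
                raise ValueError("frame_times length must equal n_frames")
            if np.any(np.diff(self.frame_times) <= 0):
                raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coordinates.shape[1]

    def mean_structure(self) -> np.ndarray:
        """Arithmetic mean of the (ideally superposed) frames, (n_sites, 3) nm."""
        return self.coordinates.mean(axis=0)


# ---------------------------------------------------------------------------
# PDB I/O (Biopython behind the scenes)
# ---------------------------------------------------------------------------


def _representative_atom_name(resname: str) -> tuple[MoleculeClass, tuple[str, ...]]:
    if resname in PROTEIN_RESIDUES:
        return MoleculeClass.PROTEIN, ("CA",)
    if resname in NUCLEIC_RESIDUES:
        # C1* is the older PDB spelling of C1'
        return MoleculeClass.NUCLEIC, ("C1'", "C1*")
    raise KeyError(resname)


def _pick_altloc(atom):
    """Highest occupancy wins; ties go to the first altloc encountered."""
    from Bio.PDB.Atom import DisorderedAtom

    if isinstance(atom, DisorderedAtom):
        children = atom.disordered_get_list()
        best = children[0]
        for child in children[1:]:
            occ_b, occ_c = best.get_occupancy() or 0.0, child.get_occupancy() or 0.0
            if occ_c > occ_b:
                best = child
        return best
    return atom


def read_multimodel_pdb(
    path: str | Path,
) -> tuple[list[SiteTopology], CoordinateEnsemble]:
    """Read a (multi-)model PDB into topology + ensemble.

    One frame per MODEL and one site per standard residue: amino acids map to
    Cα, nucleotides to C1′ (``C1*`` accepted).  Residues that are neither
    (water, ions, ligands) are skipped.  All models must present the same
    residues in the same order.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("ens", str(path))

    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")

    topology: list[SiteTopology] = []
    frames: list[np.ndarray] = []
    reference_keys: list[tuple] | None = None
    for model in models:
        keys, coords = [], []
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                try:
                    mol_class, atom_names = _representative_atom_name(resname)
                except KeyError:
                    continue
                atom = None
                for name in atom_names:
                    if name in residue:
                        atom = _pick_altloc(residue[name])
                        break
                if atom is None:
                    raise ValueError(
                        f"{path}: residue {chain.id}:{resname}{residue.id[1]} "
                        f"lacks representative atom {atom_names[0]}"
                    )
                keys.append((chain.id, residue.id[1], resname, mol_class, atom_names[0]))
                coords.append(atom.get_coord())
        if not keys:
            raise ValueError(f"{path}: selection matched no residues")
        if reference_keys is None:
            reference_keys = keys
            topology = [
                SiteTopology(
                    site_index=i,
                    chain_id=k[0],
                    residue_number=k[1],
                    residue_name=k[2],
                    molecule_class=k[3],
                    representative_atom=k[4],
                )
                for i, k in enumerate(keys)
            ]
        elif keys != reference_keys:
            raise ValueError(f"{path}: models differ in residue content or order")
        frames.append(np.asarray(coords, dtype=float) / ANGSTROM_PER_NM)

    ensemble = CoordinateEnsemble(np.stack(frames))
    return topology, ensemble


def write_multimodel_pdb(
    path: str | Path,
    topology: Sequence[SiteTopology],
    ensemble: CoordinateEnsemble,
) -> None:
    """Write the representative-site ensemble as a multi-model PDB (Å)."""
    from Bio.PDB import PDBIO
    from Bio.PDB.Atom import Atom
    from Bio.PDB.Chain import Chain
    from Bio.PDB.Model import Model
    from Bio.PDB.Residue import Residue
    from Bio.PDB.Structure import Structure

    validate_topology(topology)
    structure = Structure("ens")
    for f in range(ensemble.n_frames):
        model = Model(f, f + 1)
        chains: dict[str, Chain] = {}
        for site in topology:
            chain = chains.setdefault(site.chain_id, Chain(site.chain_id))
            residue = Residue((" ", site.residue_number, " "), site.residue_name, "")
            coord = ensemble.coordinates[f, site.site_index] * ANGSTROM_PER_NM
            element = site.representative_atom[0]
            residue.add(
                Atom(
                    site.representative_atom,
                    coord,
                    0.0,
                    1.0,
                    " ",
                    site.representative_atom.ljust(4),
                    site.site_index + 1,
                    element=element,
                )
            )
            chain.add(residue)
        for chain in chains.values():
            model.add(chain)
        structure.add(model)
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(path))


# ---------------------------------------------------------------------------
# Plain coordinate table
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["frame", "site_index", "x_nm", "y_nm", "z_nm"]


def read_coordinate_table(path: str | Path) -> CoordinateEnsemble:
    """Read the TSV dialect (frame, site_index, x_nm, y_nm, z_nm)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    n_frames = int(df["frame"].max()) + 1
    n_sites = int(df["site_index"].max()) + 1
    if len(df) != n_frames * n_sites:
        raise ValueError(f"{path}: incomplete frame/site grid")
    df = df.sort_values(["frame", "site_index"])
    coords = df[["x_nm", "y_nm", "z_nm"]].to_numpy().reshape(n_frames, n_sites, 3)
    return CoordinateEnsemble(coords)


def write_coordinate_table(path: str | Path, ensemble: CoordinateEnsemble) -> None:
    frames, sites = np.meshgrid(
        np.arange(ensemble.n_frames), np.arange(ensemble.n_sites), indexing="ij"
    )
    flat = ensemble.coordinates.reshape(-1, 3)
    pd.DataFrame(
        {
            "frame": frames.ravel(),
            "site_index": sites.ravel(),
            "x_nm": flat[:, 0],
            "y_nm": flat[:, 1],
            "z_nm": flat[:, 2],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Concatenation with equilibration trimming
# ---------------------------------------------------------------------------


def concatenate_runs(
    ensembles: Sequence[CoordinateEnsemble],
    trim_fraction: float | None = None,
    trim_time_ps: float | None = None,
) -> CoordinateEnsemble:
    """Concatenate independent runs after dropping leading equilibration frames.

    Trimming is applied per run, before concatenation: either a leading
    fraction of frames or a leading span of simulated time (requires
    ``frame_times``).  With three 20 ns runs and a 5 ns trim the retained
    fraction per run is 0.75.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    if trim_fraction is not None and trim_time_ps is not None:
        raise ValueError("specify trim_fraction or trim_time_ps, not both")
    n_sites = ensembles[0].n_sites
    parts = []
    for i, ens in enumerate(ensembles):
        if ens.n_sites != n_sites:
            raise ValueError(
                f"run {i} has {ens.n_sites} sites, expected {n_sites}"
            )
        if trim_fraction is not None:
            if not 0.0 <= trim_fraction < 1.0:
                raise ValueError("trim_fraction must be in [0, 1)")
            n_trim = int(round(trim_fraction * ens.n_frames))
        elif trim_time_ps is not None:
            if ens.frame_times is None:
                raise ValueError("trim_time_ps requires frame_times on every run")
            t0 = ens.frame_times[0]
            n_trim = int(np.searchsorted(ens.frame_times, t0 + trim_time_ps))
        else:
            n_trim = 0
        if n_trim >= ens.n_frames:
            raise ValueError(f"trim removes every frame of run {i}")
        parts.append(ens.coordinates[n_trim:])
    superposed = all(e.superposed for e in ensembles)
    return CoordinateEnsemble(np.concatenate(parts, axis=0), superposed=superposed)


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centred ``mobile`` onto centred ``target``."""
    H = mobile.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _check_fit_sites(reference: np.ndarray, fit_sites: np.ndarray) -> None:
    pts = reference[fit_sites]
    if len(fit_sites) < 3:
        raise ValueError("superposition needs at least 3 fit sites")
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-10) < 2:
        raise ValueError("fit sites are collinear; rotation is underdetermined")


def _fit_frames(coords: np.ndarray, reference: np.ndarray, fit_sites: np.ndarray) -> np.ndarray:
    ref_fit = reference[fit_sites]
    ref_centroid = ref_fit.mean(axis=0)
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        mob_fit = coords[f, fit_sites]
        mob_centroid = mob_fit.mean(axis=0)
        R = kabsch_rotation(mob_fit - mob_centroid, ref_fit - ref_centroid)
        out[f] = (coords[f] - mob_centroid) @ R.T + ref_centroid
    return out


def superpose(
    ensemble: CoordinateEnsemble,
    reference: int | str = "mean",
    fit_sites: Sequence[int] | None = None,
    tol_nm: float = 1e-6,
    max_iter: int = 10,
) -> CoordinateEnsemble:
    """Least-squares superpose every frame onto a reference.

    ``reference`` is either a frame index or ``"mean"``, in which case the fit
    iterates (fit → recompute mean) until the mean structure moves by less
    than ``tol_nm`` RMS or ``max_iter`` rounds.  The iterative-mean fit is the
    default used before covariance analysis, since fluctuations are measured
    about the mean structure.
    """
    fit = (
        np.arange(ensemble.n_sites)
        if fit_sites is None
        else np.asarray(fit_sites, dtype=int)
    )
    coords = ensemble.coordinates.copy()
    if reference == "mean":
        _check_fit_sites(coords[0], fit)
        ref = coords.mean(axis=0)  # seeding with the mean makes the fit idempotent
        for _ in range(max_iter):
            coords = _fit_frames(coords, ref, fit)
            new_ref = coords.mean(axis=0)
            shift = math.sqrt(np.mean(np.sum((new_ref - ref) ** 2, axis=1)))
            ref = new_ref
            if shift < tol_nm:
                break
    else:
        ref = ensemble.coordinates[int(reference)]
        _check_fit_sites(ref, fit)
        coords = _fit_frames(coords, ref, fit)
    return CoordinateEnsemble(coords, frame_times=ensemble.frame_times, superposed=True)


def rmsd_series(
    ensemble: CoordinateEnsemble,
    reference: int | np.ndarray = 0,
    fit_sites: Sequence[int] | None = None,
) -> np.ndarray:
    """Per-frame RMSD (nm) to a reference frame or external structure.

    Each frame is superposed onto the reference over ``fit_sites`` (all sites
    by default) and the RMSD is evaluated over all sites.
    """
    if isinstance(reference, (int, np.integer)):
        ref = ensemble.coordinates[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
    if ref.shape != (ensemble.n_sites, 3):
        raise ValueError(
            f"reference has shape {ref.shape}, expected {(ensemble.n_sites, 3)}"
        )
    fit = (
        np.arange(ensemble.n_sites)
        if fit_sites is None
        else np.asarray(fit_sites, dtype=int)
    )
    _check_fit_sites(ref, fit)
    fitted = _fit_frames(ensemble.coordinates, ref, fit)
    return np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=2), axis=1))


def write_rmsd_series(
    path: str | Path, rmsd: np.ndarray, times_ps: np.ndarray | None = None
) -> None:
    first = ("time_ps", times_ps) if times_ps is not None else ("frame", np.arange(len(rmsd)))
    pd.DataFrame({first[0]: first[1], "rmsd_nm": rmsd}).to_csv(path, sep="\t", index=False)
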