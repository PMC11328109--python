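"""Ion-protein proximity statistics on trajectory frames.

Frames carry explicit protein atoms and ions (thiocyanate SCN-, guanidinium
Gdm+).  The protein "surface" is operationalised as the set of protein heavy
atoms; hydrogens are excluded on both the protein and ion side.  An ion is
inside the solvation shell when any of its heavy atoms lies within the
cutoff (4 A by default) of any protein heavy atom.  A side-chain contact is
an (ion, residue) pair with any ion heavy atom within the cutoff of any
heavy side-chain atom, counted once per pair per frame; a per-atom counting
convention is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "BACKBONE_ATOMS",
    "ION_SYNONYMS",
    "ProteinAtoms",
    "Ion",
    "TrajectoryFrame",
    "ResidueClassMap",
    "ShellOccupancy",
    "ContactStats",
    "ions_in_shell",
    "occupancy_series",
    "side_chain_contacts",
    "contact_stats",
    "min_distance_distribution",
    "read_frames",
    "write_frames",
]

#: Backbone atom names; everything else heavy is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Residue-name synonyms recognised as ions, mapped to canonical species.
ION_SYNONYMS = {"SCN": "SCN", "THC": "SCN", "GDM": "GDM", "GAI": "GDM"}


@dataclass
class ProteinAtoms:
    """Protein atoms of one frame (parallel arrays)."""

    res_name: np.ndarray
    res_id: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite protein coordinates")
        for name in ("res_name", "res_id", "atom_name", "element"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != self.coords.shape[0]:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)

    @property
    def is_hydrogen(self) -> np.ndarray:
        return np.char.upper(self.element.astype(str)) == "H"

    @property
    def is_side_chain(self) -> np.ndarray:
        backbone = np.isin(np.char.upper(self.atom_name.astype(str)),
                           sorted(BACKBONE_ATOMS))
        return ~backbone & ~self.is_hydrogen

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[~self.is_hydrogen]


@dataclass
class Ion:
    """One ion: species label plus per-atom elements/names/coordinates."""

    species: str
    elements: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.elements = np.asarray(self.elements)
        self.atom_names = np.asarray(self.atom_names)
        if self.coords.shape[0] == 0:
            raise ValueError("ion must have at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite ion coordinates")
        if self.species == "SCN":
            got = sorted(np.char.upper(self.elements.astype(str)))
            if got != ["C", "N", "S"]:
                raise ValueError(f"SCN ion must have atoms {{S, C, N}}, got {got}")

    @property
    def heavy_coords(self) -> np.ndarray:
        heavy = np.char.upper(self.elements.astype(str)) != "H"
        return self.coords[heavy]


@dataclass
class TrajectoryFrame:
    """Protein plus ions at one time point."""

    protein: ProteinAtoms
    ions: list
    index: int = 0
    temperature: float | None = None


@dataclass(frozen=True)
class ResidueClassMap:
    """Residue name -> chemical class used for contact aggregation."""

    mapping: dict = field(default_factory=lambda: dict(_DEFAULT_CLASSES))

    CLASSES = ("positive", "negative", "aromatic", "aliphatic")

    def classify(self, res_name: str) -> str:
        return self.mapping.get(str(res_name).upper(), "unclassified")


_DEFAULT_CLASSES = {
    "LYS": "positive", "ARG": "positive",
    "ASP": "negative", "GLU": "negative",
    "PHE": "aromatic", "TYR": "aromatic",
    "VAL": "aliphatic", "ILE": "aliphatic", "LEU": "aliphatic",
    "ALA": "aliphatic",
    "GLY": "unclassified", "PRO": "unclassified",
}


@dataclass(frozen=True)
class ShellOccupancy:
    """Per-frame in-shell ion counts with their normalised histogram."""

    counts: np.ndarray
    histogram: dict  # count -> percentage of frames
    mean: float

    @classmethod
    def from_counts(cls, counts) -> "ShellOccupancy":
        counts = np.asarray(counts, dtype=int)
        values, freq = np.unique(counts, return_counts=True)
        hist = {int(v): 100.0 * f / counts.size for v, f in zip(values, freq)}
        return cls(counts=counts, histogram=hist, mean=float(counts.mean()))


@dataclass(frozen=True)
class ContactStats:
    """Per-class (min, max, mean) contact counts over frames."""

    per_class: dict  # class -> {"min": int, "max": int, "mean": float}


def _protein_tree(frame: TrajectoryFrame) -> cKDTree:
    heavy = frame.protein.heavy_coords
    if heavy.shape[0] == 0:
        raise ValueError("frame has no protein heavy atoms")
    return cKDTree(heavy)


def ions_in_shell(frame: TrajectoryFrame, cutoff: float = 4.0,
                  species: str | None = None) -> int:
    """Number of ions with >= 1 heavy atom within ``cutoff`` of the protein."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    tree = _protein_tree(frame)
    count = 0
    for ion in frame.ions:
        if species is not None and ion.species != species:
            continue
        d, _ = tree.query(ion.heavy_coords, k=1)
        if np.min(d) <= cutoff:
            count += 1
    return count


def occupancy_series(frames, cutoff: float = 4.0,
                     species: str | None = None) -> ShellOccupancy:
    """Shell-occupancy histogram (percent of frames per ion count) and mean."""
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    counts = [ions_in_shell(f, cutoff, species) for f in frames]
    return ShellOccupancy.from_counts(counts)


def _side_chain_groups(protein: ProteinAtoms):
    """Yield (res_id, res_name, heavy side-chain coords) per residue."""
    side = protein.is_side_chain
    for res_id in np.unique(protein.res_id):
        sel = protein.res_id == res_id
        names = protein.res_name[sel]
        yield int(res_id), str(names[0]), protein.coords[sel & side]


def side_chain_contacts(frame: TrajectoryFrame, class_map: ResidueClassMap | None = None,
                        cutoff: float = 4.0, per_atom: bool = False,
                        species: str | None = "SCN") -> dict:
    """Per-class contact counts between ions and heavy side-chain atoms.

    A contact is an (ion, residue) pair within the cutoff, deduplicated per
    frame; with ``per_atom=True`` each (ion atom, side-chain atom) pair below
    the cutoff counts instead.
    """
    class_map = class_map or ResidueClassMap()
    counts = {c: 0 for c in ResidueClassMap.CLASSES}
    groups = []
    for res_id, res_name, sc_coords in _side_chain_groups(frame.protein):
        cls = class_map.classify(res_name)
        if cls == "unclassified":
            continue
        if sc_coords.shape[0] == 0:
            warnings.warn(f"residue {res_name}{res_id} has no heavy side-chain "
                          "atoms; skipped", stacklevel=2)
            continue
        groups.append((cls, cKDTree(sc_coords)))
    for ion in frame.ions:
        if species is not None and ion.species != species:
            continue
        xyz = ion.heavy_coords
        for cls, tree in groups:
            if per_atom:
                counts[cls] += sum(len(hits) for hits in
                                   tree.query_ball_point(xyz, cutoff))
            else:
                d, _ = tree.query(xyz, k=1)
                if np.min(d) <= cutoff:
                    counts[cls] += 1
    return counts


def contact_stats(frames, class_map: ResidueClassMap | None = None,
                  cutoff: float = 4.0, per_atom: bool = False,
                  species: str | None = "SCN") -> ContactStats:
    """Min/max/mean per-class contacts over a frame series."""
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    per_frame = [side_chain_contacts(f, class_map, cutoff, per_atom, species)
                 for f in frames]
    stats = {}
    for cls in ResidueClassMap.CLASSES:
        vals = np.array([c[cls] for c in per_frame])
        stats[cls] = {"min": int(vals.min()), "max": int(vals.max()),
                      "mean": float(vals.mean())}
    return ContactStats(per_class=stats)


def min_distance_distribution(frames, ion_atom: str = "N", bin_width: float = 0.05,
                              max_range: float | None = None,
                              species: str = "SCN"):
    """Histogram of per-ion per-frame minimum distances to the protein surface.

    For every frame and every ion of ``species``, the minimum distance from
    the ion atoms of element ``ion_atom`` to any protein heavy atom is
    collected and binned with ``bin_width`` [A].  Returns (bin_edges, counts,
    distances).
    """
    frames = list(frames)
    distances = []
    n_ions = 0
    for frame in frames:
        tree = _protein_tree(frame)
        for ion in frame.ions:
            if ion.species != species:
                continue
            n_ions += 1
            sel = np.char.upper(ion.elements.astype(str)) == ion_atom.upper()
            if not np.any(sel):
                continue
            d, _ = tree.query(ion.coords[sel], k=1)
            distances.append(float(np.min(d)))
    if n_ions == 0:
        raise ValueError(f"no {species} ions in the frame set")
    distances = np.asarray(distances)
    hi = max_range if max_range is not None else float(distances.max()) + bin_width
    kept = distances[distances < hi]
    if kept.size == 0:
        warnings.warn("all minimum distances beyond max_range; empty histogram",
                      stacklevel=2)
        edges = np.arange(0.0, hi + bin_width / 2, bin_width)
        return edges, np.zeros(edges.size - 1, dtype=int), distances
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(kept, bins=edges)
    return edges, counts, distances


# ---------------------------------------------------------------------------
# multi-model PDB I/O (biotite-backed)


def _frame_to_atom_array(frame: TrajectoryFrame):
    import biotite.structure as struc

    prot = frame.protein
    n_ion = sum(ion.coords.shape[0] for ion in frame.ions)
    n = prot.coords.shape[0] + n_ion
    arr = struc.AtomArray(n)
    coords = [prot.coords]
    arr.res_name[:len(prot.res_name)] = prot.res_name
    arr.res_id[:len(prot.res_id)] = prot.res_id
    arr.atom_name[:len(prot.atom_name)] = prot.atom_name
    arr.element[:len(prot.element)] = np.char.upper(prot.element.astype(str))
    arr.chain_id[:len(prot.res_id)] = "A"
    arr.hetero[:len(prot.res_id)] = False
    pos = len(prot.res_id)
    next_res = int(prot.res_id.max()) + 1 if len(prot.res_id) else 1
    for ion in frame.ions:
        m = ion.coords.shape[0]
        arr.res_name[pos:pos + m] = ion.species
        arr.res_id[pos:pos + m] = next_res
        arr.atom_name[pos:pos + m] = ion.atom_names
        arr.element[pos:pos + m] = np.char.upper(ion.elements.astype(str))
        arr.chain_id[pos:pos + m] = "B"
        arr.hetero[pos:pos + m] = True
        coords.append(ion.coords)
        pos += m
        next_res += 1
    arr.coord = np.concatenate(coords, axis=0)
    return arr


_AMINO_ACIDS = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL"})


def _atom_array_to_frame(arr, index: int = 0,
                         temperature: float | None = None) -> TrajectoryFrame:
    res_names = np.char.upper(arr.res_name.astype(str))
    is_ion = np.isin(res_names, sorted(ION_SYNONYMS))
    is_aa = np.isin(res_names, sorted(_AMINO_ACIDS))
    prot_sel = is_aa & ~is_ion
    protein = ProteinAtoms(
        res_name=arr.res_name[prot_sel].astype(str),
        res_id=arr.res_id[prot_sel].astype(int),
        atom_name=arr.atom_name[prot_sel].astype(str),
        element=arr.element[prot_sel].astype(str),
        coords=arr.coord[prot_sel],
    )
    ions = []
    ion_ids = arr.res_id[is_ion]
    for res_id in np.unique(ion_ids):
        sel = is_ion & (arr.res_id == res_id)
        species = ION_SYNONYMS.get(str(res_names[sel][0]), "other")
        ions.append(Ion(species=species,
                        elements=arr.element[sel].astype(str),
                        atom_names=arr.atom_name[sel].astype(str),
                        coords=arr.coord[sel]))
    return TrajectoryFrame(protein=protein, ions=ions, index=index,
                           temperature=temperature)


def read_frames(path, temperature: float | None = None) -> list:
    """Read a (multi-model) PDB file into a list of frames."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    frames = []
    for model in range(1, n_models + 1):
        arr = pdb.get_structure(model=model)
        frames.append(_atom_array_to_frame(arr, index=model - 1,
                                           temperature=temperature))
    return frames


def write_frames(frames, path) -> None:
    """Write frames as a multi-model PDB (MODEL/ENDMDL delimited)."""
    from biotite.structure.io.pdb import PDBFile

    lines = []
    for k, frame in enumerate(frames, start=1):
        pdb = PDBFile()
        pdb.set_structure(_frame_to_atom_array(frame))
        atom_lines = [l for l in pdb.lines if l.startswith(("ATOM", "HETATM"))]
        lines.append(f"MODEL     {k:>4}")
        lines.extend(atom_lines)
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
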