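"""Synthetic datasets with known ground truth for every pipeline stage.

Three generators emulate the study's data sources:

* DSC thermograms from the two-state forward model plus an instrument
  baseline and Gaussian noise (defaults: the aqueous-buffer transition,
  Td = 102.6 C, dHd = 470 kJ/mol, dCp = 5.2 kJ/K/mol);
* ITC titrations from the equal-and-independent-sites isotherm with the
  published injection schedule (25 x 10 ul into 961 ul, 300 mM syringe,
  42 uM protein) and weak-binding defaults n = 30, Kb = 6.3 1/M,
  dHb = -14.9 kJ/mol;
* trajectory frames with a procedurally built toy protein (one residue of
  every side-chain class, correct PDB atom names) and ions placed so each
  ion's minimum heavy-atom distance to the protein equals an assigned value.

Every generator takes a seed and is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import Ion, ProteinAtoms, TrajectoryFrame
from .dsc import BaselineModel, DSCTrace, TwoStateParams, simulate_trace, suggested_grid
from .itc import BindingParams, TitrationData, TitrationSchedule, simulate_titration

__all__ = [
    "DEFAULT_DSC_PARAMS",
    "DEFAULT_BINDING_PARAMS",
    "DEFAULT_SCHEDULE",
    "make_dsc_dataset",
    "make_itc_dataset",
    "dilution_heats",
    "toy_protein",
    "make_frame_set",
    "frames_from_counts",
]

#: Buffer-condition two-state parameters (Td 102.6 C, dHd 470, dCp 5.2).
DEFAULT_DSC_PARAMS = TwoStateParams(td=375.75, dh=470.0, dcp=5.2)

#: Weak thiocyanate binding to the D2 domain.
DEFAULT_BINDING_PARAMS = BindingParams(n=30.0, kb=6.3, dh_total=-14.9)

#: Published titration protocol.
DEFAULT_SCHEDULE = TitrationSchedule(
    cell_volume_ul=961.0, injection_volume_ul=10.0, n_injections=25,
    syringe_conc=0.300, protein_conc=42e-6)


def make_dsc_dataset(params: TwoStateParams = DEFAULT_DSC_PARAMS,
                     grid=None, baseline: BaselineModel | None = None,
                     noise_sd: float = 0.0, seed=None
                     ) -> tuple[DSCTrace, TwoStateParams]:
    """Synthetic thermogram plus its generating parameters."""
    if grid is None:
        grid = suggested_grid(params)
    trace = simulate_trace(params, grid, baseline=baseline,
                           noise_sd=noise_sd, seed=seed, label="synthetic-dsc")
    return trace, params


def dilution_heats(schedule: TitrationSchedule, q_first_uJ: float = -8.0) -> np.ndarray:
    """Salt-dilution heat series: decays with the syringe/cell gradient.

    The exotherm of diluting the titrant shrinks as the cell ligand
    concentration approaches the syringe concentration; a geometric decay
    with the displacement ratio captures that shape.
    """
    v, cell = schedule.injection_volume_ul, schedule.cell_volume_ul
    k = np.arange(schedule.n_injections)
    return q_first_uJ * (1.0 - v / cell) ** k


def make_itc_dataset(params: BindingParams = DEFAULT_BINDING_PARAMS,
                     schedule: TitrationSchedule = DEFAULT_SCHEDULE,
                     noise_sd_uJ: float = 0.0, seed=None,
                     with_dilution: bool = False,
                     q_dilution_uJ: float = -8.0
                     ) -> tuple[TitrationData, BindingParams, np.ndarray | None]:
    """Synthetic titration, its generating parameters, and the dilution series."""
    dil = dilution_heats(schedule, q_dilution_uJ) if with_dilution else None
    data = simulate_titration(params, schedule, noise_sd_uJ=noise_sd_uJ,
                              seed=seed, dilution_heats_uJ=dil)
    return data, params, dil


# ---------------------------------------------------------------------------
# toy protein and ion placement

# Side-chain atom names per residue type (backbone N/CA/C/O implied).
_SIDE_CHAINS = {
    "LYS": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    "ARG": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"), ("CZ", "C"),
            ("NH1", "N"), ("NH2", "N")],
    "ASP": [("CB", "C"), ("CG", "C"), ("OD1", "O"), ("OD2", "O")],
    "GLU": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("OE1", "O"), ("OE2", "O")],
    "PHE": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C"), ("CE1", "C"),
            ("CE2", "C"), ("CZ", "C")],
    "TYR": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C"), ("CE1", "C"),
            ("CE2", "C"), ("CZ", "C"), ("OH", "O")],
    "VAL": [("CB", "C"), ("CG1", "C"), ("CG2", "C")],
    "ILE": [("CB", "C"), ("CG1", "C"), ("CG2", "C"), ("CD1", "C")],
    "LEU": [("CB", "C"), ("CG", "C"), ("CD1", "C"), ("CD2", "C")],
    "ALA": [("CB", "C")],
    "GLY": [],
    "PRO": [("CB", "C"), ("CG", "C"), ("CD", "C")],
}

_TOY_SEQUENCE = ("LYS", "ARG", "ASP", "GLU", "PHE", "TYR",
                 "VAL", "ILE", "LEU", "ALA", "GLY", "PRO")


def toy_protein(radius: float = 8.0) -> ProteinAtoms:
    """Idealised ring-shaped mini-protein with one residue per type.

    Residues sit on a circle in the xy-plane with side chains pointing
    radially outward; geometry is schematic but atom names are standard PDB
    names so side-chain/backbone classification behaves as on real files.
    """
    res_names, res_ids, atom_names, elements, coords = [], [], [], [], []
    n_res = len(_TOY_SEQUENCE)
    for i, res in enumerate(_TOY_SEQUENCE):
        theta = 2.0 * np.pi * i / n_res
        u = np.array([np.cos(theta), np.sin(theta), 0.0])  # outward
        t = np.array([-np.sin(theta), np.cos(theta), 0.0])  # tangential
        ca = radius * u

        def add(name, element, xyz):
            res_names.append(res)
            res_ids.append(i + 1)
            atom_names.append(name)
            elements.append(element)
            coords.append(xyz)

        add("N", "N", ca - 1.46 * t + np.array([0.0, 0.0, 0.4]))
        add("CA", "C", ca)
        add("C", "C", ca + 1.52 * t + np.array([0.0, 0.0, 0.4]))
        add("O", "O", ca + 1.52 * t + np.array([0.0, 0.0, 1.6]))
        for j, (name, element) in enumerate(_SIDE_CHAINS[res]):
            # extend outward with a small alternating vertical zigzag
            zig = 0.35 * ((-1) ** j) * np.array([0.0, 0.0, 1.0])
            add(name, element, ca + (1.5 + 1.3 * j) * u + zig)
    return ProteinAtoms(res_name=np.array(res_names), res_id=np.array(res_ids),
                        atom_name=np.array(atom_names), element=np.array(elements),
                        coords=np.array(coords))


def _build_scn(anchor: np.ndarray, u: np.ndarray, distance: float,
               contact_element: str) -> Ion:
    p = anchor + distance * u
    if contact_element.upper() == "N":
        order = [("N1", "N", 0.0), ("C1", "C", 1.17), ("S1", "S", 2.83)]
    elif contact_element.upper() == "S":
        order = [("S1", "S", 0.0), ("C1", "C", 1.66), ("N1", "N", 2.83)]
    else:
        raise ValueError("SCN contact element must be N or S")
    names = [o[0] for o in order]
    elements = [o[1] for o in order]
    coords = np.array([p + d * u for _, _, d in order])
    return Ion(species="SCN", elements=np.array(elements),
               atom_names=np.array(names), coords=coords)


def _build_gdm(anchor: np.ndarray, u: np.ndarray, distance: float) -> Ion:
    p = anchor + distance * u  # contact nitrogen
    w = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, w)) > 0.9:
        w = np.array([1.0, 0.0, 0.0])
    w = w - np.dot(w, u) * u
    w = w / np.linalg.norm(w)
    c = p + 1.34 * u
    n2 = c + 1.34 * (0.5 * u + 0.866 * w)
    n3 = c + 1.34 * (0.5 * u - 0.866 * w)
    names = ["N1", "C", "N2", "N3", "HN11", "HN21", "HN31"]
    elements = ["N", "C", "N", "N", "H", "H", "H"]
    coords = np.array([p, c, n2, n3,
                       p + 1.0 * (0.3 * u + 0.954 * w),  # H still farther out
                       n2 + 1.0 * u, n3 + 1.0 * u])
    return Ion(species="GDM", elements=np.array(elements),
               atom_names=np.array(names), coords=coords)


def _min_distance(protein_heavy: np.ndarray, ion: Ion) -> float:
    diff = protein_heavy[:, None, :] - ion.heavy_coords[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def make_frame_set(plan, seed=None, temperature: float | None = None,
                   protein: ProteinAtoms | None = None,
                   tol: float = 1e-6, max_tries: int = 200
                   ) -> tuple[list, list]:
    """Frames with ions at prescribed minimum distances from the protein.

    ``plan`` is a list of frames, each a list of ion assignments
    ``(species, min_distance)`` or ``(species, min_distance, contact_element)``.
    Each ion is placed along the outward normal from a randomly chosen
    exterior side-chain atom; placements whose realised minimum distance
    deviates from the assignment by more than ``tol`` (or that clash with an
    already placed ion) are rejected and resampled.

    Returns (frames, realised minimum distances per frame).
    """
    rng = np.random.default_rng(seed)
    protein = protein or toy_protein()
    heavy = protein.heavy_coords
    centroid = heavy.mean(axis=0)
    radii = np.linalg.norm(heavy - centroid, axis=1)
    exterior = np.flatnonzero(radii >= np.quantile(radii, 0.6))
    frames, realised = [], []
    for f_idx, assignments in enumerate(plan):
        ions, dists, placed = [], [], []
        for spec in assignments:
            species, distance = spec[0], float(spec[1])
            contact = spec[2] if len(spec) > 2 else "N"
            if distance <= 0:
                raise ValueError("plan distances must be positive")
            ok = False
            for _ in range(max_tries):
                anchor = heavy[rng.choice(exterior)]
                u = anchor - centroid
                u = u / np.linalg.norm(u)
                # small random tilt so several ions can share an anchor
                axis = rng.normal(size=3)
                axis -= np.dot(axis, u) * u
                axis /= np.linalg.norm(axis)
                angle = rng.uniform(0.0, 0.35)
                u = np.cos(angle) * u + np.sin(angle) * axis
                if species == "SCN":
                    ion = _build_scn(anchor, u, distance, contact)
                elif species == "GDM":
                    ion = _build_gdm(anchor, u, distance)
                else:
                    raise ValueError(f"unknown ion species {species!r}")
                d = _min_distance(heavy, ion)
                clash = any(np.linalg.norm(ion.heavy_coords[0] - q) < 1.0
                            for q in placed)
                if abs(d - distance) <= tol and not clash:
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"infeasible ion placement at {distance} A in frame {f_idx}")
            ions.append(ion)
            dists.append(d)
            placed.append(ion.heavy_coords[0])
        frames.append(TrajectoryFrame(protein=protein, ions=ions, index=f_idx,
                                      temperature=temperature))
        realised.append(dists)
    return frames, realised


def frames_from_counts(counts, cutoff: float = 4.0, n_total: int | None = None,
                       species: str = "SCN", seed=None) -> list:
    """Frames engineered so exactly ``counts[k]`` ions fall inside the shell.

    All frames carry the same total ion number (``n_total``, default the
    maximum count) so the set round-trips through multi-model PDB; ions not
    in the shell are parked at 1.5-6 A beyond the cutoff.
    """
    counts = [int(c) for c in counts]
    n_total = max(counts) if n_total is None else int(n_total)
    if n_total < max(counts):
        raise ValueError("n_total below the largest requested count")
    rng = np.random.default_rng(seed)
    plan = []
    for c in counts:
        inside = rng.uniform(2.8, cutoff - 0.15, size=c)
        outside = rng.uniform(cutoff + 1.5, cutoff + 6.0, size=n_total - c)
        plan.append([(species, float(d)) for d in np.concatenate([inside, outside])])
    frames, _ = make_frame_set(plan, seed=rng.integers(2**31 - 1))
    return frames
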